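"""Core value types shared by the pipeline stages.

Conventions used throughout the package:

* pixel coordinates are 0-based ``(row, column)`` with row 0 at the image top,
  matching the raster order of PNG and DICOM;
* images are 2-D ``float64`` arrays normalised to ``[0, 1]``;
* masks are 2-D boolean arrays, ``True`` = endometrium foreground;
* physical scale is a single isotropic pixel spacing in mm/px.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError

PATHOLOGY_LABELS = ("N", "P", "EC")  # normal, polyp, endometrial cancer


@dataclass(frozen=True)
class UltrasoundImage:
    """One grayscale ultrasound frame with its physical pixel spacing.

    Parameters
    ----------
    pixels:
        2-D array of grayscale values in ``[0, 1]``.
    spacing_mm_per_px:
        Isotropic physical size of one pixel in millimetres; must be positive
        before any millimetre-valued output can be produced.
    case_id, frame_id:
        Free-form identifiers carried through to reports.
    """

    pixels: np.ndarray
    spacing_mm_per_px: float
    case_id: str = ""
    frame_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError(
                f"image pixels must be a 2-D array with positive size, got shape {px.shape}"
            )
        if not np.isfinite(self.spacing_mm_per_px) or self.spacing_mm_per_px <= 0:
            raise ValidationError(
                f"spacing_mm_per_px must be > 0, got {self.spacing_mm_per_px}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class BinaryMask:
    """A strictly two-valued foreground mask on the same grid as its image."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValidationError(
                f"mask must be a 2-D array with positive size, got shape {arr.shape}"
            )
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.isin(uniq, (0, 1)).all():
                raise ValidationError(
                    "mask values must be two-valued (boolean or {0,1}); "
                    f"found values {uniq[:10]}"
                )
            arr = arr.astype(bool)
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def foreground_count(self) -> int:
        return int(self.values.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryMask):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            (self.values == other.values).all()
        )


@dataclass(frozen=True)
class InscribedCircle:
    """Maximal circle inside a connected foreground region.

    ``radius_px`` is the Euclidean distance from the (integer) centre pixel to
    the nearest background pixel, where everything outside the image counts as
    background.  A single isolated foreground pixel therefore has radius 1.
    """

    center_row: int
    center_col: int
    radius_px: float

    def __post_init__(self) -> None:
        if self.radius_px < 1:
            raise ValidationError(
                f"inscribed-circle radius must be >= 1 px, got {self.radius_px}"
            )


@dataclass(frozen=True)
class ThicknessMeasurement:
    """Endometrial thickness derived from the largest inscribed circle.

    The pixel-count convention is ``thickness_px = 2 * radius_px - 1`` so a
    1-px region measures 1 px and odd-width strips are measured exactly.
    """

    circle: InscribedCircle
    thickness_px: float
    thickness_mm: float
    spacing_mm_per_px: float


@dataclass(frozen=True)
class EvaluationRecord:
    """One case's predicted and reference thickness, with optional pathology.

    ``predicted_mm`` is the automated measurement (y), ``reference_mm`` the
    sonographer gold standard (x); the compared error is ``y - x``.
    """

    case_id: str
    predicted_mm: float
    reference_mm: float
    pathology: str | None = None

    def __post_init__(self) -> None:
        for name in ("predicted_mm", "reference_mm"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v}")
        if self.pathology is not None and self.pathology not in PATHOLOGY_LABELS:
            raise ValidationError(
                f"pathology must be one of {PATHOLOGY_LABELS}, got {self.pathology!r}"
            )

    @property
    def error_mm(self) -> float:
        """Signed measurement error y - x in mm."""
        return self.predicted_mm - self.reference_mm

    @property
    def abs_error_mm(self) -> float:
        return abs(self.error_mm)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and texture parameters of a synthetic ultrasound phantom.

    The phantom emulates the longitudinal endometrial section: a single bright
    band of controllable maximal thickness on a darker speckled background.
    """

    height_px: int = 128
    width_px: int = 160
    target_thickness_px: int = 21
    curvature: float = 0.5
    foreground_intensity_mean: float = 0.75
    background_intensity_mean: float = 0.2
    speckle_scale: float = 0.3
    spacing_mm_per_px: float = 0.1

    def __post_init__(self) -> None:
        if self.height_px < 8 or self.width_px < 8:
            raise ValidationError("phantom must be at least 8x8 px")
        if not (1 <= self.target_thickness_px < min(self.height_px, self.width_px)):
            raise ValidationError(
                "target_thickness_px must satisfy 1 <= t < min(height, width), "
                f"got {self.target_thickness_px} for {self.height_px}x{self.width_px}"
            )
        if self.curvature < 0:
            raise ValidationError(f"curvature must be >= 0, got {self.curvature}")
        if not (0 < self.foreground_intensity_mean <= 1):
            raise ValidationError("foreground_intensity_mean must be in (0, 1]")
        if not (0 <= self.background_intensity_mean < 1):
            raise ValidationError("background_intensity_mean must be in [0, 1)")
        if self.foreground_intensity_mean <= self.background_intensity_mean:
            raise ValidationError(
                "phantoms are bright-on-dark: foreground mean must exceed background mean"
            )
        if self.speckle_scale < 0:
            raise ValidationError(f"speckle_scale must be >= 0, got {self.speckle_scale}")
        if self.spacing_mm_per_px <= 0:
            raise ValidationError(
                f"spacing_mm_per_px must be > 0, got {self.spacing_mm_per_px}"
            )


@dataclass(frozen=True)
class Phantom:
    """A generated phantom: image, ground-truth mask and oracle thickness."""

    spec: PhantomSpec
    image: UltrasoundImage
    mask: BinaryMask
    true_thickness_px: int
    seed: int

    @property
    def true_thickness_mm(self) -> float:
        return self.true_thickness_px * self.spec.spacing_mm_per_px


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-pixel 2x2 tally between a predicted and a reference mask."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class StratumRow:
    """One thickness stratum of the stratified acceptable-rate report."""

    label: str
    n_cases: int
    n_within: int

    @property
    def n_over(self) -> int:
        return self.n_cases - self.n_within

    @property
    def acceptable_rate_percent(self) -> float | None:
        """Rate in percent, or None for an empty stratum (rendered as an em dash)."""
        if self.n_cases == 0:
            return None
        return 100.0 * self.n_within / self.n_cases


@dataclass(frozen=True)
class StratifiedReport:
    """Acceptable-rate report stratified by reference thickness."""

    strata: tuple[StratumRow, ...]
    total: StratumRow
    threshold_mm: float
    bounds_mm: tuple[float, float] = (3.0, 10.0)
    rows: tuple[StratumRow, ...] = field(init=False)

    def __post_init__(self) -> None:
        if sum(r.n_cases for r in self.strata) != self.total.n_cases:
            raise ValidationError("stratum case counts must sum to the Total row")
        if sum(r.n_within for r in self.strata) != self.total.n_within:
            raise ValidationError("stratum within counts must sum to the Total row")
        object.__setattr__(self, "rows", (*self.strata, self.total))
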