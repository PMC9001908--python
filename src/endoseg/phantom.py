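"""Synthetic ultrasound phantoms with known endometrial geometry.

The generator renders a single bright, gently curved band — the longitudinal
endometrial section — of a requested maximal thickness on a darker background,
then applies multiplicative Rayleigh speckle, the standard first-order model
of ultrasound texture.  The ground-truth mask is the exact support of the
band before noise, and the band's true maximal thickness is re-measured on
that mask with the same inscribed-circle oracle the pipeline uses, so every
phantom carries a self-consistent reference value.

Geometry: the band is the set of pixels within ``(t - 1) / 2`` of a quadratic
centreline spanning the image width.  For odd ``t`` the rendered band is
exactly ``t`` pixels thick; for even ``t`` it is ``t - 1``, within the
documented +-1 px tolerance of the thickness convention.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import ndimage

from .datatypes import BinaryMask, Phantom, PhantomSpec, UltrasoundImage
from .exceptions import ValidationError
from .thickness import inscribed_circle_fast, thickness_from_radius

__all__ = ["PhantomSpec", "Phantom", "generate_phantom", "generate_cohort"]

_RAYLEIGH_MEAN = np.sqrt(np.pi / 2.0)  # mean of Rayleigh(sigma=1)


def _centerline_rows(spec: PhantomSpec, cols: np.ndarray) -> np.ndarray:
    """Row coordinate of the quadratic centreline at each (fractional) column."""
    h, w = spec.height_px, spec.width_px
    u = 2.0 * cols / (w - 1) - 1.0  # [-1, 1] across the width
    # Zero-mean parabola so the band stays vertically centred; amplitude is
    # curvature * H/8, bounded so the band cannot leave the frame.
    amplitude = spec.curvature * h / 8.0
    return h / 2.0 + amplitude * (u * u - 0.5)


def _band_mask(spec: PhantomSpec) -> np.ndarray:
    h, w = spec.height_px, spec.width_px
    half_width = (spec.target_thickness_px - 1) / 2.0
    amplitude = spec.curvature * h / 8.0
    if h / 2.0 + abs(amplitude) * 0.5 + half_width + 1 >= h:
        raise ValidationError(
            "band does not fit: reduce target_thickness_px or curvature "
            f"(thickness {spec.target_thickness_px}, curvature {spec.curvature}, "
            f"height {h})"
        )
    # Rasterise the centreline at 4x column supersampling, then take all
    # pixels within half_width of it via the distance transform.
    cols = np.linspace(0.0, w - 1.0, 4 * w)
    rows = _centerline_rows(spec, cols)
    line = np.zeros((h, w), dtype=bool)
    line[np.clip(np.rint(rows).astype(int), 0, h - 1),
         np.clip(np.rint(cols).astype(int), 0, w - 1)] = True
    dist_to_line = ndimage.distance_transform_edt(~line)
    return dist_to_line <= half_width


def generate_phantom(spec: PhantomSpec, seed: int) -> Phantom:
    """Render one phantom deterministically from ``(spec, seed)``.

    The returned image is ``band_intensity * (1 + speckle)`` clipped to
    ``[0, 1]``, where the speckle field is zero-mean rescaled Rayleigh noise
    of strength ``spec.speckle_scale``.  The mask is the noiseless band
    support and ``true_thickness_px`` is measured on it with the
    inscribed-circle search.
    """
    if not isinstance(spec, PhantomSpec):
        spec = PhantomSpec(**spec)  # allow plain dicts from config files
    band = _band_mask(spec)
    base = np.where(
        band, spec.foreground_intensity_mean, spec.background_intensity_mean
    ).astype(float)

    rng = np.random.default_rng(seed)
    rayleigh = rng.rayleigh(scale=1.0, size=band.shape)
    speckle = spec.speckle_scale * (rayleigh - _RAYLEIGH_MEAN)
    image = np.clip(base * (1.0 + speckle), 0.0, 1.0)

    mask = BinaryMask(band)
    circle = inscribed_circle_fast(mask)
    true_thickness = int(round(thickness_from_radius(circle.radius_px)))
    return Phantom(
        spec=spec,
        image=UltrasoundImage(
            pixels=image,
            spacing_mm_per_px=spec.spacing_mm_per_px,
            case_id=f"phantom-{seed}",
            frame_id="0",
        ),
        mask=mask,
        true_thickness_px=true_thickness,
        seed=seed,
    )


def generate_cohort(
    n: int,
    spec_ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> list[Phantom]:
    """Generate ``n`` phantoms with parameters sampled from given ranges.

    ``spec_ranges`` maps :class:`PhantomSpec` field names to ``(low, high)``
    ranges; ``target_thickness_px`` is sampled as a uniform integer
    (inclusive), float fields uniformly.  Unlisted fields keep the values of
    ``base_spec`` (default: :class:`PhantomSpec` defaults).  Per-phantom seeds
    are ``seed + index``, so cohorts are reproducible and phantoms carry
    independent speckle.
    """
    if n < 1:
        raise ValidationError(f"cohort size must be >= 1, got {n}")
    spec_ranges = dict(spec_ranges or {})
    base = base_spec or PhantomSpec()

    int_fields = {"height_px", "width_px", "target_thickness_px"}
    unknown = set(spec_ranges) - {f for f in PhantomSpec.__dataclass_fields__}
    if unknown:
        raise ValidationError(f"unknown PhantomSpec fields in ranges: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    phantoms: list[Phantom] = []
    for i in range(n):
        overrides: dict[str, float | int] = {}
        for name, (lo, hi) in spec_ranges.items():
            if name in int_fields:
                overrides[name] = int(rng.integers(int(lo), int(hi) + 1))
            else:
                overrides[name] = float(rng.uniform(lo, hi))
        spec = replace(base, **overrides)
        phantoms.append(generate_phantom(spec, seed=seed + i))
    return phantoms
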