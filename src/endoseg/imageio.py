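"""Reading and writing the formats the pipeline touches.

Images arrive as DICOM (pixel spacing read from the ``PixelSpacing`` header,
asserted isotropic within 1%) or as grayscale PNG with the spacing supplied
explicitly.  Masks are 0/255 PNG with the nonzero-is-foreground rule.
Measurement tables are UTF-8 CSV with a header row.

Pixel values are normalised to [0, 1] by the maximum the sample depth can
represent (``2**BitsStored - 1`` for DICOM, the dtype maximum for PNG), so
the normalisation is a property of the format dialect, not of the data.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import pydicom
from PIL import Image

from .datatypes import PATHOLOGY_LABELS, BinaryMask, EvaluationRecord, UltrasoundImage
from .exceptions import (
    AnisotropySpacingError,
    FormatError,
    MissingSpacingError,
    SchemaError,
    ValidationError,
)

__all__ = [
    "read_image",
    "read_mask",
    "write_mask",
    "read_records",
    "write_records",
    "write_image_png",
]

_ANISOTROPY_TOL = 0.01  # relative row/column spacing difference allowed


def _is_dicom(path: Path) -> bool:
    if path.suffix.lower() in (".dcm", ".dicom"):
        return True
    if path.suffix.lower() == ".png":
        return False
    try:
        with open(path, "rb") as fh:
            fh.seek(128)
            return fh.read(4) == b"DICM"
    except OSError:
        return False


def _gray_from_array(arr: np.ndarray) -> np.ndarray:
    """Collapse a (H, W[, C]) array to one grayscale channel."""
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3:
        channels = arr.reshape(arr.shape[0], arr.shape[1], -1)
        if all(
            np.array_equal(channels[..., 0], channels[..., i])
            for i in range(1, channels.shape[-1])
        ):
            return channels[..., 0]
        raise FormatError(
            "multi-channel image with disagreeing channels is not a grayscale frame"
        )
    raise FormatError(f"expected a 2-D image, got {arr.ndim}-D data")


def _read_dicom(path: Path, spacing_override: float | None) -> UltrasoundImage:
    try:
        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
    except Exception as exc:  # pydicom raises a zoo of types
        raise FormatError(f"could not read DICOM file {path}: {exc}") from exc

    if spacing_override is not None:
        spacing = float(spacing_override)
    else:
        ps = getattr(ds, "PixelSpacing", None)
        if ps is None:
            raise MissingSpacingError(
                f"{path}: no PixelSpacing in the DICOM header and no spacing "
                "override supplied"
            )
        row_sp, col_sp = float(ps[0]), float(ps[1])
        if abs(row_sp - col_sp) > _ANISOTROPY_TOL * max(row_sp, col_sp):
            raise AnisotropySpacingError(
                f"{path}: pixel spacing is anisotropic beyond 1% "
                f"(row {row_sp} mm vs column {col_sp} mm)"
            )
        spacing = row_sp

    arr = _gray_from_array(np.asarray(arr))
    bits = int(getattr(ds, "BitsStored", arr.dtype.itemsize * 8))
    maxval = float(2**bits - 1)
    pixels = np.clip(arr.astype(float) / maxval, 0.0, 1.0)
    return UltrasoundImage(
        pixels=pixels,
        spacing_mm_per_px=spacing,
        case_id=str(getattr(ds, "PatientID", path.stem)),
        frame_id=str(getattr(ds, "InstanceNumber", "0")),
    )


def _read_png_array(path: Path) -> np.ndarray:
    try:
        with Image.open(path) as img:
            return np.asarray(img)
    except Exception as exc:
        raise FormatError(f"could not read PNG file {path}: {exc}") from exc


def read_image(
    path: str | os.PathLike, spacing_override: float | None = None
) -> UltrasoundImage:
    """Read one grayscale frame from DICOM or PNG with its pixel spacing.

    DICOM carries its spacing in the header (``PixelSpacing``; row spacing is
    used and row/column isotropy is asserted within 1%).  PNG has no spacing,
    so ``spacing_override`` (mm/px) is required.  Pixel values are rescaled
    to [0, 1].
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if spacing_override is not None and spacing_override <= 0:
        raise ValidationError(
            f"spacing_override must be > 0, got {spacing_override}"
        )
    if _is_dicom(path):
        return _read_dicom(path, spacing_override)

    if spacing_override is None:
        raise MissingSpacingError(
            f"{path}: PNG carries no physical spacing; pass spacing_override in mm/px"
        )
    arr = _gray_from_array(_read_png_array(path))
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"{path}: expected an integer-sampled grayscale PNG")
    maxval = float(np.iinfo(arr.dtype).max)
    return UltrasoundImage(
        pixels=arr.astype(float) / maxval,
        spacing_mm_per_px=float(spacing_override),
        case_id=path.stem,
        frame_id="0",
    )


def read_mask(path: str | os.PathLike) -> BinaryMask:
    """Read a PNG mask; any nonzero pixel is foreground."""
    arr = _read_png_array(Path(path))
    arr = _gray_from_array(arr)
    return BinaryMask(arr != 0)


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    """Write a mask as 8-bit PNG with 0/255 encoding; inverse of read_mask."""
    values = mask.values if isinstance(mask, BinaryMask) else BinaryMask(mask).values
    Image.fromarray((values.astype(np.uint8) * 255)).save(Path(path), format="PNG")


def write_image_png(image: UltrasoundImage | np.ndarray, path: str | os.PathLike) -> None:
    """Write a [0, 1] grayscale image as 8-bit PNG (spacing is not stored)."""
    px = image.pixels if isinstance(image, UltrasoundImage) else np.asarray(image)
    arr = np.clip(np.rint(px * 255), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(Path(path), format="PNG")


_REQUIRED_COLUMNS = ("case_id", "predicted_mm", "reference_mm")


def read_records(path: str | os.PathLike) -> list[EvaluationRecord]:
    """Read prediction/reference thickness pairs from CSV.

    Requires columns ``case_id``, ``predicted_mm``, ``reference_mm`` and
    accepts an optional ``pathology`` column with values N, P or EC.
    """
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"could not read CSV {path}: {exc}") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    records = []
    has_pathology = "pathology" in frame.columns
    for i, row in frame.iterrows():
        try:
            pred = float(row["predicted_mm"])
            ref = float(row["reference_mm"])
        except (TypeError, ValueError) as exc:
            raise FormatError(
                f"{path} row {i}: non-numeric mm value "
                f"({row['predicted_mm']!r}, {row['reference_mm']!r})"
            ) from exc
        pathology = None
        if has_pathology and not pd.isna(row["pathology"]):
            pathology = str(row["pathology"])
            if pathology not in PATHOLOGY_LABELS:
                raise ValidationError(
                    f"{path} row {i}: pathology {pathology!r} not in "
                    f"{PATHOLOGY_LABELS}"
                )
        records.append(
            EvaluationRecord(
                case_id=str(row["case_id"]),
                predicted_mm=pred,
                reference_mm=ref,
                pathology=pathology,
            )
        )
    return records


def write_records(records: list[EvaluationRecord], path: str | os.PathLike) -> None:
    """Write records to CSV in the schema read_records expects."""
    pd.DataFrame(
        [
            {
                "case_id": r.case_id,
                "predicted_mm": r.predicted_mm,
                "reference_mm": r.reference_mm,
                "pathology": r.pathology,
            }
            for r in records
        ]
    ).to_csv(path, index=False)
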