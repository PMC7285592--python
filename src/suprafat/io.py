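"""File I/O: DICOM slices, ROI masks (image or polygon), spectra and result tables.

Rescale slope/intercept is applied eagerly at load so every downstream
computation works in physical intensity units.  Polygon masks follow the
pixel-center rule: a pixel belongs to the polygon iff its center (x=col,
y=row, continuous coordinates) lies inside or on the boundary.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pydicom
import shapely
from PIL import Image
from shapely.geometry import Polygon

from .datamodel import DEFAULT_MIN_ROI_PIXELS, IntensitySlice, RoiMask
from .errors import (
    AlignmentError,
    DegenerateRoiError,
    FormatError,
    InputError,
    UnsupportedInputError,
)
from .fat import FatFractionResult
from .mrs import PeakFit, Spectrum

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# slices
# ---------------------------------------------------------------------------

def load_dicom_slice(path: str | Path) -> IntensitySlice:
    """Read one single-frame DICOM file into physical intensity units."""
    path = Path(path)
    ds = pydicom.dcmread(path)
    if "PixelData" not in ds:
        raise FormatError(f"{path}: no pixel data")
    n_frames = int(ds.get("NumberOfFrames", 1) or 1)
    if n_frames > 1:
        raise UnsupportedInputError(f"{path}: multi-frame DICOM not supported")
    arr = ds.pixel_array.astype(np.float64)
    if arr.ndim != 2:
        raise UnsupportedInputError(f"{path}: expected a 2D frame, got shape {arr.shape}")
    slope = float(ds.get("RescaleSlope", 1.0))
    intercept = float(ds.get("RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    if "PixelSpacing" in ds:
        spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    else:
        spacing = (1.0, 1.0)
        log.warning("%s: no PixelSpacing tag; defaulting to 1x1 mm", path)
    return IntensitySlice(
        pixels=arr,
        pixel_spacing_mm=spacing,
        slice_index=int(ds.get("InstanceNumber", 0) or 0),
        source_id=str(ds.get("SOPInstanceUID", path.stem)),
    )


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def rasterize_polygon(vertices, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed polygon with the boundary-inclusive pixel-center rule."""
    verts = np.asarray(vertices, dtype=np.float64)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise AlignmentError(
            f"polygon needs >= 3 (x, y) vertices, got shape {verts.shape}"
        )
    poly = Polygon(verts)
    if not poly.is_valid or poly.area == 0:
        raise AlignmentError("degenerate or self-intersecting polygon")
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    # intersects includes the boundary, implementing the "ties inside" rule
    return shapely.intersects_xy(poly, xx.ravel(), yy.ravel()).reshape(rows, cols)


def load_mask(
    path: str | Path,
    region_label: str,
    slice_shape: tuple[int, int],
    slice_index: int = 0,
    observer_id: str = "",
    min_roi_pixels: int = DEFAULT_MIN_ROI_PIXELS,
) -> RoiMask:
    """Read a binary-image or JSON-polygon ROI mask aligned to a slice grid.

    JSON polygon files hold ``{"vertices": [[x, y], ...]}`` in continuous
    pixel coordinates.  Image masks (PNG or DICOM) must match the slice
    shape exactly; any nonzero pixel is in the ROI.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            payload = json.load(fh)
        if "vertices" not in payload:
            raise FormatError(f"{path}: polygon file lacks a 'vertices' key")
        mask = rasterize_polygon(payload["vertices"], slice_shape)
    elif path.suffix.lower() in (".dcm", ".dicom"):
        mask = pydicom.dcmread(path).pixel_array > 0
    else:
        mask = np.asarray(Image.open(path)) > 0
        if mask.ndim == 3:  # collapse any color channels
            mask = mask.any(axis=2)
    if mask.shape != tuple(slice_shape):
        raise AlignmentError(
            f"{path}: mask shape {mask.shape} does not match slice shape {tuple(slice_shape)}"
        )
    count = int(mask.sum())
    if count < min_roi_pixels:
        raise DegenerateRoiError(
            f"{path}: ROI has {count} pixels, fewer than {min_roi_pixels}"
        )
    log.info("%s: %s mask with %d pixels", path, region_label, count)
    return RoiMask(mask=mask, region_label=region_label,
                   slice_index=slice_index, observer_id=observer_id)


# ---------------------------------------------------------------------------
# tables and spectra
# ---------------------------------------------------------------------------

def results_to_frame(results: list[FatFractionResult | PeakFit]) -> pd.DataFrame:
    if not results:
        raise InputError("no results to write")
    rows = []
    for r in results:
        if isinstance(r, FatFractionResult):
            row = {
                "subject": r.subject_id,
                "region": r.region_label,
                "mean_fraction": r.mean_fraction,
            }
            for i, (frac, thr, (nfg, nbg)) in enumerate(
                zip(r.per_slice_fraction, r.per_slice_threshold, r.per_slice_counts)
            ):
                row[f"fraction_{i}"] = frac
                row[f"threshold_{i}"] = thr
                row[f"n_fg_{i}"] = nfg
                row[f"n_bg_{i}"] = nbg
            rows.append(row)
        elif isinstance(r, PeakFit):
            rows.append({
                "subject": "", "region": "mrs_voxel",
                "fat_water_ratio": r.fat_water_ratio,
                "amplitude_water": r.amplitude_water,
                "amplitude_lipid": r.amplitude_lipid,
                "center_water": r.center_water,
                "center_lipid": r.center_lipid,
                "residual_rms": r.residual_rms,
            })
        else:
            raise InputError(f"cannot tabulate {type(r).__name__}")
    return pd.DataFrame(rows)


def write_results_table(results: list, path: str | Path) -> None:
    """One CSV row per (subject, region); values round-trip to 6 decimals."""
    results_to_frame(results).to_csv(path, index=False)


def read_spectrum(path: str | Path, subject_id: str = "") -> Spectrum:
    """Two-column (ppm, magnitude) CSV, with or without a header line."""
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (ppm, magnitude)")
    try:
        ppm = df.iloc[:, 0].astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric ppm column") from exc
    return Spectrum(ppm=ppm, magnitude=df.iloc[:, 1].astype(float).to_numpy(),
                    subject_id=subject_id or Path(path).stem)


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    pd.DataFrame({"ppm": spectrum.ppm, "magnitude": spectrum.magnitude}).to_csv(
        path, index=False
    )


def read_ratings(path: str | Path) -> pd.DataFrame:
    """Ratings CSV with columns subject_id, rater_id, grade."""
    df = pd.read_csv(path, dtype={"subject_id": str, "rater_id": str})
    missing = {"subject_id", "rater_id", "grade"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df
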