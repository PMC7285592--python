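"""Core in-memory containers for slices, masks and slice stacks.

Conventions used throughout the package:

* arrays are indexed ``(row, col)``, 0-based;
* polygon vertices are continuous ``(x=col, y=row)`` coordinates;
* intensities are physical units, i.e. DICOM rescale slope/intercept has
  already been applied at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, IncompleteStackError, InputError

REGION_LABELS = ("muscle", "fossa")

#: Otsu on fewer pixels than this is statistically meaningless.
DEFAULT_MIN_ROI_PIXELS = 25


@dataclass
class IntensitySlice:
    """One 2D T1-weighted MR slice in physical intensity units."""

    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)
    slice_index: int = 0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise InputError(f"slice pixels must be 2D, got ndim={self.pixels.ndim}")
        if self.pixels.size < 4:
            raise InputError("slice must contain at least 4 pixels")
        if not np.all(np.isfinite(self.pixels)):
            raise InputError("slice contains non-finite intensities")
        sp = tuple(float(s) for s in self.pixel_spacing_mm)
        if len(sp) != 2 or any(s <= 0 for s in sp):
            raise InputError(f"pixel spacing must be two positive reals, got {self.pixel_spacing_mm}")
        self.pixel_spacing_mm = sp

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]


@dataclass
class RoiMask:
    """Binary pixel mask for one region on one slice."""

    mask: np.ndarray
    region_label: str
    slice_index: int = 0
    observer_id: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise InputError("mask must be 2D")
        if self.region_label not in REGION_LABELS:
            raise InputError(
                f"region_label must be one of {REGION_LABELS}, got {self.region_label!r}"
            )
        if self.pixel_count == 0:
            raise InputError("mask has no true pixels")

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())

    def check_aligned(self, image: IntensitySlice) -> None:
        if self.mask.shape != image.shape:
            raise AlignmentError(
                f"mask shape {self.mask.shape} does not match slice shape {image.shape}"
            )


@dataclass
class SliceStack:
    """Three consecutive slices with muscle/fossa masks; the middle one holds the MRS voxel."""

    images: tuple[IntensitySlice, IntensitySlice, IntensitySlice]
    muscle_masks: tuple[RoiMask | None, RoiMask | None, RoiMask | None]
    fossa_masks: tuple[RoiMask | None, RoiMask | None, RoiMask | None]
    center_index: int = field(default=-1)
    subject_id: str = ""

    def __post_init__(self) -> None:
        if len(self.images) != 3 or len(self.muscle_masks) != 3 or len(self.fossa_masks) != 3:
            raise InputError("a slice stack holds exactly 3 images and 3 masks per region")
        idx = [im.slice_index for im in self.images]
        if idx[1] != idx[0] + 1 or idx[2] != idx[1] + 1:
            raise InputError(f"slice indices must be consecutive, got {idx}")
        if self.center_index == -1:
            self.center_index = idx[1]
        if self.center_index != idx[1]:
            raise InputError(
                f"center_index {self.center_index} is not the middle slice index {idx[1]}"
            )
        for masks in (self.muscle_masks, self.fossa_masks):
            for im, m in zip(self.images, masks):
                if m is not None:
                    m.check_aligned(im)
                    if m.slice_index != im.slice_index:
                        raise InputError(
                            f"mask slice_index {m.slice_index} != image slice_index {im.slice_index}"
                        )

    def masks_for(self, region_label: str) -> tuple[RoiMask, RoiMask, RoiMask]:
        if region_label not in REGION_LABELS:
            raise InputError(f"unknown region {region_label!r}")
        masks = self.muscle_masks if region_label == "muscle" else self.fossa_masks
        if any(m is None for m in masks):
            missing = [im.slice_index for im, m in zip(self.images, masks) if m is None]
            raise IncompleteStackError(
                f"missing {region_label} mask for slice index(es) {missing}"
            )
        return masks  # type: ignore[return-value]
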