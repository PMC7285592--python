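"""Seeded synthetic data: T1-like phantoms with exact fat-pixel truth,
perturbed observer masks, linked image+spectrum cohorts and fixture files.

The phantom emulates a sagittal-shoulder geometry: a rounded-triangle
"fossa" containing a concentric "muscle" region.  Fat appears as bright
streaks inside the muscle (fatty infiltration) and as the bright
extramuscular rim of the fossa (atrophy).  Truth records carry exact
integer pixel counts, so recovery tests against the generator are sharp.

All randomness flows through ``numpy.random.default_rng`` seeded from the
spec; identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from PIL import Image
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid
from scipy import ndimage

from .datamodel import IntensitySlice, RoiMask, SliceStack
from .errors import GenerationError, InputError
from .mrs import LIPID_PPM, WATER_PPM, Spectrum, gaussian

# class separation (mu_fat - mu_muscle) / sigma_noise = 8 by default:
# T1 fat/muscle contrast is high and this keeps recovery tolerances sharp
DEFAULT_MU_MUSCLE = 100.0
DEFAULT_MU_FAT = 180.0
DEFAULT_SIGMA_NOISE = 10.0

#: True muscle fat-fraction bands per Goutallier grade, following the
#: grade definitions (0: no visible fat ... 4: more than half fat).  Even
#: "no fat" muscle keeps a small bright fraction (perimysial fascia and
#: chemical-shift artifact look fat-bright on T1), which also keeps the ROI
#: histogram detectably bimodal -- Otsu has no meaningful threshold on an
#: effectively unimodal ROI.
GRADE_FAT_BANDS = (
    (0.015, 0.03),
    (0.03, 0.10),
    (0.10, 0.35),
    (0.35, 0.50),
    (0.50, 0.80),
)


@dataclass
class PhantomSpec:
    """Parameters of one synthetic T1-like slice phantom."""

    shape: tuple[int, int] = (96, 96)
    corner_radius: int = 8               # fossa rounded-triangle corner radius (px)
    margin: int = 6                      # fossa distance from the image border (px)
    muscle_occupation: float = 0.6       # muscle pixels / fossa pixels
    true_fat_fraction: float = 0.3       # fat proportion inside the muscle
    mu_muscle: float = DEFAULT_MU_MUSCLE
    mu_fat: float = DEFAULT_MU_FAT
    mu_background: float = 50.0
    sigma_noise: float = DEFAULT_SIGMA_NOISE
    noise_model: str = "gaussian"        # or "rician"
    streak_count: int = 200              # max streaks attempted
    streak_width: int = 3
    slice_index: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_fat_fraction <= 1.0:
            raise InputError("true_fat_fraction must be in [0, 1]")
        if self.mu_fat <= self.mu_muscle:
            raise InputError("mu_fat must exceed mu_muscle")
        if not 0.0 < self.muscle_occupation <= 1.0:
            raise InputError("muscle_occupation must be in (0, 1]")
        if self.sigma_noise < 0:
            raise InputError("sigma_noise must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise InputError(f"unknown noise model {self.noise_model!r}")


@dataclass(frozen=True)
class PhantomTruth:
    """Exact pixel-count ground truth of one phantom slice."""

    n_muscle: int
    n_fat_in_muscle: int
    n_fossa: int
    n_fat_in_fossa: int

    @property
    def muscle_fat_fraction(self) -> float:
        return 100.0 * self.n_fat_in_muscle / self.n_muscle

    @property
    def fossa_fat_fraction(self) -> float:
        return 100.0 * self.n_fat_in_fossa / self.n_fossa

    @property
    def occupation_ratio(self) -> float:
        return self.n_muscle / self.n_fossa


def _disk(radius: int) -> np.ndarray:
    r = int(radius)
    y, x = np.mgrid[-r:r + 1, -r:r + 1]
    return x**2 + y**2 <= r**2


def _fossa_mask(shape: tuple[int, int], corner_radius: int, margin: int) -> np.ndarray:
    """Rounded triangle: a shrunk triangle dilated by a disk."""
    rows, cols = shape
    r = corner_radius
    m = margin + r
    # apex up, base down, occupying the usable area
    verts = np.array([
        [cols / 2.0, m],
        [cols - 1.0 - m, rows - 1.0 - m],
        [m, rows - 1.0 - m],
    ])
    from .io import rasterize_polygon  # local import avoids a cycle at import time

    tri = rasterize_polygon(verts, shape)
    return ndimage.binary_dilation(tri, structure=_disk(r))


def _top_n_by_depth(region: np.ndarray, n: int) -> np.ndarray:
    """The n deepest pixels of a region (distance to its boundary), deterministic ties."""
    depth = ndimage.distance_transform_edt(region)
    rr, cc = np.nonzero(region)
    order = np.lexsort((cc, rr, -depth[rr, cc]))
    keep = order[:n]
    out = np.zeros_like(region)
    out[rr[keep], cc[keep]] = True
    return out


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[IntensitySlice, RoiMask, RoiMask, PhantomTruth]:
    """Build one phantom slice with exact fat-pixel truth.

    Exactly ``round(f * n_muscle)`` fat pixels are laid down as
    random-orientation streaks inside the muscle; the extramuscular fossa
    is filled at fat intensity (atrophy).  Raises
    :class:`~suprafat.errors.GenerationError` when the streak geometry
    cannot reach the requested fraction.
    """
    rng = np.random.default_rng(spec.seed)
    fossa = _fossa_mask(spec.shape, spec.corner_radius, spec.margin)
    n_fossa = int(fossa.sum())
    if n_fossa < 100:
        raise GenerationError("fossa too small; enlarge the shape or reduce margins")
    n_muscle = int(round(spec.muscle_occupation * n_fossa))
    muscle = _top_n_by_depth(fossa, n_muscle)

    target = int(round(spec.true_fat_fraction * n_muscle))
    fat = np.zeros(spec.shape, dtype=bool)
    if target > 0:
        mr, mc = np.nonzero(muscle)
        size = float(np.sqrt(n_muscle))
        stamp = _disk(max(spec.streak_width // 2, 0))
        placed: list[tuple[int, int]] = []
        attempts = 0
        while len(placed) < target:
            attempts += 1
            if attempts > spec.streak_count and len(placed) == 0:
                raise GenerationError(
                    "could not place fatty streaks; increase streak_count or muscle size"
                )
            if attempts > 50 * spec.streak_count:
                raise GenerationError(
                    f"streak geometry cannot reach fat fraction {spec.true_fat_fraction}"
                )
            i = rng.integers(len(mr))
            theta = rng.uniform(0, np.pi)
            length = rng.uniform(0.3, 0.8) * size
            t = np.arange(0.0, length, 0.5)
            ys = np.round(mr[i] + t * np.sin(theta)).astype(int)
            xs = np.round(mc[i] + t * np.cos(theta)).astype(int)
            streak = np.zeros(spec.shape, dtype=bool)
            ok = (ys >= 0) & (ys < spec.shape[0]) & (xs >= 0) & (xs < spec.shape[1])
            streak[ys[ok], xs[ok]] = True
            streak = ndimage.binary_dilation(streak, structure=stamp) & muscle & ~fat
            sr, sc = np.nonzero(streak)
            for y, x in zip(sr, sc):
                if len(placed) >= target:
                    break
                placed.append((y, x))
                fat[y, x] = True

    base = np.full(spec.shape, spec.mu_background, dtype=np.float64)
    base[fossa] = spec.mu_fat          # extramuscular fossa: fat (atrophy)
    base[muscle] = spec.mu_muscle
    base[fat] = spec.mu_fat

    if spec.sigma_noise > 0:
        if spec.noise_model == "gaussian":
            pixels = base + rng.normal(0.0, spec.sigma_noise, spec.shape)
        else:  # rician: magnitude of complex Gaussian noise around the signal
            n1 = rng.normal(0.0, spec.sigma_noise, spec.shape)
            n2 = rng.normal(0.0, spec.sigma_noise, spec.shape)
            pixels = np.sqrt((base + n1) ** 2 + n2**2)
    else:
        pixels = base

    image = IntensitySlice(pixels=pixels, slice_index=spec.slice_index,
                           source_id=f"phantom-seed{spec.seed}")
    truth = PhantomTruth(
        n_muscle=n_muscle,
        n_fat_in_muscle=int(fat.sum()),
        n_fossa=n_fossa,
        n_fat_in_fossa=int(fat.sum()) + (n_fossa - n_muscle),
    )
    return (
        image,
        RoiMask(muscle, "muscle", spec.slice_index, observer_id="truth"),
        RoiMask(fossa, "fossa", spec.slice_index, observer_id="truth"),
        truth,
    )


def perturb_mask(mask: RoiMask, delta: float, seed: int, observer_id: str = "") -> RoiMask:
    """Grow or shrink a mask boundary to change its area by a relative delta.

    Pixels are added (removed) from the boundary inward/outward in order of
    distance, with random tie-breaking, which mimics an observer drawing a
    slightly looser or tighter contour while preserving connectedness.
    """
    if not -0.25 < delta < 0.25:
        raise InputError(f"delta must be in (-0.25, 0.25), got {delta}")
    n = mask.pixel_count
    target = int(round((1.0 + delta) * n))
    if target < 1:
        raise GenerationError("perturbation would empty the mask")
    rng = np.random.default_rng(seed)
    m = mask.mask.copy()
    if target > n:
        add = target - n
        dist = ndimage.distance_transform_edt(~m)
        rr, cc = np.nonzero(~m)
        if len(rr) < add:
            raise GenerationError("not enough room to grow the mask")
        order = np.lexsort((rng.random(len(rr)), dist[rr, cc]))
        chosen = order[:add]
        m[rr[chosen], cc[chosen]] = True
    elif target < n:
        remove = n - target
        dist = ndimage.distance_transform_edt(m)
        rr, cc = np.nonzero(m)
        order = np.lexsort((rng.random(len(rr)), dist[rr, cc]))
        chosen = order[:remove]
        m[rr[chosen], cc[chosen]] = False
    return RoiMask(m, mask.region_label, mask.slice_index,
                   observer_id=observer_id or f"perturbed{delta:+.3f}")


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def generate_spectrum(
    fat_water_ratio: float,
    amplitude_water: float = 1.0,
    noise_sigma: float = 0.0,
    baseline: float = 0.05,
    sigma_water: float = 0.12,
    sigma_lipid: float = 0.15,
    n_points: int = 512,
    ppm_range: tuple[float, float] = (0.0, 6.0),
    seed: int = 0,
    subject_id: str = "",
) -> Spectrum:
    """Water + lipid Gaussian peaks on a flat baseline with optional noise."""
    if fat_water_ratio < 0:
        raise InputError("fat_water_ratio must be >= 0")
    rng = np.random.default_rng(seed)
    ppm = np.linspace(*ppm_range, n_points)
    mag = (
        baseline
        + gaussian(ppm, amplitude_water, WATER_PPM, sigma_water)
        + gaussian(ppm, fat_water_ratio * amplitude_water, LIPID_PPM, sigma_lipid)
    )
    if noise_sigma > 0:
        mag = mag + rng.normal(0.0, noise_sigma, n_points)
    return Spectrum(ppm=ppm, magnitude=np.clip(mag, 0.0, None),
                    subject_id=subject_id)


# ---------------------------------------------------------------------------
# linked cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Parameters of a simulated study cohort with paired image + MRS data."""

    n_subjects: int = 38
    grade_mix: tuple[float, ...] = (0.08, 0.16, 0.45, 0.13, 0.18)
    grade_fat_bands: tuple[tuple[float, float], ...] = GRADE_FAT_BANDS
    link_slope: float = 2.0              # true MRS ratio = slope * fat fraction
    link_noise_sd: float = 0.03          # SD of the ratio around the link
    spectrum_noise_sigma: float = 0.005  # additive spectral noise (water amp = 1)
    image_noise_sigma: float = DEFAULT_SIGMA_NOISE
    observer_count: int = 4
    area_delta_range: tuple[float, float] = (0.02, 0.05)
    phantom_shape: tuple[int, int] = (96, 96)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.grade_mix) - 1.0) > 1e-9:
            raise InputError("grade_mix must sum to 1")
        lo, hi = self.area_delta_range
        if not 0.0 <= lo <= hi <= 0.25:
            raise InputError("area_delta_range must lie within [0, 0.25]")
        if self.n_subjects < 1 or self.observer_count < 1:
            raise InputError("need at least one subject and one observer")


@dataclass
class CohortSubject:
    subject_id: str
    grade: int
    stack: SliceStack
    spectrum: Spectrum
    truth: dict
    observer_masks: dict[str, tuple[RoiMask, RoiMask]] = field(default_factory=dict)


def apportion(n: int, proportions: tuple[float, ...]) -> tuple[int, ...]:
    """Largest-remainder apportionment of n items over proportions."""
    raw = np.asarray(proportions, dtype=float) * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    if remainder > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:remainder]] += 1
    return tuple(int(c) for c in counts)


def generate_linked_cohort(spec: CohortSpec) -> list[CohortSubject]:
    """Simulate subjects whose true MRS ratio is a linear function of their
    true muscle fat fraction, with three phantom slices and perturbed
    observer masks per subject."""
    rng = np.random.default_rng(spec.seed)
    counts = apportion(spec.n_subjects, spec.grade_mix)
    subjects: list[CohortSubject] = []
    sid = 0
    for grade, count in enumerate(counts):
        lo, hi = spec.grade_fat_bands[grade]
        for _ in range(count):
            sid += 1
            f = float(rng.uniform(lo, hi))
            images, muscles, fossae = [], [], []
            truth_fracs = []
            for offset in (-1, 0, 1):
                pspec = PhantomSpec(
                    shape=spec.phantom_shape,
                    true_fat_fraction=f,
                    sigma_noise=spec.image_noise_sigma,
                    slice_index=10 + offset,
                    seed=int(rng.integers(2**31)),
                )
                img, mus, fos, truth = generate_phantom(pspec)
                images.append(img)
                muscles.append(mus)
                fossae.append(fos)
                truth_fracs.append(truth.muscle_fat_fraction)
                if offset == 0:
                    center_truth = truth
            stack = SliceStack(tuple(images), tuple(muscles), tuple(fossae),
                               subject_id=f"subj{sid:03d}")

            ratio_true = spec.link_slope * f
            if spec.link_noise_sd > 0:
                ratio_true = max(ratio_true + rng.normal(0.0, spec.link_noise_sd), 0.0)
            spectrum = generate_spectrum(
                ratio_true,
                noise_sigma=spec.spectrum_noise_sigma,
                seed=int(rng.integers(2**31)),
                subject_id=stack.subject_id,
            )

            observer_masks: dict[str, tuple[RoiMask, RoiMask]] = {
                "obs0": (muscles[1], fossae[1])
            }
            for obs in range(1, spec.observer_count):
                delta = float(rng.uniform(*spec.area_delta_range))
                delta *= rng.choice((-1.0, 1.0))
                observer_masks[f"obs{obs}"] = (
                    perturb_mask(muscles[1], delta, int(rng.integers(2**31)), f"obs{obs}"),
                    perturb_mask(fossae[1], delta, int(rng.integers(2**31)), f"obs{obs}"),
                )

            subjects.append(CohortSubject(
                subject_id=stack.subject_id,
                grade=grade,
                stack=stack,
                spectrum=spectrum,
                truth={
                    "grade": grade,
                    "true_fat_fraction": f,
                    "true_muscle_fraction_percent": float(np.mean(truth_fracs)),
                    "true_fossa_fraction_percent": center_truth.fossa_fat_fraction,
                    "true_mrs_ratio": ratio_true,
                    "occupation_ratio": center_truth.occupation_ratio,
                },
                observer_masks=observer_masks,
            ))
    return subjects


def cohort_truth_table(subjects: list[CohortSubject]):
    import pandas as pd

    return pd.DataFrame(
        [{"subject_id": s.subject_id, **s.truth} for s in subjects]
    ).set_index("subject_id")


# ---------------------------------------------------------------------------
# fixture files
# ---------------------------------------------------------------------------

def write_fixture_dicom(image: IntensitySlice, path: str | Path,
                        bits: int = 16) -> None:
    """Write a minimal single-frame secondary-capture DICOM that round-trips.

    Intensities are quantized to unsigned ``bits``-bit stored values with
    rescale slope/intercept mapping back to physical units; the worst-case
    round-trip error is half of one stored-value step.
    """
    arr = image.pixels
    lo, hi = float(arr.min()), float(arr.max())
    levels = (1 << bits) - 1
    slope = (hi - lo) / levels if hi > lo else 1.0
    stored = np.round((arr - lo) / slope).astype("<u2")

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.Rows, ds.Columns = arr.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = bits
    ds.HighBit = bits - 1
    ds.PixelRepresentation = 0
    ds.RescaleSlope = f"{slope:.10g}"
    ds.RescaleIntercept = f"{lo:.10g}"
    ds.PixelSpacing = [f"{image.pixel_spacing_mm[0]:.6g}",
                       f"{image.pixel_spacing_mm[1]:.6g}"]
    ds.InstanceNumber = image.slice_index
    ds.PixelData = stored.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def write_mask_png(mask: RoiMask, path: str | Path) -> None:
    Image.fromarray((mask.mask * np.uint8(255))).save(str(path))
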