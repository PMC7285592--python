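"""Clustering-based (Otsu) threshold selection on ROI intensity histograms.

The threshold is the histogram cut maximizing the between-class variance

    sigma2_B(t) = omega0(t) * omega1(t) * (mu0(t) - mu1(t))**2

where ``omega`` are the class probabilities and ``mu`` the class means of
the two intensity clusters split at ``t``.  On T1-weighted images fat is
hyperintense, so the bright class above the threshold is read as fat.

The histogram is built over the ROI's own min-max intensity range (per-ROI,
per-slice threshold), not over the whole image and not over the DICOM bit
depth: the threshold adapts to the local contrast of the segmented area.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .datamodel import DEFAULT_MIN_ROI_PIXELS, IntensitySlice, RoiMask
from .errors import DegenerateRoiError, InputError

log = logging.getLogger(__name__)

DEFAULT_N_BINS = 256


@dataclass(frozen=True)
class Histogram:
    """Intensity histogram over an ROI; rightmost bin closed."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_pixels: int
    degenerate_span: bool = False

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class ThresholdResult:
    """Otsu threshold with the class statistics at the maximizing cut."""

    threshold: float
    omega0: float
    omega1: float
    mu0: float
    mu1: float
    between_class_variance: float
    degenerate: bool = False


def compute_histogram(pixels, n_bins: int = DEFAULT_N_BINS,
                      min_roi_pixels: int = DEFAULT_MIN_ROI_PIXELS) -> Histogram:
    """Histogram of ROI intensities over their min-max span.

    A constant input yields a single-bin histogram flagged
    ``degenerate_span`` rather than an error, so downstream code can report
    a zero fat fraction for contrast-free ROIs.
    """
    values = np.asarray(pixels, dtype=np.float64).ravel()
    if values.size < min_roi_pixels:
        raise DegenerateRoiError(
            f"ROI has {values.size} pixels; at least {min_roi_pixels} required"
        )
    if not np.all(np.isfinite(values)):
        raise InputError("non-finite intensities in ROI")
    if n_bins < 2:
        raise InputError(f"n_bins must be >= 2, got {n_bins}")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        return Histogram(
            bin_edges=np.array([lo, hi]),
            counts=np.array([values.size]),
            n_pixels=values.size,
            degenerate_span=True,
        )
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    return Histogram(bin_edges=edges, counts=counts, n_pixels=values.size)


def otsu_threshold(hist: Histogram) -> ThresholdResult:
    """Between-class-variance-maximizing cut over all interior bin edges.

    Class statistics are computed from bin centers.  Candidate cut at edge
    ``k`` assigns bins ``0..k-1`` to the dark class and ``k..`` to the
    bright class; ties are broken toward the lowest threshold.
    """
    if hist.degenerate_span or hist.n_bins < 2:
        return ThresholdResult(
            threshold=float(hist.bin_edges[-1]),
            omega0=1.0, omega1=0.0, mu0=float(hist.bin_edges[-1]),
            mu1=float(hist.bin_edges[-1]), between_class_variance=0.0,
            degenerate=True,
        )

    counts = hist.counts.astype(np.float64)
    total = counts.sum()
    w = counts / total
    centers = hist.bin_centers

    # cumulative class probability / mean below each interior edge
    cw = np.cumsum(w)                      # omega0 at cut after bin i
    cm = np.cumsum(w * centers)            # unnormalized first moment
    grand = cm[-1]

    omega0 = cw[:-1]
    omega1 = 1.0 - omega0
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = cm[:-1] / omega0
        mu1 = (grand - cm[:-1]) / omega1
    valid = (omega0 > 0) & (omega1 > 0)
    sigma2 = np.zeros_like(omega0)
    sigma2[valid] = omega0[valid] * omega1[valid] * (mu0[valid] - mu1[valid]) ** 2

    if not np.any(valid) or sigma2.max() <= 0.0:
        return ThresholdResult(
            threshold=float(hist.bin_edges[-1]),
            omega0=1.0, omega1=0.0, mu0=grand, mu1=grand,
            between_class_variance=0.0, degenerate=True,
        )

    best = int(np.argmax(sigma2))  # argmax returns the first (lowest-t) maximizer
    return ThresholdResult(
        threshold=float(hist.bin_edges[best + 1]),
        omega0=float(omega0[best]),
        omega1=float(omega1[best]),
        mu0=float(mu0[best]),
        mu1=float(mu1[best]),
        between_class_variance=float(sigma2[best]),
    )


def binarize(image: IntensitySlice, mask: RoiMask, threshold: float) -> tuple[int, int]:
    """Split masked pixels into (N_fg, N_bg): strictly above vs at-or-below threshold."""
    mask.check_aligned(image)
    values = image.pixels[mask.mask]
    n_fg = int(np.count_nonzero(values > threshold))
    return n_fg, values.size - n_fg


class OtsuThresholder(BaseEstimator):
    """Otsu threshold selection as a scikit-learn style estimator.

    Parameters
    ----------
    n_bins : int, default 256
        Number of histogram bins over the min-max span of the fitted values.
    min_roi_pixels : int, default 25
        Minimum number of intensities required to fit.

    Attributes
    ----------
    histogram_ : Histogram
    result_ : ThresholdResult
    threshold_ : float
        Pixels strictly above this value are classified as bright (fat).
    degenerate_ : bool
        True when the fitted values had no contrast (constant ROI).
    """

    def __init__(self, n_bins: int = DEFAULT_N_BINS,
                 min_roi_pixels: int = DEFAULT_MIN_ROI_PIXELS):
        self.n_bins = n_bins
        self.min_roi_pixels = min_roi_pixels

    def fit(self, X, y=None) -> "OtsuThresholder":
        self.histogram_ = compute_histogram(X, self.n_bins, self.min_roi_pixels)
        self.result_ = otsu_threshold(self.histogram_)
        self.threshold_ = self.result_.threshold
        self.degenerate_ = self.result_.degenerate
        if self.degenerate_:
            log.warning("degenerate (contrast-free) ROI: threshold set to max intensity")
        return self

    def predict(self, X) -> np.ndarray:
        """Boolean fat labels: True where intensity > fitted threshold."""
        check_is_fitted(self, "threshold_")
        values = np.asarray(X, dtype=np.float64)
        if self.degenerate_:
            return np.zeros(values.shape, dtype=bool)
        return values > self.threshold_

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).predict(X)
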