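"""Reliability and group-comparison statistics for the validation study.

Covers inter-observer reliability (ICC with 95% CI, coefficient of
variation), one-way ANOVA with Tukey HSD post hoc comparisons across
Goutallier grade groups, Pearson correlation against the MRS reference,
and post-hoc power computed from published group summaries (means, 95%
CIs and group sizes) when raw per-patient data are unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError, UndefinedStatisticError

DEFAULT_ALPHA = 0.05

# smallest positive float: the "p < machine precision" boundary value
_P_FLOOR = float(np.nextafter(0.0, 1.0))


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class RatingsMatrix:
    """Subjects x observers grid of measurements (fractions, areas or grades)."""

    values: np.ndarray
    subject_ids: tuple[str, ...] = ()
    observer_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise InputError("ratings must be a 2D subjects x observers grid")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise InputError(f"need >= 2 subjects and >= 2 observers, got {n} x {k}")
        if not np.all(np.isfinite(self.values)):
            raise InputError("ratings contain missing or non-finite cells")
        if not self.subject_ids:
            self.subject_ids = tuple(f"s{i}" for i in range(n))
        if not self.observer_ids:
            self.observer_ids = tuple(f"o{j}" for j in range(k))
        if len(self.subject_ids) != n or len(self.observer_ids) != k:
            raise InputError("id lists do not match the grid shape")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RatingsMatrix":
        """Wide DataFrame: index = subjects, columns = observers."""
        return cls(df.to_numpy(dtype=float),
                   tuple(map(str, df.index)), tuple(map(str, df.columns)))

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_observers(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    model_label: str
    mean_squares: tuple[float, float, float]  # (MSR, MSC, MSE)


@dataclass(frozen=True)
class GradeGroupSummary:
    """Per-grade group sizes with measurement means and 95% CIs."""

    grades: tuple[int, ...]
    n: tuple[int, ...]
    mean: tuple[float, ...]
    ci_low: tuple[float, ...]
    ci_high: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        lengths = {len(self.grades), len(self.n), len(self.mean),
                   len(self.ci_low), len(self.ci_high)}
        if len(lengths) != 1:
            raise InputError("summary fields must have equal length")
        for m, lo, hi in zip(self.mean, self.ci_low, self.ci_high):
            if not lo <= m <= hi:
                raise InputError(f"mean {m} outside its CI ({lo}, {hi})")


@dataclass(frozen=True)
class PowerResult:
    test_label: str
    alpha: float
    power: float
    effect: float  # noncentrality parameter or effect size used


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------

def icc(m: RatingsMatrix, alpha: float = DEFAULT_ALPHA, average: bool = False) -> IccResult:
    """Two-way random-effects, absolute-agreement intraclass correlation.

    Default is the single-measurement form ICC(2,1), the conservative
    convention for radiology reliability studies; ``average=True`` gives
    the k-rater average form ICC(2,k).  The confidence interval follows
    the Shrout-Fleiss F-based construction.
    """
    x = m.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)

    ss_total = ((x - grand) ** 2).sum()
    if ss_total <= 0:
        raise UndefinedStatisticError("zero total variance: ICC undefined")
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)

    denom_single = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom_single == 0:
        raise UndefinedStatisticError("degenerate mean squares: ICC undefined")
    icc21 = (msr - mse) / denom_single

    # Satterthwaite df for the MSC/MSE mixture
    a = (k * icc21) / (n * (1 - icc21)) if icc21 < 1 else np.inf
    b = 1 + (k * icc21 * (n - 1)) / (n * (1 - icc21)) if icc21 < 1 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
    else:
        v = (n - 1) * (k - 1)

    if mse > 0 and np.isfinite(v):
        f_low = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_up = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_low * mse) / (
            f_low * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f_up * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_up * msr
        )
    else:  # perfect agreement
        lower = upper = icc21

    if average:
        def to_avg(r: float) -> float:
            return k * r / (1 + (k - 1) * r) if (1 + (k - 1) * r) != 0 else 1.0
        return IccResult(to_avg(icc21), to_avg(lower), to_avg(upper),
                         f"ICC(2,{k})", (msr, msc, mse))
    return IccResult(float(icc21), float(min(lower, icc21)), float(max(upper, icc21)),
                     "ICC(2,1)", (msr, msc, mse))


def cv_across_observers(m: RatingsMatrix) -> pd.DataFrame:
    """Per-subject coefficient of variation (%) across observers.

    CV_i = 100 * sd_i / mean_i with the sample (n-1) standard deviation.
    Returns a DataFrame indexed by subject with a ``cv_percent`` column;
    the summary (mean and range) is in ``df.attrs``.
    """
    if np.any(m.values <= 0):
        raise UndefinedStatisticError("CV requires strictly positive measurements")
    means = m.values.mean(axis=1)
    sds = m.values.std(axis=1, ddof=1)
    cv = 100.0 * sds / means
    df = pd.DataFrame({"cv_percent": cv}, index=list(m.subject_ids))
    df.attrs["mean_cv"] = float(cv.mean())
    df.attrs["range"] = (float(cv.min()), float(cv.max()))
    return df


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def _check_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(gs) < 2:
        raise InputError("need at least 2 groups")
    if any(g.size < 1 for g in gs):
        raise InputError("every group needs at least one observation")
    if sum(g.size for g in gs) <= len(gs):
        raise InputError("total N must exceed the number of groups")
    return gs


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, int, int, float]:
    """One-way fixed-effects ANOVA: returns (F, df_between, df_within, p).

    The zero-within-variance boundary with unequal means reports F = inf
    and p at the smallest positive float rather than NaN.
    """
    gs = _check_groups(groups)
    k = len(gs)
    n_total = sum(g.size for g in gs)
    grand = np.concatenate(gs).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df1, df2 = k - 1, n_total - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, df1, df2, 1.0
        return float("inf"), df1, df2, _P_FLOOR
    f_stat = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(f_stat, df1, df2))
    return float(f_stat), df1, df2, p


def tukey_hsd(groups: Sequence[Sequence[float]],
              labels: Sequence[str] | None = None) -> pd.DataFrame:
    """All-pairs Tukey HSD table with Tukey-Kramer errors for unequal n.

    Columns: group_a, group_b, mean_diff, se, q, p_adj.  The adjusted p is
    the survival function of the studentized range distribution with
    parameters (k, N - k) at the observed q.
    """
    gs = _check_groups(groups)
    k = len(gs)
    n_total = sum(g.size for g in gs)
    df_within = n_total - k
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    mse = ss_within / df_within
    if labels is None:
        labels = [f"g{i}" for i in range(k)]

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = gs[i].mean() - gs[j].mean()
            if mse == 0.0:
                q = 0.0 if diff == 0 else float("inf")
                p = 1.0 if diff == 0 else _P_FLOOR
                se = 0.0
            else:
                se = np.sqrt(mse / 2 * (1 / gs[i].size + 1 / gs[j].size))
                q = abs(diff) / se
                p = float(sps.studentized_range.sf(q, k, df_within))
            rows.append({"group_a": labels[i], "group_b": labels[j],
                         "mean_diff": float(diff), "se": float(se),
                         "q": float(q), "p_adj": min(max(p, 0.0), 1.0)})
    return pd.DataFrame(rows)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Pearson product-moment correlation: returns (R, R^2, p)."""
    xa = np.asarray(x, dtype=np.float64)
    ya = np.asarray(y, dtype=np.float64)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise InputError("x and y must be equal-length 1D vectors")
    if xa.size < 3:
        raise InputError("need at least 3 points")
    if xa.std() == 0 or ya.std() == 0:
        raise UndefinedStatisticError("zero variance: correlation undefined")
    r, p = sps.pearsonr(xa, ya)
    return float(r), float(r * r), float(p)


# ---------------------------------------------------------------------------
# post-hoc power from published summaries
# ---------------------------------------------------------------------------

def sd_from_ci(mean: float, ci_low: float, ci_high: float, n: int,
               alpha: float = DEFAULT_ALPHA) -> float:
    """Back-derive a group SD from a t-based two-sided CI on the mean."""
    if n < 2:
        raise InputError("need n >= 2 to recover an SD from a CI")
    halfwidth = (ci_high - ci_low) / 2.0
    if halfwidth < 0:
        raise InputError("CI upper bound below lower bound")
    t_crit = sps.t.ppf(1 - alpha / 2, n - 1)
    return halfwidth * np.sqrt(n) / t_crit


def anova_power_from_summary(summary: GradeGroupSummary,
                             alpha: float = DEFAULT_ALPHA) -> PowerResult:
    """Post-hoc one-way ANOVA power from group means, 95% CIs and sizes.

    Group SDs are recovered by inverting the t-based CI; the noncentrality
    is lambda = sum n_g (mean_g - grand)^2 / pooled within-variance, and
    power = P(F'(k-1, N-k, lambda) > F_crit) under the noncentral F.
    """
    n = np.asarray(summary.n, dtype=np.int64)
    means = np.asarray(summary.mean, dtype=np.float64)
    if np.any(n < 2):
        raise InputError("every group needs n >= 2 for SD back-derivation")
    k = len(n)
    if k < 2:
        raise InputError("need at least 2 groups")
    sds = np.array([
        sd_from_ci(m, lo, hi, ni, alpha)
        for m, lo, hi, ni in zip(summary.mean, summary.ci_low, summary.ci_high, n)
    ])
    pooled_var = float(((n - 1) * sds**2).sum() / (n - 1).sum())
    if pooled_var <= 0:
        raise UndefinedStatisticError("zero pooled within-group variance")
    n_total = int(n.sum())
    grand = float((n * means).sum() / n_total)
    lam = float((n * (means - grand) ** 2).sum() / pooled_var)
    df1, df2 = k - 1, n_total - k
    f_crit = sps.f.ppf(1 - alpha, df1, df2)
    power = float(sps.ncf.sf(f_crit, df1, df2, lam)) if lam > 0 else alpha
    return PowerResult(f"one-way ANOVA ({summary.label or 'summary'})",
                       alpha, power, lam)


def correlation_power(r: float, n: int, alpha: float = DEFAULT_ALPHA) -> PowerResult:
    """Post-hoc power of the two-sided Pearson test via the Fisher z approximation."""
    if not abs(r) < 1:
        raise InputError(f"|r| must be < 1, got {r}")
    if n < 4:
        raise InputError("need n >= 4")
    z_crit = sps.norm.ppf(1 - alpha / 2)
    shift = np.sqrt(n - 3) * np.arctanh(r)
    power = float(sps.norm.cdf(shift - z_crit) + sps.norm.cdf(-shift - z_crit))
    return PowerResult("Pearson correlation", alpha, power, float(r))
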