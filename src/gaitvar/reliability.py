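"""Reliability statistics: ICC(2,1), convergence profiles, stride-count
requirement and the 2.6% CoV cut-off.

Two complementary views of "how many strides are enough":

* consistency of a parameter across the straight-walking segments of a
  single trial, measured with the intraclass correlation from a two-way
  random-effects ANOVA in its single-measure form, ICC(2,1), treating
  segments as repeated measurements;
* convergence of the cumulative statistic: across subjects, the Pearson
  correlation between the value at n strides and the value at the final
  reference stride count, with the smallest n achieving R > 0.8 taken as
  the required stride count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .metrics import CumulativeSeries, UndefinedStatisticError

# Interpretation bands for ICC
POOR = "poor"
FAIR_TO_GOOD = "fair_to_good"
EXCELLENT = "excellent"


def icc_band(icc: float) -> str:
    """Map an ICC to its interpretation band.

    Below 0.4 is poor; 0.4 through 0.8 (both ends inclusive) fair to
    good; above 0.8 excellent.
    """
    if icc < 0.4:
        return POOR
    if icc <= 0.8:
        return FAIR_TO_GOOD
    return EXCELLENT


@dataclass
class ICCResult:
    icc: float
    n_subjects: int
    k_segments: int
    ms_rows: float   # between-subject mean square
    ms_cols: float   # between-segment mean square
    ms_error: float  # residual mean square

    @property
    def band(self) -> str:
        return icc_band(self.icc)


def icc_two_way_random_single(matrix) -> ICCResult:
    """ICC(2,1): two-way random-effects, absolute-agreement, single measure.

    ``matrix`` is subjects x segments with no missing cells (drop
    incomplete subjects first).  From the two-way ANOVA decomposition with
    n subjects and k segments::

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    where MSR, MSC and MSE are the row (subject), column (segment) and
    residual mean squares.  The mean squares are returned for audit.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be 2-D (subjects x segments)")
    if np.isnan(x).any():
        raise ValueError("missing cells: drop incomplete subjects first")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 segments")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    if ss_total == 0:
        raise UndefinedStatisticError("zero total variance: ICC undefined")
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return ICCResult(icc=float(icc), n_subjects=n, k_segments=k,
                     ms_rows=float(msr), ms_cols=float(msc),
                     ms_error=float(mse))


@dataclass
class ConvergenceResult:
    """Pearson R between the cumulative statistic at n strides and at the
    final reference count, per n, across subjects."""

    parameter: str
    statistic: str
    n_values: np.ndarray
    r_by_n: np.ndarray

    def r_at(self, n: int) -> float:
        k = int(np.searchsorted(self.n_values, n))
        if k >= len(self.n_values) or self.n_values[k] != n:
            raise KeyError(f"n={n} not in profile")
        return float(self.r_by_n[k])


def convergence_profile(series: list[CumulativeSeries],
                        statistic: str) -> ConvergenceResult:
    """Correlate each subject's cumulative value at n with their final value.

    All subjects must share the same n-grid.  At ``n = n_max`` the
    correlation is the statistic with itself and is set to exactly 1.
    Intermediate n with zero cross-subject variance yield NaN (they can
    never satisfy a threshold criterion).
    """
    if len(series) < 3:
        raise ValueError("need >= 3 subjects")
    if statistic not in ("cum_mean", "cum_cov"):
        raise ValueError("statistic must be 'cum_mean' or 'cum_cov'")
    grid = series[0].n_values
    for s in series[1:]:
        if not np.array_equal(s.n_values, grid):
            raise ValueError("subjects must share the same n_min/n_max grid")
    mat = np.vstack([getattr(s, statistic) for s in series])  # subjects x n
    final = mat[:, -1]
    if final.std() == 0:
        raise UndefinedStatisticError(
            "zero cross-subject variance at the reference stride count")
    r = np.empty(mat.shape[1])
    fc = final - final.mean()
    fnorm = np.sqrt((fc**2).sum())
    for j in range(mat.shape[1]):
        col = mat[:, j] - mat[:, j].mean()
        denom = np.sqrt((col**2).sum()) * fnorm
        r[j] = np.nan if denom == 0 else float((col * fc).sum() / denom)
    r[-1] = 1.0
    return ConvergenceResult(parameter=series[0].parameter,
                             statistic=statistic, n_values=grid.copy(),
                             r_by_n=r)


def required_stride_count(result: ConvergenceResult, threshold: float = 0.8,
                          sustained: bool = False) -> Optional[int]:
    """Smallest stride count n with R > threshold.

    By default the first crossing counts even if R dips below the
    threshold at a later n; with ``sustained=True`` the smallest n from
    which R stays above the threshold through n_max is returned instead.
    Since R at n_max is 1 by construction, a result always exists for
    thresholds below 1.
    """
    above = result.r_by_n > threshold
    if sustained:
        # last index where the criterion fails, then the next n
        failing = np.nonzero(~above)[0]
        if len(failing) == 0:
            return int(result.n_values[0])
        k = failing[-1] + 1
        return int(result.n_values[k]) if k < len(above) else None
    hits = np.nonzero(above)[0]
    return int(result.n_values[hits[0]]) if len(hits) else None


def classify_above_cutoff(cov_values, cutoff: float = 2.6) -> tuple[int, float]:
    """Count and fraction of subjects with CoV strictly above the cut-off.

    The default 2.6% is the literature-proposed upper limit of
    physiological stride-time CoV; values above it are classed as
    increased variability.
    """
    v = np.asarray(cov_values, dtype=float)
    if v.size == 0:
        return 0, 0.0
    n_above = int((v > cutoff).sum())
    return n_above, n_above / v.size
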