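"""Descriptive variability metrics.

The central quantity is the coefficient of variation,
``CoV = (SD / mean) x 100`` with the sample SD (n-1 denominator), applied
to stride length and stride time.  Cumulative series track how the mean
and CoV of the first *n* strides evolve with n; per-segment statistics
quantify consistency across the straight-walking bouts between turns;
peri-turn normalization expresses turn-adjacent strides as a percentage of
the subject's own reference mean.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .turns import PeriTurnSet, SegmentedTrial

logger = logging.getLogger(__name__)


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is requested on degenerate input."""


def coefficient_of_variation(values) -> float:
    """CoV in percent: sample SD over mean, times 100.

    Requires at least two values and a positive mean.  Scale-invariant:
    multiplying every value by a positive constant leaves the CoV
    unchanged.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise UndefinedStatisticError("CoV needs at least 2 values")
    mean = v.mean()
    if mean <= 0:
        raise UndefinedStatisticError("CoV undefined for non-positive mean")
    return float(v.std(ddof=1) / mean * 100.0)


@dataclass
class CumulativeSeries:
    """Per-n cumulative mean and CoV of the first n strides, n in [n_min, n_max].

    Stride counts are 1-based: ``cum_mean[k]`` covers the first
    ``n_values[k]`` strides.  At ``n = n_max`` the cumulative CoV equals
    the whole-window CoV exactly.
    """

    parameter: str
    n_values: np.ndarray
    cum_mean: np.ndarray
    cum_cov: np.ndarray

    def at(self, n: int, statistic: str) -> float:
        k = int(np.searchsorted(self.n_values, n))
        if k >= len(self.n_values) or self.n_values[k] != n:
            raise KeyError(f"n={n} not in series")
        return float({"cum_mean": self.cum_mean,
                      "cum_cov": self.cum_cov}[statistic][k])


def cumulative_series(values, n_max: int, n_min: int = 3,
                      parameter: str = "") -> CumulativeSeries:
    """Cumulative mean and CoV over the first n strides for n = n_min..n_max.

    The window starts at 3 strides because a CoV over fewer is
    meaningless.  Callers enforce the analysis reference (40 strides with
    the standard excision, 32 with the generous one).
    """
    v = np.asarray(values, dtype=float)
    if n_min < 2:
        raise ValueError("n_min must be >= 2")
    if n_max < n_min:
        raise ValueError("n_max must be >= n_min")
    if v.size < n_max:
        raise ValueError(f"need at least n_max={n_max} values, got {v.size}")
    ns = np.arange(n_min, n_max + 1)
    # running first/second moments; sample SD via the n-1 correction
    csum = np.cumsum(v)
    csum2 = np.cumsum(v * v)
    means = csum[ns - 1] / ns
    var = (csum2[ns - 1] - ns * means**2) / (ns - 1)
    var = np.maximum(var, 0.0)  # guard float cancellation
    covs = np.sqrt(var) / means * 100.0
    # recompute the endpoint directly so it matches the whole-window CoV
    # to the last bit
    covs[-1] = coefficient_of_variation(v[:n_max])
    means[-1] = v[:n_max].mean()
    return CumulativeSeries(parameter=parameter, n_values=ns,
                            cum_mean=means, cum_cov=covs)


@dataclass
class SegmentStats:
    """Mean and CoV per straight segment, plus the spread of segment CoVs."""

    parameter: str
    seg_means: list[float]
    seg_covs: list[float]

    @property
    def cov_range(self) -> float:
        """max - min of the segment CoVs (absolute difference across
        segments; small ranges indicate stable within-subject variability
        even when ICC is low)."""
        return float(max(self.seg_covs) - min(self.seg_covs))


def per_segment_stats(seg: SegmentedTrial, parameter: str,
                      min_len: int = 3) -> SegmentStats:
    """Mean and CoV of each segment; segments shorter than ``min_len``
    strides are skipped with a warning."""
    means, covs = [], []
    for k, indices in enumerate(seg.segments):
        if len(indices) < min_len:
            logger.warning("%s: segment %d has %d strides (<%d); skipped",
                           seg.trial.subject_id, k, len(indices), min_len)
            continue
        vals = [getattr(seg.trial.records[i],
                        "length_pct_stature" if parameter == "SL" else "time_s")
                for i in indices]
        means.append(float(np.mean(vals)))
        covs.append(coefficient_of_variation(vals))
    if not covs:
        raise UndefinedStatisticError("all segments too short")
    return SegmentStats(parameter=parameter, seg_means=means, seg_covs=covs)


def normalize_periturn(periturn: PeriTurnSet, parameter: str) -> dict[str, np.ndarray]:
    """Peri-turn strides as percent of the subject's reference mean.

    The reference is the mean over the subject's first analyzed strides
    (the same 40- or 32-stride window the cumulative statistics use); a
    stride exactly at the reference maps to 100%.
    """
    ref = periturn.ref_mean_sl if parameter == "SL" else periturn.ref_mean_st
    if not ref > 0:
        raise UndefinedStatisticError("reference mean must be positive")
    attr = "length_pct_stature" if parameter == "SL" else "time_s"
    return {
        "before": np.array([100.0 * getattr(r, attr) / ref
                            for r in periturn.before]),
        "after": np.array([100.0 * getattr(r, attr) / ref
                           for r in periturn.after]),
    }


@dataclass
class PairedTestResult:
    t: float
    df: int
    p: float


def paired_t_test(differences) -> PairedTestResult:
    """Paired t-test on a vector of differences.

    ``t = mean(d) / (SD(d)/sqrt(n))`` with ``df = n - 1`` and a two-sided
    p-value from Student's t.  Degenerate (zero-variance) differences
    raise rather than returning an infinite statistic.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise UndefinedStatisticError("paired t-test needs >= 2 differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise UndefinedStatisticError("zero-variance differences: t undefined")
    n = d.size
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return PairedTestResult(t=float(t), df=n - 1, p=float(p))


@dataclass
class PeriTurnComparison:
    """Pooled peri-turn contrast for one (side, parameter) pair: mean
    relative value (% of individual reference) and the paired t-test of
    the relative values against 100%."""

    side: str
    parameter: str
    n: int
    mean_relative_pct: float
    test: PairedTestResult


def compare_periturn(periturn_sets: list[PeriTurnSet], side: str,
                     parameter: str) -> PeriTurnComparison:
    """Pool normalized peri-turn strides across subjects and test whether
    they differ from the individual averages (relative value != 100%)."""
    rel = np.concatenate([normalize_periturn(ps, parameter)[side]
                          for ps in periturn_sets]) if periturn_sets else np.array([])
    if rel.size < 2:
        raise UndefinedStatisticError("too few pooled peri-turn strides")
    return PeriTurnComparison(side=side, parameter=parameter, n=int(rel.size),
                              mean_relative_pct=float(rel.mean()),
                              test=paired_t_test(rel - 100.0))


@dataclass
class DensityHistogram:
    bin_edges: np.ndarray
    densities: np.ndarray
    fit_mean: float
    fit_sd: float

    def pdf(self, x) -> np.ndarray:
        """Normal density with the fitted mean/SD, for overlay plots."""
        if self.fit_sd == 0:
            raise UndefinedStatisticError("degenerate sample: no PDF overlay")
        return stats.norm.pdf(np.asarray(x, dtype=float),
                              self.fit_mean, self.fit_sd)


def density_histogram(values, n_bins: int = 20) -> DensityHistogram:
    """Probability-density histogram with a fitted-normal overlay.

    Densities integrate to one, so cohorts of different sizes are directly
    comparable.  The fitted normal uses the sample mean and sample SD.  A
    degenerate all-equal sample yields a single spike bin and SD 0.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise UndefinedStatisticError("histogram needs >= 2 values")
    if np.ptp(v) == 0:
        edges = np.array([v[0] - 0.5, v[0] + 0.5])
        return DensityHistogram(bin_edges=edges, densities=np.array([1.0]),
                                fit_mean=float(v[0]), fit_sd=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dens, edges = np.histogram(v, bins=n_bins, density=True)
    return DensityHistogram(bin_edges=edges, densities=dens,
                            fit_mean=float(v.mean()),
                            fit_sd=float(v.std(ddof=1)))
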