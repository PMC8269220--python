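"""Specific growth- and death-rate estimation from sparse cell-density series.

Cultures counted every 12–24 h yield curves with a handful of points spanning
lag, exponential, stationary, and death behaviour.  Rates are estimated by
exhaustively segmenting each curve into up to three contiguous phases
(two breakpoints), fitting ordinary least squares of log₂(density) on time
within each segment, and selecting the segmentation by the Bayesian
information criterion on the pooled residual sum of squares.  Slopes are
therefore directly in doublings·h⁻¹.  Segments whose slope is statistically
indistinguishable from zero (t-test, p ≥ 0.05) or whose fitted fold change is
below a threshold are classified stationary and excluded from the reported
phases; a curve with no surviving positive-slope phase is a "no growth" call
rather than a zero rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrowthCurve",
    "PhaseFit",
    "RateSummary",
    "NoGrowthError",
    "segment_and_fit",
    "max_growth_rate",
    "summarize_replicates",
    "yield_ratio",
    "GrowthModel",
    "GrowthResults",
]

MAX_BREAKPOINTS = 2
STATIONARY_ALPHA = 0.05


class NoGrowthError(ValueError):
    """Raised when no positive-growth phase is detected in a curve."""


@dataclass
class GrowthCurve:
    """A sparse cell-density time series for one replicate culture."""

    replicate_id: str
    times: np.ndarray       # hours, strictly increasing
    densities: np.ndarray   # cells/ml, strictly positive

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.densities.shape:
            raise ValueError("times and densities must be 1-D and equal length")
        if len(self.times) < 2:
            raise ValueError("a growth curve needs at least 2 observations")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.densities <= 0):
            raise ValueError("densities must be strictly positive")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class PhaseFit:
    """One log-linear phase of a curve (inclusive index span)."""

    kind: str           # "growth" or "death"
    start_index: int
    end_index: int
    rate: float         # doublings/h; negative for death
    intercept: float    # log2 cells/ml at t = 0
    r_squared: float

    def __post_init__(self):
        if self.kind not in ("growth", "death"):
            raise ValueError(f"unknown phase kind {self.kind!r}")
        if self.kind == "growth" and self.rate <= 0:
            raise ValueError("growth phase must have positive rate")
        if self.kind == "death" and self.rate >= 0:
            raise ValueError("death phase must have negative rate")


@dataclass(frozen=True)
class RateSummary:
    """Replicate-level summary of specific growth rates."""

    mean_rate: float
    sd_rate: float       # sample SD (n-1); NaN for a single replicate
    n_replicates: int
    doubling_time: float  # h, 1/mean_rate (inf if mean_rate <= 0)


def _ols_log2(times: np.ndarray, log2_dens: np.ndarray):
    """Slope, intercept, RSS, r², slope p-value, and slope SE of the
    regression of log2 density on time."""
    res = stats.linregress(times, log2_dens)
    fitted = res.intercept + res.slope * times
    rss = float(np.sum((log2_dens - fitted) ** 2))
    return res.slope, res.intercept, rss, res.rvalue**2, res.pvalue, res.stderr


def _pooled_slope_se(times_seg: np.ndarray, sigma2: float) -> float:
    """Slope SE for one segment under a common error variance."""
    sxx = float(np.sum((times_seg - times_seg.mean()) ** 2))
    return math.sqrt(sigma2 / sxx) if sxx > 0 else math.inf


def _t_pvalue(effect: float, se: float, df: int) -> float:
    """Two-sided t-test p-value, robust to the zero-residual limit."""
    if se == 0:
        return 0.0 if effect != 0 else 1.0
    if df < 1:
        return 1.0
    return float(2 * stats.t.sf(abs(effect) / se, df))


def _segmentations(n: int, min_points: int, max_breakpoints: int = MAX_BREAKPOINTS):
    """All partitions of indices 0..n-1 into ≤ max_breakpoints+1 contiguous
    segments of ≥ min_points each, ordered fewer-segments-first then earlier
    breakpoints (the tie-break order)."""
    for k in range(0, max_breakpoints + 1):
        # breakpoints are indices where a new segment starts
        for bps in combinations(range(min_points, n - min_points + 1), k):
            bounds = (0, *bps, n)
            if all(b - a >= min_points for a, b in zip(bounds, bounds[1:])):
                yield [(a, b - 1) for a, b in zip(bounds, bounds[1:])]


def segment_and_fit(
    curve: GrowthCurve,
    min_points: int = 3,
    min_fold_change: float = 2.0,
    alpha: float = STATIONARY_ALPHA,
) -> list[PhaseFit]:
    """Segment a sparse curve into phases and fit per-phase log-linear rates.

    Exhaustive search over segmentations with at most two breakpoints; the
    number of phases is chosen by BIC on the pooled RSS (n·ln(RSS/n) +
    p·ln(n), p = 3k − 1 for k segments), ties broken toward fewer phases and
    earlier breakpoints.  Adjacent segments whose slopes do not differ
    significantly (t-test at ``alpha`` on the error variance pooled across
    segments) are then merged and refitted, since BIC alone over-segments
    noisy single-phase curves this sparse.  Within each retained segment the
    slope of
    log₂(density) on time is the specific rate in doublings·h⁻¹.  Segments
    with slope p ≥ alpha or fitted |fold change| < min_fold_change are
    stationary and omitted.  Curves shorter than ``min_points`` give an empty
    result with a warning.
    """
    if min_points < 3:
        raise ValueError("min_points must be at least 3")
    n = len(curve)
    if n < min_points:
        warnings.warn(
            f"curve {curve.replicate_id!r} has {n} < {min_points} points; "
            "no phases fitted",
            stacklevel=2,
        )
        return []
    log2_dens = np.log2(curve.densities)

    best = None  # (bic, n_segments, segmentation, fits)
    for segmentation in _segmentations(n, min_points):
        fits = [
            _ols_log2(curve.times[a : b + 1], log2_dens[a : b + 1])
            for a, b in segmentation
        ]
        rss = sum(f[2] for f in fits)
        k = len(segmentation)
        n_params = 3 * k - 1
        bic = n * np.log(max(rss, 1e-30) / n) + n_params * np.log(n)
        # strictly-less comparison + fewer-first generation order = tie-break
        if best is None or bic < best[0] - 1e-12:
            best = (bic, k, segmentation, fits)

    _, _, segmentation, fits = best

    def pooled_sigma2(seg, fs):
        k = len(seg)
        df = n - 2 * k
        rss = sum(f[2] for f in fs)
        return (rss / df if df > 0 else 0.0), max(df, 0)

    # Merge adjacent segments whose slopes are statistically
    # indistinguishable: BIC alone over-segments noisy single-phase curves
    # at these sample sizes.  Slope SEs use the variance pooled across
    # segments, since 3-point segments carry almost no df of their own.
    merged = True
    while merged and len(segmentation) > 1:
        merged = False
        sigma2, df = pooled_sigma2(segmentation, fits)
        for idx in range(len(segmentation) - 1):
            (a1, b1), (a2, b2) = segmentation[idx], segmentation[idx + 1]
            se = math.hypot(
                _pooled_slope_se(curve.times[a1 : b1 + 1], sigma2),
                _pooled_slope_se(curve.times[a2 : b2 + 1], sigma2),
            )
            diff = fits[idx][0] - fits[idx + 1][0]
            if _t_pvalue(diff, se, df) >= alpha:
                segmentation = (
                    segmentation[:idx] + [(a1, b2)] + segmentation[idx + 2 :]
                )
                fits = (
                    fits[:idx]
                    + [_ols_log2(curve.times[a1 : b2 + 1], log2_dens[a1 : b2 + 1])]
                    + fits[idx + 2 :]
                )
                merged = True
                break

    phases: list[PhaseFit] = []
    sigma2, df = pooled_sigma2(segmentation, fits)
    for (a, b), (slope, intercept, _rss, r2, _pval, _se) in zip(segmentation, fits):
        duration = curve.times[b] - curve.times[a]
        fold_log2 = abs(slope) * duration
        pval = _t_pvalue(slope, _pooled_slope_se(curve.times[a : b + 1], sigma2), df)
        if pval >= alpha or fold_log2 < np.log2(min_fold_change):
            continue  # stationary
        phases.append(
            PhaseFit(
                kind="growth" if slope > 0 else "death",
                start_index=a,
                end_index=b,
                rate=float(slope),
                intercept=float(intercept),
                r_squared=float(r2),
            )
        )
    return phases


def max_growth_rate(fits: list[PhaseFit]) -> float:
    """Largest positive specific rate across phases (doublings·h⁻¹).

    Raises ``NoGrowthError`` when no growth phase is present — the analogue
    of a "no growth detected" call.
    """
    rates = [f.rate for f in fits if f.kind == "growth"]
    if not rates:
        raise NoGrowthError("no growth detected")
    return max(rates)


def summarize_replicates(rates: list[float]) -> RateSummary:
    """Mean, sample SD (n−1), and doubling time of replicate rates."""
    if len(rates) == 0:
        raise ValueError("need at least one replicate rate")
    arr = np.asarray(rates, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else float("nan")
    doubling = 1.0 / mean if mean > 0 else float("inf")
    return RateSummary(
        mean_rate=mean, sd_rate=sd, n_replicates=len(arr), doubling_time=doubling
    )


def yield_ratio(
    treatment_max_densities: list[float],
    control_max_densities: list[float],
) -> float:
    """Growth yield of a treatment relative to its control, in percent.

    100 × mean(treatment maximum densities) / mean(control maximum densities).
    """
    if len(treatment_max_densities) == 0 or len(control_max_densities) == 0:
        raise ValueError("density lists must be nonempty")
    control_mean = float(np.mean(control_max_densities))
    if control_mean == 0:
        raise ValueError("control mean density is zero")
    return 100.0 * float(np.mean(treatment_max_densities)) / control_mean


class GrowthModel:
    """Segmented log-linear growth model for one cell-density curve.

    Thin model/results wrapper over :func:`segment_and_fit`::

        res = GrowthModel(curve).fit()
        res.max_growth_rate
        print(res.summary())
    """

    def __init__(self, curve: GrowthCurve):
        self.curve = curve

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, replicate_id: str = "") -> "GrowthModel":
        """Build from a frame with ``time_h`` and ``cells_per_ml`` columns."""
        df = df.sort_values("time_h")
        return cls(
            GrowthCurve(
                replicate_id=replicate_id or str(df.get("replicate", pd.Series([""])).iloc[0]),
                times=df["time_h"].to_numpy(),
                densities=df["cells_per_ml"].to_numpy(),
            )
        )

    def fit(self, min_points: int = 3, min_fold_change: float = 2.0) -> "GrowthResults":
        phases = segment_and_fit(self.curve, min_points, min_fold_change)
        return GrowthResults(self.curve, phases)


class GrowthResults:
    """Fitted phases of a growth curve with rate accessors and a summary table."""

    def __init__(self, curve: GrowthCurve, phases: list[PhaseFit]):
        self.curve = curve
        self.phases = phases

    @property
    def max_growth_rate(self) -> float:
        return max_growth_rate(self.phases)

    @property
    def grew(self) -> bool:
        return any(p.kind == "growth" for p in self.phases)

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "replicate": self.curve.replicate_id,
                "kind": p.kind,
                "t_start_h": self.curve.times[p.start_index],
                "t_end_h": self.curve.times[p.end_index],
                "rate_doublings_per_h": p.rate,
                "doubling_time_h": 1.0 / p.rate if p.rate > 0 else float("nan"),
                "r_squared": p.r_squared,
            }
            for p in self.phases
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "replicate",
                "kind",
                "t_start_h",
                "t_end_h",
                "rate_doublings_per_h",
                "doubling_time_h",
                "r_squared",
            ],
        )
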