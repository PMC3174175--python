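"""Protein concentration time series and growth objectives.

A protein concentration is modeled as a succession of exponential laws
``c(t) = K_i * g_i**(t - t_i)`` between cutpoints ``t_i`` (minutes), with a
basal level assumed null.  Each segment's per-minute growth factor ``g_i``
converts into a per-transition growth objective

    lambda_obj = g_i ** delta

where ``delta`` is the mean real-time duration (minutes) of one Markov
transition.  ``delta`` follows from the N-end rule: a passive step
multiplies the concentration by ``rho``, so the shortest amino-acid
half-life ``tau`` of the protein corresponds to ``log(1/2)/log(rho)``
passive steps and

    delta = tau * log(1/rho) / log(2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, EtmcError

__all__ = [
    "ProteinSeries",
    "PiecewiseExpFit",
    "GrowthObjective",
    "transition_duration",
    "fit_piecewise_exponential",
    "growth_objective",
    "reconstruct_series",
    "compare_series",
]


@dataclass
class ProteinSeries:
    """Sampled concentration curve: times in minutes, concentrations > 0."""

    protein: str
    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.size < 2:
            raise EtmcError("a series needs at least two points")
        if np.any(np.diff(self.times) <= 0):
            raise EtmcError("times must be strictly increasing")
        if np.any(self.concentrations <= 0):
            raise EtmcError("concentrations must be positive")


@dataclass
class Segment:
    start: float  # minutes
    end: float
    K: float  # value at segment start
    factor: float  # per-minute growth factor

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def ratio(self) -> float:
        """Concentration fold-change over the whole segment."""
        return self.factor**self.duration


@dataclass
class PiecewiseExpFit:
    """Per-segment exponential fit (log-space least squares, basal 0)."""

    protein: str
    segments: list[Segment]
    residual: float = 0.0

    @property
    def cutpoints(self) -> list[float]:
        return [s.start for s in self.segments] + [self.segments[-1].end]

    def __call__(self, t: float) -> float:
        for seg in self.segments:
            if seg.start <= t <= seg.end or seg is self.segments[-1]:
                if t <= seg.end:
                    return seg.K * seg.factor ** (t - seg.start)
        seg = self.segments[-1]
        return seg.K * seg.factor ** (t - seg.start)


@dataclass
class GrowthObjective:
    """Per-transition growth factor target for one protein and phase."""

    protein: str
    segment: int
    lambda_obj: float
    delta: float  # minutes per transition
    interval: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.lambda_obj <= 0:
            raise EtmcError("growth objective must be positive")
        if self.interval is not None:
            lo, hi = self.interval
            if lo > hi:
                raise EtmcError("objective interval must satisfy lo <= hi")

    def with_interval(self, rel_width: float = 0.05) -> "GrowthObjective":
        """Attach a +/- rel_width interval around the point objective."""
        lo = self.lambda_obj * (1 - rel_width)
        hi = self.lambda_obj * (1 + rel_width)
        return GrowthObjective(self.protein, self.segment, self.lambda_obj, self.delta, (lo, hi))


def transition_duration(rho: float, half_life: float) -> float:
    """Mean transition duration delta (minutes) from the N-end rule."""
    if not (0.0 < rho < 1.0):
        raise ConfigError(f"passive rate must be in (0,1) for a finite duration, got {rho}")
    if half_life <= 0:
        raise ConfigError("half-life must be positive")
    return half_life * math.log(1.0 / rho) / math.log(2.0)


def fit_piecewise_exponential(
    series: ProteinSeries, cutpoints: list[float]
) -> PiecewiseExpFit:
    """Least-squares fit of log-concentration against time per segment.

    ``cutpoints`` bound the segments (first = start of segment 0, last =
    end of the final segment); each segment needs >= 2 points.  With
    exactly 2 points the fit reduces to the endpoint ratio.
    """
    if len(cutpoints) < 2:
        raise EtmcError("need at least two cutpoints")
    t, c = series.times, series.concentrations
    logc = np.log(c)
    segments: list[Segment] = []
    sse = 0.0
    for k in range(len(cutpoints) - 1):
        lo, hi = cutpoints[k], cutpoints[k + 1]
        mask = (t >= lo - 1e-12) & (t <= hi + 1e-12)
        if mask.sum() < 2:
            raise EtmcError(f"segment [{lo},{hi}] contains fewer than 2 points")
        ts, ys = t[mask], logc[mask]
        slope, intercept = np.polyfit(ts, ys, 1)
        sse += float(np.sum((intercept + slope * ts - ys) ** 2))
        K = math.exp(intercept + slope * lo)  # value extrapolated to segment start
        segments.append(Segment(start=lo, end=hi, K=K, factor=math.exp(slope)))
    return PiecewiseExpFit(protein=series.protein, segments=segments, residual=sse)


def growth_objective(fit: PiecewiseExpFit, segment: int, delta: float) -> GrowthObjective:
    """Per-transition growth factor: (segment fold-change)**(delta / duration)."""
    if delta <= 0:
        raise EtmcError("delta must be positive")
    seg = fit.segments[segment]
    if seg.duration <= 0:
        raise EtmcError("segment has zero duration")
    lam = seg.ratio ** (delta / seg.duration)  # == factor**delta
    return GrowthObjective(protein=fit.protein, segment=segment, lambda_obj=lam, delta=delta)


def reconstruct_series(
    lambdas: list[float],
    delta: float,
    K0: float,
    times: np.ndarray,
    cutpoints: list[float] | None = None,
    protein: str = "predicted",
) -> ProteinSeries:
    """Inverse of :func:`growth_objective`: continuous piecewise-exponential
    curve ``c(t) = K_seg * lambda**((t - t_seg)/delta)``.

    One lambda per segment; ``cutpoints`` default to a single segment
    spanning the full time range.
    """
    times = np.asarray(times, dtype=float)
    if cutpoints is None:
        cutpoints = [float(times[0]), float(times[-1])]
    if len(lambdas) != len(cutpoints) - 1:
        raise EtmcError("need one lambda per segment")
    if any(l <= 0 for l in lambdas):
        raise EtmcError("lambdas must be positive")
    conc = np.empty_like(times)
    K = K0
    for k, lam in enumerate(lambdas):
        lo, hi = cutpoints[k], cutpoints[k + 1]
        last = k == len(lambdas) - 1
        mask = (times >= lo - 1e-12) & ((times <= hi + 1e-12) | last)
        conc[mask] = K * lam ** ((times[mask] - lo) / delta)
        K = K * lam ** ((hi - lo) / delta)  # continuity at the cutpoint
    return ProteinSeries(protein=protein, times=times, concentrations=conc)


def compare_series(a: ProteinSeries, b: ProteinSeries) -> tuple[float, float]:
    """Pearson correlation between two curves on ``a``'s time grid.

    ``b`` is resampled by exponential (log-linear) interpolation; times of
    ``a`` outside ``b``'s range are dropped.  Returns ``(r, p_value)``.
    """
    from scipy import stats

    tmin, tmax = b.times[0], b.times[-1]
    mask = (a.times >= tmin) & (a.times <= tmax)
    if mask.sum() < 3:
        raise EtmcError("need at least 3 common time points")
    logb = np.interp(a.times[mask], b.times, np.log(b.concentrations))
    res = stats.pearsonr(a.concentrations[mask], np.exp(logb))
    return float(res.statistic), float(res.pvalue)
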