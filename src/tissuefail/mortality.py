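"""Mortality-rate estimation, the exponential null, and trend classification.

A non-interacting population loses a constant fraction of its cells per unit
time: the per-capita mortality rate ``m = -(Δn/n)(1/Δt)`` is constant and
``n(t) = n0 * exp(-m t)``.  Deviations from this null carry the signature of
intercellular interaction: if m falls as n grows (negative slope of m vs n),
cells help each other survive (cooperative); if m rises with n, they compete
for resources; a flat m(n) indicates no interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .counting import LiveSeries, Lifetime
from .errors import CensoredInputError, InsufficientDataError, UndefinedTrendError

__all__ = [
    "MortalityCurve",
    "NullFit",
    "TrendResult",
    "GroupComparison",
    "mortality_rate",
    "fit_null",
    "classify_m_vs_n",
    "probability_of_death",
    "normalize_time",
    "compare_groups",
]


@dataclass
class MortalityCurve:
    """Per-interval mortality rates with their interval-start live counts."""

    times: np.ndarray    # interval start times, days
    m: np.ndarray        # per-day mortality rate, -(Δn/n)(1/Δt)
    n_at: np.ndarray     # live count at interval start
    delta_t: np.ndarray  # interval lengths, days


@dataclass
class NullFit:
    """OLS fit of ln n on t (the exponential, non-interacting null)."""

    n0_hat: float
    m_hat: float
    r_squared: float
    residuals: np.ndarray  # per-time deviations of ln n from the fit


@dataclass
class TrendResult:
    """Least-squares slope of m against n/n0 with a bootstrap CI and label."""

    slope: float
    ci_low: float
    ci_high: float
    label: str  # cooperative | competitive | non_interacting
    n0: float


@dataclass
class GroupComparison:
    """Two-sided two-sample (Student) t-test with per-group mean ± SD."""

    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float
    p_value: float
    significant: bool


def _extract(series) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, LiveSeries):
        return np.asarray(series.times, float), np.asarray(series.n_live_est, float)
    times, n = series
    return np.asarray(times, float), np.asarray(n, float)


def mortality_rate(series) -> MortalityCurve:
    """Discrete per-capita mortality rate per interval.

    Accepts a LiveSeries or a ``(times, n)`` pair; times must be strictly
    increasing with at least two points.  Intervals starting at n = 0 are
    omitted (the rate is undefined there).
    """
    times, n = _extract(series)
    if times.size < 2:
        raise InsufficientDataError("need at least two time points")
    if not (np.diff(times) > 0).all():
        raise ValueError("times must be strictly increasing")
    dt = np.diff(times)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = -(np.diff(n)) / (n[:-1] * dt)
    keep = n[:-1] > 0
    return MortalityCurve(times=times[:-1][keep], m=m[keep], n_at=n[:-1][keep], delta_t=dt[keep])


def fit_null(series) -> NullFit:
    """Fit the exponential null n(t) = n0 exp(-m t) by OLS of ln n on t."""
    times, n = _extract(series)
    keep = n > 0
    times, n = times[keep], n[keep]
    if times.size < 3:
        raise InsufficientDataError("need at least three points with n > 0")
    res = stats.linregress(times, np.log(n))
    fitted = res.intercept + res.slope * times
    return NullFit(
        n0_hat=float(np.exp(res.intercept)),
        m_hat=float(-res.slope),
        r_squared=float(res.rvalue**2),
        residuals=np.log(n) - fitted,
    )


def classify_m_vs_n(
    curve: MortalityCurve,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed=None,
    n0: float | None = None,
) -> TrendResult:
    """Classify the m(n) trend by the sign of its bootstrap slope CI.

    The slope of m on n/n0 is estimated by least squares; the CI is the
    percentile interval over ``n_boot`` resamples of the (n, m) pairs.  A CI
    entirely below 0 ⇒ cooperative (mortality falls when the population is
    dense); entirely above 0 ⇒ competitive; containing 0 ⇒ non_interacting.
    """
    if curve.m.size < 4:
        raise InsufficientDataError("need at least four (n, m) pairs")
    n0 = float(n0 if n0 is not None else curve.n_at.max())
    x = curve.n_at / n0
    y = curve.m
    if np.ptp(x) == 0:
        raise UndefinedTrendError("all n values equal; slope undefined")
    slope = float(stats.linregress(x, y).slope)

    rng = np.random.default_rng(seed)
    k = x.size
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, k, size=k)
        xb, yb = x[idx], y[idx]
        if np.ptp(xb) == 0:
            boots[b] = np.nan
            continue
        boots[b] = stats.linregress(xb, yb).slope
    boots = boots[np.isfinite(boots)]
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])

    if hi < 0:
        label = "cooperative"
    elif lo > 0:
        label = "competitive"
    else:
        label = "non_interacting"
    return TrendResult(slope=slope, ci_low=float(lo), ci_high=float(hi), label=label, n0=n0)


def probability_of_death(series) -> MortalityCurve:
    """Per-interval death probability p_t = m_t * Δt, clamped to [0, 1].

    For positive counts this equals 1 - n_{t+1}/n_t.
    """
    curve = mortality_rate(series)
    p = np.clip(curve.m * curve.delta_t, 0.0, 1.0)
    return MortalityCurve(times=curve.times, m=p, n_at=curve.n_at, delta_t=curve.delta_t)


def normalize_time(curve: MortalityCurve, lifetime: Lifetime | float, grid_points: int = 21):
    """Map a curve onto a fixed normalized-time grid t/T in [0, 1].

    Values are linearly interpolated onto ``grid_points`` equally spaced
    abscissae.  Refuses censored lifetimes.
    """
    if isinstance(lifetime, Lifetime):
        if lifetime.censored:
            raise CensoredInputError("cannot normalize by a censored lifetime")
        T = lifetime.time
    else:
        T = float(lifetime)
    if T <= 0:
        raise ValueError("lifetime must be > 0")
    grid = np.linspace(0.0, 1.0, grid_points)
    frac = curve.times / T
    values = np.interp(grid, frac, curve.m)
    return grid, values


def compare_groups(values_a, values_b) -> GroupComparison:
    """Two-sided Student's t-test between two groups (significance at 0.05).

    Identical-mean groups with zero variance yield p = 1 by convention;
    different means with zero variance yield p = 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs at least two values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t = np.inf if a.mean() > b.mean() else -np.inf
            p = 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        t_statistic=float(t), p_value=float(p), significant=bool(p < 0.05),
    )
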