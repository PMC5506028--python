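"""Dead-cell-per-gel estimation and live-cell bookkeeping.

Implements the counting arithmetic of the imaging protocol: per-day imaging
records are averaged and scaled up to the whole gel (by the slice count and
the inverse field-of-view fraction), an affine calibration is applied, and
live-cell numbers are obtained by cumulative subtraction from the theoretical
day-0 count.  The tissue lifetime is the first time at which at most 2% of
the initial population remains alive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import IncompleteRecordError
from .imaging import ImagingProtocol

__all__ = [
    "CalibrationCurve",
    "LiveSeries",
    "Lifetime",
    "dead_per_gel_slices",
    "dead_per_gel_projection",
    "live_series",
    "lifetime",
    "live_series_from_records",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Affine normalization of raw counts: actual = (raw - intercept) / gain, clamped >= 0."""

    gain: float = 1.0
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be > 0")

    def __call__(self, raw: float) -> float:
        return max(0.0, (float(raw) - self.intercept) / self.gain)


@dataclass
class LiveSeries:
    """Estimated live-cell counts and percentages over time for one replicate."""

    times: np.ndarray       # days, starting at 0
    n_live_est: np.ndarray  # counts, non-increasing, in [0, N0]
    N0: float

    @property
    def live_pct(self) -> np.ndarray:
        return 100.0 * self.n_live_est / self.N0


@dataclass(frozen=True)
class Lifetime:
    """First time at which live % <= 2, or the last observed time if censored."""

    time: float
    censored: bool = False


def dead_per_gel_slices(
    counts,
    protocol: ImagingProtocol,
    calibration: CalibrationCurve = CalibrationCurve(),
) -> float:
    """Whole-gel dead-cell estimate from per-slice counts.

    ``counts`` are the day's middle-slice counts (default 3 stacks x 3 slices
    = 9 values).  The mean count is calibrated, multiplied by the number of
    slices per stack, and scaled by the inverse per-stack field-of-view
    fraction (8 for the default 1/8 stacks).
    """
    counts = np.asarray(counts, dtype=float)
    expected = protocol.n_stacks * protocol.middle_slices
    if counts.size != expected:
        raise IncompleteRecordError(
            f"expected {expected} slice counts, got {counts.size}"
        )
    return calibration(counts.mean()) * protocol.n_slices / protocol.stack_fov_fraction


def dead_per_gel_projection(
    counts,
    protocol: ImagingProtocol,
    calibration: CalibrationCurve = CalibrationCurve(),
) -> float:
    """Whole-gel dead-cell estimate from per-stack maximum-projection counts."""
    counts = np.asarray(counts, dtype=float)
    if counts.size != protocol.n_stacks:
        raise IncompleteRecordError(
            f"expected {protocol.n_stacks} projection counts, got {counts.size}"
        )
    return calibration(counts.mean()) / protocol.stack_fov_fraction


def live_series(times, dead_estimates, N0: float) -> LiveSeries:
    """Cumulative live-cell bookkeeping.

    ``n_live[0] = N0`` (the theoretical encapsulated number); each day's
    dead-cell estimate is subtracted from the previous live count, clamped at
    zero.  ``times`` are the estimate times (day 0 is prepended).
    """
    if N0 <= 0:
        raise ValueError("N0 must be > 0")
    dead = np.asarray(dead_estimates, dtype=float)
    if (dead < 0).any():
        raise ValueError("dead estimates must be >= 0")
    times = np.asarray(times, dtype=float)
    if times.size != dead.size:
        raise ValueError("times and dead_estimates must have equal length")
    n = np.empty(dead.size + 1)
    n[0] = N0
    for i, dm in enumerate(dead):
        n[i + 1] = max(0.0, n[i] - dm)
    return LiveSeries(times=np.concatenate([[0.0], times]), n_live_est=n, N0=float(N0))


def lifetime(series: LiveSeries, threshold_pct: float = 2.0) -> Lifetime:
    """First time with live % <= threshold (default 2%, i.e. >= 98% dead)."""
    pct = series.live_pct
    below = np.flatnonzero(pct <= threshold_pct)
    if below.size == 0:
        return Lifetime(time=float(series.times[-1]), censored=True)
    return Lifetime(time=float(series.times[below[0]]), censored=False)


def live_series_from_records(
    records: pd.DataFrame,
    protocol: ImagingProtocol,
    N0: float,
    calibration: CalibrationCurve = CalibrationCurve(),
) -> dict[int, LiveSeries]:
    """Per-replicate live series from an emulator record table.

    The table must carry columns replicate, day, mode, dead_count (as written
    by :func:`tissuefail.imaging.records_to_frame`).
    """
    out: dict[int, LiveSeries] = {}
    for rep, sub in records.groupby("replicate"):
        days = np.sort(sub["day"].unique())
        dead_est = []
        for day in days:
            day_counts = sub.loc[sub["day"] == day, "dead_count"].to_numpy()
            mode = sub.loc[sub["day"] == day, "mode"].iloc[0]
            if mode == "slices":
                dead_est.append(dead_per_gel_slices(day_counts, protocol, calibration))
            else:
                dead_est.append(dead_per_gel_projection(day_counts, protocol, calibration))
        out[int(rep)] = live_series(days, dead_est, N0)
    return out
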