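"""Tabular serialization of simulator and pipeline outputs (CSV/TSV)."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .counting import LiveSeries
from .model import PopulationTrajectory, TissueState

__all__ = [
    "trajectories_frame",
    "snapshot_frame",
    "write_records_tsv",
    "read_records_tsv",
    "live_series_frame",
    "read_live_series_csv",
]


def trajectories_frame(trajectories: Sequence[PopulationTrajectory]) -> pd.DataFrame:
    """Stack trajectories into columns replicate, day, n_live, new_deaths, G."""
    frames = []
    for rep, tr in enumerate(trajectories):
        frames.append(pd.DataFrame({
            "replicate": rep,
            "day": tr.times,
            "n_live": tr.n.astype(int),
            "new_deaths": np.concatenate([[0.0], tr.new_deaths]).astype(int),
            "G": tr.G,
        }))
    return pd.concat(frames, ignore_index=True)


def snapshot_frame(state: TissueState) -> pd.DataFrame:
    """Per-cell snapshot: cell_id, x_um, y_um, z_um, alive, age_class, c, p."""
    return pd.DataFrame({
        "cell_id": np.arange(state.n_cells),
        "x_um": state.positions[:, 0],
        "y_um": state.positions[:, 1],
        "z_um": state.positions[:, 2],
        "alive": state.alive,
        "age_class": state.age_class,
        "c": state.c,
        "p": state.p,
        "senescent": state.senescent,
    })


def write_records_tsv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_records_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["slice"] = df["slice"].astype(str)
    return df


def live_series_frame(series: dict[int, LiveSeries]) -> pd.DataFrame:
    """Columns replicate, day, dead_est, n_live_est, live_pct."""
    frames = []
    for rep in sorted(series):
        ls = series[rep]
        dead = np.concatenate([[0.0], -np.diff(ls.n_live_est)])
        frames.append(pd.DataFrame({
            "replicate": rep,
            "day": ls.times,
            "dead_est": dead,
            "n_live_est": ls.n_live_est,
            "live_pct": ls.live_pct,
        }))
    return pd.concat(frames, ignore_index=True)


def read_live_series_csv(path) -> dict[int, LiveSeries]:
    df = pd.read_csv(path)
    out: dict[int, LiveSeries] = {}
    for rep, sub in df.groupby("replicate"):
        sub = sub.sort_values("day")
        n = sub["n_live_est"].to_numpy(float)
        n0 = 100.0 * n[0] / sub["live_pct"].iloc[0] if sub["live_pct"].iloc[0] > 0 else n[0]
        out[int(rep)] = LiveSeries(times=sub["day"].to_numpy(float), n_live_est=n, N0=float(n0))
    return out
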