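"""Summary/plot generation over a completed run directory.

``report(run_dir)`` inspects the tables written by the CLI verbs, recomputes
group summaries from them, writes a deterministic ``summary.json`` and a set
of diagnostic plots (live-% curves, mortality rate vs time and vs live
fraction, probability of death, normalized-time curves, lifetime bars).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .counting import lifetime
from .errors import TissueFailError
from .io import read_live_series_csv
from .mortality import mortality_rate, normalize_time

__all__ = ["report"]

_SECTIONS = {
    "density": "density_lifetimes.csv",
    "stress": "stress_lifetimes.csv",
    "media": "media_lifetimes.csv",
}


def _lifetime_summary(df: pd.DataFrame, group_cols: list[str]) -> list[dict]:
    out = []
    for keys, sub in df.groupby(group_cols, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        entry = dict(zip(group_cols, [str(k) for k in keys]))
        entry["mean_lifetime_days"] = round(float(sub["lifetime_days"].mean()), 6)
        entry["sd_lifetime_days"] = round(float(sub["lifetime_days"].std(ddof=1)), 6) if len(sub) > 1 else 0.0
        entry["n"] = int(len(sub))
        out.append(entry)
    return out


def _plot_series(series_files: list[Path], out_dir: Path) -> list[str]:
    made = []
    for path in sorted(series_files):
        label = path.stem.replace("live_series_", "")
        series = read_live_series_csv(path)
        fig, axes = plt.subplots(2, 2, figsize=(10, 8))
        for rep, ls in sorted(series.items()):
            axes[0, 0].plot(ls.times, ls.live_pct, alpha=0.6)
            curve = mortality_rate(ls)
            axes[0, 1].plot(curve.times, curve.m, alpha=0.6)
            axes[1, 0].plot(curve.n_at / ls.N0, curve.m, ".", alpha=0.5)
            lt = lifetime(ls)
            if not lt.censored and lt.time > 0:
                grid, vals = normalize_time(curve, lt)
                axes[1, 1].plot(grid, vals, alpha=0.6)
        axes[0, 0].set(xlabel="day", ylabel="live %", title=f"{label}: live cell %")
        axes[0, 1].set(xlabel="day", ylabel="m (1/day)", title="mortality rate m(t)")
        axes[1, 0].set(xlabel="n / n0", ylabel="m (1/day)", title="m vs live fraction")
        axes[1, 1].set(xlabel="t / T", ylabel="m (1/day)", title="normalized time")
        fig.tight_layout()
        out = out_dir / f"curves_{label}.png"
        fig.savefig(out, dpi=110)
        plt.close(fig)
        made.append(out.name)
    return made


def _plot_lifetime_bars(df: pd.DataFrame, group_cols: list[str], title: str, out: Path) -> None:
    g = df.groupby(group_cols)["lifetime_days"]
    means, sds = g.mean(), g.std(ddof=1).fillna(0.0)
    labels = [" / ".join(map(str, k)) if isinstance(k, tuple) else str(k) for k in means.index]
    fig, ax = plt.subplots(figsize=(max(6, 0.9 * len(labels)), 4))
    ax.bar(range(len(means)), means.to_numpy(), yerr=sds.to_numpy(), capsize=3)
    ax.set_xticks(range(len(means)))
    ax.set_xticklabels(labels, rotation=45, ha="right")
    ax.set_ylabel("lifetime (days)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out, dpi=110)
    plt.close(fig)


def report(run_dir, out_dir=None) -> dict:
    """Build summary.json (+ plots) from a run directory; returns the summary."""
    run_dir = Path(run_dir)
    out_dir = Path(out_dir) if out_dir is not None else run_dir
    out_dir.mkdir(parents=True, exist_ok=True)

    present = {k: run_dir / f for k, f in _SECTIONS.items() if (run_dir / f).exists()}
    series_files = sorted(run_dir.glob("live_series_*.csv"))
    verdict_file = run_dir / "media_verdicts.json"
    if not present and not series_files:
        missing = sorted(_SECTIONS.values()) + ["live_series_*.csv"]
        raise TissueFailError(f"no run artifacts found in {run_dir}; expected any of: {missing}")

    summary: dict = {"sections": {}}
    cfg_file = run_dir / "config.yaml"
    if cfg_file.exists():
        from .scenarios import ScenarioConfig

        summary["config_hash"] = ScenarioConfig.from_yaml(cfg_file).config_hash()

    plots: list[str] = []
    if "density" in present:
        df = pd.read_csv(present["density"])
        summary["sections"]["density"] = _lifetime_summary(df, ["density", "age_class"])
        tests = run_dir / "density_tests.csv"
        if tests.exists():
            summary["sections"]["density_tests"] = json.loads(
                pd.read_csv(tests).to_json(orient="records"))
        _plot_lifetime_bars(df, ["density", "age_class"], "Lifetime by density and age",
                            out_dir / "lifetimes_density.png")
        plots.append("lifetimes_density.png")
    else:
        summary["sections"]["density"] = "missing"

    if "stress" in present:
        df = pd.read_csv(present["stress"])
        summary["sections"]["stress"] = _lifetime_summary(df, ["density", "age_class", "stress"])
        _plot_lifetime_bars(df, ["density", "age_class", "stress"],
                            "Lifetime with/without oxidative stress",
                            out_dir / "lifetimes_stress.png")
        plots.append("lifetimes_stress.png")
    else:
        summary["sections"]["stress"] = "missing"

    if "media" in present:
        df = pd.read_csv(present["media"])
        summary["sections"]["media"] = _lifetime_summary(df, ["hypothesis", "arm"]
                                                         if "hypothesis" in df.columns else ["arm"])
        if verdict_file.exists():
            summary["sections"]["media_verdicts"] = json.loads(verdict_file.read_text())
        group = ["hypothesis", "arm"] if "hypothesis" in df.columns else ["arm"]
        _plot_lifetime_bars(df, group, "Conditioned-media lifetimes",
                            out_dir / "lifetimes_media.png")
        plots.append("lifetimes_media.png")
    else:
        summary["sections"]["media"] = "missing"

    plots.extend(_plot_series(series_files, out_dir))
    summary["plots"] = sorted(plots)

    (out_dir / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=2) + "\n")
    return summary
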