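"""Reference computations reproducing the study's headline quantities.

Each function runs the package end-to-end at a documented problem size and
returns plainly named numbers (spacings, the non-interacting rate, counting
errors, lifetimes and their t-tests, trend-label fractions, conditioned-
media predicate counts).  They back both the acceptance checks and the
reproduction script.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .counting import live_series_from_records
from .distances import estimated_spacing, per_plane_nn
from .experiments import evaluate_hypotheses, run_density_sweep, run_media_experiment
from .imaging import generate_experiment
from .model import ModelParams, run
from .mortality import compare_groups, fit_null
from .scenarios import ScenarioConfig

__all__ = [
    "spacing_benchmark",
    "noninteracting_null_benchmark",
    "counting_benchmark",
    "density_signature_benchmark",
    "media_benchmark",
    "poisson_nn_benchmark",
]


def spacing_benchmark() -> dict:
    """Estimated cell-cell spacing (µm) for the three seeding densities."""
    return {
        label: estimated_spacing(5.0, n).rounded_um
        for label, n in (("1k", 1_000), ("10k", 10_000), ("100k", 100_000))
    }


def noninteracting_null_benchmark(seed: int, n_reps: int = 100, n_cells: int = 10_000) -> dict:
    """Fit the exponential null on non-interacting runs (beta=theta=0, r=0).

    Returns the mean fitted rate, its SE over replicates, the theoretical
    daily rate -ln(1-d), and the mean r² of the log-linear fits.
    """
    d = 0.2
    m_hats, r2s = [], []
    for rep in range(n_reps):
        p = ModelParams(n_cells=n_cells, d=d, beta=0.0, theta=0.0,
                        lambda_int=0.0, seed=(seed, 101, rep))
        traj, _ = run(p)
        fit = fit_null((traj.times, traj.n))
        m_hats.append(fit.m_hat)
        r2s.append(fit.r_squared)
    m_hats = np.array(m_hats)
    return {
        "m_hat_mean": float(m_hats.mean()),
        "m_hat_se": float(m_hats.std(ddof=1) / np.sqrt(n_reps)),
        "m_theory": float(-np.log(1 - d)),
        "r_squared_mean": float(np.mean(r2s)),
        "n_reps": n_reps,
    }


def counting_benchmark(seed: int, n_reps: int = 50) -> dict:
    """Counting-pipeline accuracy on emulated 10K constructs.

    Exhaustive-FOV arm: whole-gel single stack, all slices, identity
    calibration — maximum absolute deviation from the ground-truth live
    series.  Default-protocol arm: median relative error of the total-death
    estimate over ``n_reps`` replicates.
    """
    exhaustive = ScenarioConfig(
        density="10K", age_class="young", replicates=2, seed=seed + 201,
        protocol={"n_stacks": 1, "stack_fov_fraction": 1.0, "middle_slices": 10},
    )
    records, truth = generate_experiment(exhaustive)
    series = live_series_from_records(records, exhaustive.build_protocol(), exhaustive.n_cells)
    max_err = 0.0
    for rep, ls in series.items():
        traj = truth[rep]["trajectory"]
        true_at = {round(t, 6): n for t, n in zip(traj.times, traj.n)}
        for t, n in zip(ls.times, ls.n_live_est):
            max_err = max(max_err, abs(n - true_at[round(t, 6)]))

    default = ScenarioConfig(density="10K", age_class="young",
                             replicates=n_reps, seed=seed + 202)
    records, truth = generate_experiment(default)
    series = live_series_from_records(records, default.build_protocol(), default.n_cells)
    rel_errors = []
    for rep, ls in series.items():
        traj = truth[rep]["trajectory"]
        true_total = traj.n[0] - traj.n[-1]
        est_total = ls.n_live_est[0] - ls.n_live_est[-1]
        rel_errors.append(abs(est_total - true_total) / true_total)
    return {
        "exhaustive_max_abs_error": float(max_err),
        "median_rel_error_pct": float(100.0 * np.median(rel_errors)),
        "n_reps": n_reps,
    }


def density_signature_benchmark(seed: int, n_reps: int = 20) -> dict:
    """Young vs pre-aged lifetimes and m(n) labels at 100K and 1K densities."""
    cfg = ScenarioConfig(replicates=n_reps, seed=seed, hypothesis="reception")
    res = run_density_sweep(cfg, densities=("1K", "100K"))
    out: dict = {"n_reps": n_reps}
    for density in ("1K", "100K"):
        young = res["arms"][(density, "young")]
        aged = res["arms"][(density, "pre_aged")]
        cmp = compare_groups(young.lifetime_values, aged.lifetime_values)
        key = density.lower()
        out[f"lifetime_young_{key}"] = cmp.mean_a
        out[f"lifetime_aged_{key}"] = cmp.mean_b
        out[f"p_young_vs_aged_{key}"] = cmp.p_value
        labels = Counter(young.trend_labels(seed=seed))
        out[f"frac_cooperative_young_{key}"] = labels["cooperative"] / n_reps
        out[f"frac_noninteracting_young_{key}"] = labels["non_interacting"] / n_reps
    return out


def media_benchmark(seed: int, n_reps: int = 20) -> dict:
    """Conditioned-media matrix under both aging hypotheses."""
    results = {}
    for hyp in ("reception", "production"):
        cfg = ScenarioConfig(replicates=n_reps, seed=seed, hypothesis=hyp)
        results[hyp] = run_media_experiment(cfg)
    verdicts = evaluate_hypotheses(results)
    out = {"n_reps": n_reps}
    for hyp, v in verdicts.items():
        out[f"{hyp}_predicates_met"] = sum(v.predicates.values())
        out[f"{hyp}_matches_pattern"] = int(v.overall)
    out["verdicts"] = verdicts
    out["results"] = results
    return out


def poisson_nn_benchmark(seed: int, n_points: int = 2000, n_draws: int = 4) -> dict:
    """Mean per-plane NN distance vs the 2-D Poisson closed form 0.5/sqrt(ρ)."""
    rng = np.random.default_rng((seed, 301))
    side = 1000.0
    theory = 0.5 / np.sqrt(n_points / side**2)
    means = []
    for _ in range(n_draws):
        xy = rng.random((n_points, 2)) * side
        pos = np.column_stack([xy, np.full(n_points, 5.0)])
        means.append(per_plane_nn(pos, np.array([0.0, 10.0])).mean)
    mean = float(np.mean(means))
    return {
        "mean_um": mean,
        "theory_um": float(theory),
        "rel_error_pct": float(100.0 * abs(mean - theory) / theory),
        "n_points": n_points,
    }
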