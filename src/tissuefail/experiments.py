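"""Experiment orchestration: density/stress sweeps and conditioned-media runs.

Every arm follows the full observation chain — simulate the construct,
emulate the daily staining/imaging, run the counting pipeline on the emitted
records, then analyze the resulting live series (lifetimes, mortality
trends, group t-tests).  Conditioned-media arms pair each replicate with its
control through shared seed streams so that the only difference is the
medium schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .counting import Lifetime, LiveSeries, lifetime, live_series_from_records
from .errors import MissingArmError
from .imaging import generate_experiment
from .model import build_interaction_graph, step_day
from .mortality import GroupComparison, classify_m_vs_n, compare_groups, mortality_rate
from .scenarios import ScenarioConfig, initial_state_for

__all__ = [
    "ArmResult",
    "PatternVerdict",
    "run_arm",
    "run_density_sweep",
    "run_stress_sweep",
    "donor_media_schedule",
    "run_media_experiment",
    "evaluate_hypotheses",
]

PREDICATE_NAMES = (
    "aged_dense_not_rescued_by_young_cm",
    "aged_sparse_not_rescued_by_young_cm",
    "young_sparse_rescued_by_young_cm",
    "young_sparse_rescued_by_aged_cm",
)


@dataclass
class ArmResult:
    """Full-pipeline output of one experimental arm."""

    scenario: ScenarioConfig
    series: dict[int, LiveSeries]          # pipeline-estimated live series per replicate
    lifetimes: list[Lifetime]
    truth: list                            # ground-truth per replicate (trajectory, footprints, state)
    records: pd.DataFrame

    @property
    def lifetime_values(self) -> np.ndarray:
        return np.array([lt.time for lt in self.lifetimes])

    def trend_labels(self, seed: int = 0, min_live_fraction: float = 0.10) -> list[str]:
        """Per-replicate m(n) trend labels.

        The trend is fit on the daily series (uniform Δt; sub-daily day-1
        stains probe early viability, not the rate trend) and on intervals
        starting above ``min_live_fraction`` of the seeded population — below
        that, the cumulative-subtraction error of the counting pipeline
        dominates the estimated counts and would anchor the fit on artifact
        leverage points.
        """
        from .counting import LiveSeries
        from .mortality import MortalityCurve

        labels = []
        for rep, ls in sorted(self.series.items()):
            keep = np.isclose(ls.times % 1.0, 0.0)
            daily = LiveSeries(times=ls.times[keep], n_live_est=ls.n_live_est[keep], N0=ls.N0)
            curve = mortality_rate(daily)
            sel = curve.n_at >= min_live_fraction * ls.N0
            curve = MortalityCurve(times=curve.times[sel], m=curve.m[sel],
                                   n_at=curve.n_at[sel], delta_t=curve.delta_t[sel])
            res = classify_m_vs_n(curve, seed=(seed, rep), n0=ls.N0)
            labels.append(res.label)
        return labels


@dataclass
class PatternVerdict:
    """Which conditioned-media predicates a hypothesis satisfies."""

    hypothesis: str
    predicates: dict[str, bool]
    comparisons: dict[str, GroupComparison] = field(default_factory=dict)

    @property
    def overall(self) -> bool:
        return all(self.predicates.values())

    @property
    def violated(self) -> list[str]:
        return [k for k, v in self.predicates.items() if not v]


def run_arm(
    scenario: ScenarioConfig,
    n_replicates: int | None = None,
    media_policies=None,
) -> ArmResult:
    """simulate → emulate → count for one arm."""
    records, truth = generate_experiment(scenario, n_replicates, media_policies)
    protocol = scenario.build_protocol()
    series = live_series_from_records(records, protocol, scenario.n_cells)
    lts = [lifetime(series[rep]) for rep in sorted(series)]
    return ArmResult(scenario=scenario, series=series, lifetimes=lts,
                     truth=truth, records=records)


# --------------------------------------------------------------------- sweeps

def run_density_sweep(
    config: ScenarioConfig,
    densities=("1K", "10K", "100K"),
    age_classes=("young", "pre_aged"),
) -> dict:
    """Full pipeline per density x age class with young-vs-aged t-tests.

    Returns a dict with ``arms`` (ArmResult per (density, age)), a
    ``lifetimes`` table, per-replicate ``trends``, and young-vs-aged
    ``tests`` per density.
    """
    arms: dict[tuple[str, str], ArmResult] = {}
    rows = []
    trend_rows = []
    for density in densities:
        for age in age_classes:
            scn = replace(config, density=density, age_class=age, media="none")
            arm = run_arm(scn)
            arms[(density, age)] = arm
            for rep, lt in enumerate(arm.lifetimes):
                rows.append({"density": density, "age_class": age, "replicate": rep,
                             "lifetime_days": lt.time, "censored": lt.censored})
            for rep, label in enumerate(arm.trend_labels(seed=config.seed)):
                trend_rows.append({"density": density, "age_class": age,
                                   "replicate": rep, "label": label})
    lifetimes = pd.DataFrame(rows)
    trends = pd.DataFrame(trend_rows)

    test_rows = []
    if set(age_classes) >= {"young", "pre_aged"}:
        for density in densities:
            cmp = compare_groups(
                arms[(density, "young")].lifetime_values,
                arms[(density, "pre_aged")].lifetime_values,
            )
            test_rows.append({
                "density": density,
                "mean_young": cmp.mean_a, "sd_young": cmp.sd_a,
                "mean_aged": cmp.mean_b, "sd_aged": cmp.sd_b,
                "t": cmp.t_statistic, "p_value": cmp.p_value,
                "significant": cmp.significant,
            })
    return {"arms": arms, "lifetimes": lifetimes, "trends": trends,
            "tests": pd.DataFrame(test_rows)}


def run_stress_sweep(
    config: ScenarioConfig,
    densities=("1K", "10K", "100K"),
    age_classes=("young", "pre_aged"),
) -> dict:
    """With/without oxidative stress for every density x age class.

    Stress multiplies the intrinsic damage rate by ``sigma_stress``; paired
    seed streams make the with/without comparison a paired perturbation.
    """
    arms: dict[tuple[str, str, bool], ArmResult] = {}
    rows = []
    for density in densities:
        for age in age_classes:
            for stress in (False, True):
                scn = replace(config, density=density, age_class=age,
                              stress=stress, media="none")
                arm = run_arm(scn)
                arms[(density, age, stress)] = arm
                for rep, lt in enumerate(arm.lifetimes):
                    rows.append({"density": density, "age_class": age, "stress": stress,
                                 "replicate": rep, "lifetime_days": lt.time,
                                 "censored": lt.censored})
    lifetimes = pd.DataFrame(rows)

    test_rows = []
    for density in densities:
        for age in age_classes:
            cmp = compare_groups(
                arms[(density, age, False)].lifetime_values,
                arms[(density, age, True)].lifetime_values,
            )
            test_rows.append({"density": density, "age_class": age,
                              "comparison": "no_stress_vs_stress",
                              "mean_no_stress": cmp.mean_a, "mean_stress": cmp.mean_b,
                              "p_value": cmp.p_value, "significant": cmp.significant})
        if set(age_classes) >= {"young", "pre_aged"}:
            cmp = compare_groups(
                arms[(density, "young", True)].lifetime_values,
                arms[(density, "pre_aged", True)].lifetime_values,
            )
            test_rows.append({"density": density, "age_class": "both",
                              "comparison": "young_vs_aged_under_stress",
                              "mean_no_stress": cmp.mean_a, "mean_stress": cmp.mean_b,
                              "p_value": cmp.p_value, "significant": cmp.significant})
    return {"arms": arms, "lifetimes": lifetimes, "tests": pd.DataFrame(test_rows)}


# ------------------------------------------------------------ conditioned media

def donor_media_schedule(
    donor_scenario: ScenarioConfig,
    replicate: int,
    horizon_days: int,
) -> np.ndarray:
    """Daily conditioned-medium levels harvested from one donor construct.

    The donor is fabricated and maintained for ``conditioning_days`` (default
    2) with its medium accumulating; the first harvest carries that
    conditioned medium.  Thereafter the donor receives fresh medium after
    every harvest, so each subsequent day's harvest carries one day of
    conditioning.  Harvests continue (approaching zero as the donor tissue
    dies) for ``horizon_days`` recipient days.
    """
    conditioning = int(donor_scenario.aging_value("conditioning_days"))
    params = donor_scenario.build_params()
    key = (donor_scenario.seed, 990_001,
           0 if donor_scenario.age_class == "young" else 1, replicate)
    ss = np.random.SeedSequence(key)
    place_seed, run_seed = ss.spawn(2)
    state = initial_state_for(donor_scenario, params, place_seed)
    rng = np.random.default_rng(run_seed)
    graph = build_interaction_graph(state.positions, params.lambda_int)

    harvests: list[float] = []
    day = 0
    while len(harvests) < horizon_days:
        state = step_day(state, graph, params, rng)
        day += 1
        if day >= conditioning:
            harvests.append(state.G)
            state = replace(state, G=0.0)  # fresh medium after each harvest
    return np.array(harvests)


_MEDIA_ARMS = {
    # arm name: (density, age_class, donor age or None for control)
    "aged_100K_control": ("100K", "pre_aged", None),
    "aged_100K_young_cm": ("100K", "pre_aged", "young"),
    "young_1K_control": ("1K", "young", None),
    "young_1K_young_cm": ("1K", "young", "young"),
    "young_1K_aged_cm": ("1K", "young", "pre_aged"),
    "aged_1K_control": ("1K", "pre_aged", None),
    "aged_1K_young_cm": ("1K", "pre_aged", "young"),
    "aged_1K_aged_cm": ("1K", "pre_aged", "pre_aged"),
}


def run_media_experiment(config: ScenarioConfig, horizon_days: int = 45) -> dict:
    """The conditioned-media transfer matrix for one hypothesis setting.

    Donors are 100K constructs (young or pre-aged) conditioned for 2 days;
    their media are harvested daily and handed to recipients, whose controls
    receive fresh (non-conditioned) medium on the same schedule.  Recipient
    replicates share seed streams across arms, so each conditioned arm is
    pathwise paired with its control.
    """
    reps = config.replicates
    donor_schedules: dict[str, list[np.ndarray]] = {}
    for donor_age in ("young", "pre_aged"):
        donor_scn = replace(config, density="100K", age_class=donor_age,
                            media="none", stress=False)
        donor_schedules[donor_age] = [
            donor_media_schedule(donor_scn, rep, horizon_days) for rep in range(reps)
        ]

    arms: dict[str, ArmResult] = {}
    rows = []
    for name, (density, age, donor_age) in _MEDIA_ARMS.items():
        media = "none" if donor_age is None else (
            "receive_young_100K" if donor_age == "young" else "receive_aged_100K"
        )
        scn = replace(config, density=density, age_class=age, media=media, stress=False)
        policies = None if donor_age is None else donor_schedules[donor_age]
        arm = run_arm(scn, media_policies=policies)
        arms[name] = arm
        for rep, lt in enumerate(arm.lifetimes):
            rows.append({"arm": name, "density": density, "age_class": age,
                         "conditioned_media": donor_age or "none", "replicate": rep,
                         "lifetime_days": lt.time, "censored": lt.censored})
    return {
        "hypothesis": config.hypothesis,
        "arms": arms,
        "lifetimes": pd.DataFrame(rows),
        "donor_schedules": donor_schedules,
    }


def _rescued(arm_cm: ArmResult, arm_ctrl: ArmResult) -> tuple[bool, GroupComparison]:
    cmp = compare_groups(arm_cm.lifetime_values, arm_ctrl.lifetime_values)
    return bool(cmp.significant and cmp.mean_a > cmp.mean_b), cmp


def evaluate_hypotheses(results_by_hypothesis: dict[str, dict]) -> dict[str, PatternVerdict]:
    """Apply the conditioned-media pattern predicates to each hypothesis arm.

    The four predicates encode the observed transfer pattern: dense pre-aged
    tissues are not rescued by young conditioned media, sparse pre-aged
    tissues are not rescued either, while sparse young tissues are rescued by
    conditioned media from dense donors of either age.  A hypothesis matches
    only if all four hold.
    """
    verdicts: dict[str, PatternVerdict] = {}
    for hyp, result in results_by_hypothesis.items():
        arms = result["arms"]
        required = set(_MEDIA_ARMS)
        missing = required - set(arms)
        if missing:
            raise MissingArmError(f"hypothesis {hyp!r} missing arms: {sorted(missing)}")
        comparisons: dict[str, GroupComparison] = {}

        def resc(cm: str, ctrl: str, tag: str) -> bool:
            ok, cmp = _rescued(arms[cm], arms[ctrl])
            comparisons[tag] = cmp
            return ok

        predicates = {
            "aged_dense_not_rescued_by_young_cm":
                not resc("aged_100K_young_cm", "aged_100K_control", "aged_dense_young_cm"),
            "aged_sparse_not_rescued_by_young_cm":
                not resc("aged_1K_young_cm", "aged_1K_control", "aged_sparse_young_cm"),
            "young_sparse_rescued_by_young_cm":
                resc("young_1K_young_cm", "young_1K_control", "young_sparse_young_cm"),
            "young_sparse_rescued_by_aged_cm":
                resc("young_1K_aged_cm", "young_1K_control", "young_sparse_aged_cm"),
        }
        verdicts[hyp] = PatternVerdict(hypothesis=hyp, predicates=predicates,
                                       comparisons=comparisons)
    return verdicts
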