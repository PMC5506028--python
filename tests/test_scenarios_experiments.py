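"""Scenario configs, orchestration helpers, hypothesis verdicts, reporting."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from tissuefail.counting import Lifetime
from tissuefail.errors import ConfigurationError, MissingArmError, TissueFailError
from tissuefail.experiments import (
    ArmResult,
    donor_media_schedule,
    evaluate_hypotheses,
    run_arm,
    run_density_sweep,
    run_stress_sweep,
)
from tissuefail.mortality import compare_groups
from tissuefail.report import report
from tissuefail.scenarios import DENSITIES, ScenarioConfig, arm_seed


class TestScenarioConfig:
    def test_yaml_round_trip(self, tmp_path):
        scn = ScenarioConfig(density="10K", age_class="pre_aged", stress=True,
                             replicates=5, seed=9, params={"beta": 0.7})
        path = tmp_path / "scenario.yaml"
        scn.to_yaml(path)
        back = ScenarioConfig.from_yaml(path)
        assert back == scn
        assert back.config_hash() == scn.config_hash()

    def test_hash_sensitive_to_parameters(self):
        a = ScenarioConfig(seed=1)
        b = ScenarioConfig(seed=2)
        assert a.config_hash() != b.config_hash()

    @pytest.mark.parametrize("kw", [
        {"density": "2K"},
        {"age_class": "ancient"},
        {"media": "banana"},
        {"hypothesis": "teleportation"},
        {"aging": {"nonsense": 1}},
    ])
    def test_invalid_values_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            ScenarioConfig(**kw)

    def test_density_and_stress_modulate_params(self):
        base = ScenarioConfig(density="1K").build_params()
        assert base.n_cells == DENSITIES["1K"]
        assert base.dt == pytest.approx(1 / 12)
        stressed = ScenarioConfig(density="100K", stress=True).build_params()
        assert stressed.sigma == pytest.approx(2.0)
        assert stressed.dt == 1.0

    def test_media_arms_share_replicate_streams(self):
        a = ScenarioConfig(media="none", seed=3)
        b = ScenarioConfig(media="receive_young_100K", seed=3)
        assert arm_seed(a, 0).entropy == arm_seed(b, 0).entropy
        assert arm_seed(a, 0).entropy != arm_seed(a, 1).entropy


def fake_arm(lifetimes):
    scn = ScenarioConfig()
    return ArmResult(scenario=scn, series={},
                     lifetimes=[Lifetime(t) for t in lifetimes],
                     truth=[], records=pd.DataFrame())


def fake_matrix(rescue_map):
    base = [14.0, 15.0, 14.5, 15.5, 14.0, 15.0]
    arms = {}
    for name in ("aged_100K_control", "aged_100K_young_cm", "young_1K_control",
                 "young_1K_young_cm", "young_1K_aged_cm", "aged_1K_control",
                 "aged_1K_young_cm", "aged_1K_aged_cm"):
        shift = rescue_map.get(name, 0.0)
        arms[name] = fake_arm([v + shift for v in base])
    return {"hypothesis": "reception", "arms": arms,
            "lifetimes": pd.DataFrame(), "donor_schedules": {}}


class TestEvaluateHypotheses:
    def test_all_predicates_satisfied(self):
        res = fake_matrix({"young_1K_young_cm": 6.0, "young_1K_aged_cm": 4.0})
        verdict = evaluate_hypotheses({"reception": res})["reception"]
        assert verdict.overall
        assert verdict.violated == []

    def test_violating_predicate_named(self):
        res = fake_matrix({"young_1K_young_cm": 6.0, "young_1K_aged_cm": 4.0,
                           "aged_100K_young_cm": 6.0})
        verdict = evaluate_hypotheses({"reception": res})["reception"]
        assert not verdict.overall
        assert verdict.violated == ["aged_dense_not_rescued_by_young_cm"]

    def test_missing_arm_rejected(self):
        res = fake_matrix({})
        del res["arms"]["aged_1K_control"]
        with pytest.raises(MissingArmError):
            evaluate_hypotheses({"reception": res})


class TestDonorSchedule:
    def test_first_harvest_carries_two_days_of_conditioning(self):
        scn = ScenarioConfig(density="10K", age_class="young", seed=4)
        sched = donor_media_schedule(scn, 0, horizon_days=6)
        assert len(sched) == 6
        assert sched[0] > sched[1] > 0  # 2-day conditioned > 1-day refresh
        assert (sched >= 0).all()

    def test_schedules_differ_between_donor_ages(self):
        young = donor_media_schedule(
            ScenarioConfig(density="10K", age_class="young", seed=4), 0, 6)
        aged = donor_media_schedule(
            ScenarioConfig(density="10K", age_class="pre_aged", seed=4), 0, 6)
        assert not np.allclose(young, aged)


class TestDensitySweep:
    def test_small_sweep_structure(self):
        cfg = ScenarioConfig(replicates=2, seed=13, density="10K")
        res = run_density_sweep(cfg, densities=("10K",), age_classes=("young", "pre_aged"))
        assert set(res["lifetimes"]["age_class"]) == {"young", "pre_aged"}
        assert len(res["lifetimes"]) == 4
        assert len(res["tests"]) == 1
        assert set(res["trends"]["label"]) <= {"cooperative", "competitive", "non_interacting"}

    def test_single_replicate_runs_without_tests(self):
        cfg = ScenarioConfig(replicates=1, seed=13)
        arm = run_arm(replace(cfg, density="10K", age_class="young"))
        assert len(arm.lifetimes) == 1


class TestStressSweep:
    def test_oxidative_stress_resilience_pattern(self):
        """Stress shortens every group's lifetime; young dense tissues keep a
        significant advantage over pre-aged under stress, while at 1K the
        young advantage under stress is not significant."""
        cfg = ScenarioConfig(replicates=6, seed=19)
        res = run_stress_sweep(cfg, densities=("1K", "100K"))
        arms = res["arms"]
        for density in ("1K", "100K"):
            for age in ("young", "pre_aged"):
                assert (arms[(density, age, True)].lifetime_values.mean()
                        < arms[(density, age, False)].lifetime_values.mean())
        dense = compare_groups(arms[("100K", "young", True)].lifetime_values,
                               arms[("100K", "pre_aged", True)].lifetime_values)
        sparse = compare_groups(arms[("1K", "young", True)].lifetime_values,
                                arms[("1K", "pre_aged", True)].lifetime_values)
        assert dense.significant and dense.mean_a > dense.mean_b
        assert not sparse.significant


class TestReport:
    def test_empty_directory_rejected(self, tmp_path):
        with pytest.raises(TissueFailError):
            report(tmp_path)

    def test_summary_deterministic_and_recomputable(self, tmp_path):
        df = pd.DataFrame({
            "density": ["1K", "1K", "100K", "100K"],
            "age_class": ["young"] * 4,
            "replicate": [0, 1, 0, 1],
            "lifetime_days": [17.0, 19.0, 23.0, 24.0],
            "censored": [False] * 4,
        })
        df.to_csv(tmp_path / "density_lifetimes.csv", index=False)
        s1 = report(tmp_path)
        blob1 = (tmp_path / "summary.json").read_bytes()
        s2 = report(tmp_path)
        blob2 = (tmp_path / "summary.json").read_bytes()
        assert blob1 == blob2
        dense = [e for e in s1["sections"]["density"] if e["density"] == "100K"][0]
        assert dense["mean_lifetime_days"] == pytest.approx(23.5)
        assert s1["sections"]["media"] == "missing"
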