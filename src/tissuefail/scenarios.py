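"""Scenario configuration: densities, age classes, stress, media regimes.

A scenario bundles everything needed to reproduce one experimental arm:
construct density (1K/10K/100K cells per 5 µL), cell age class, oxidative
stress, the media regime, the aging hypothesis in force, model-parameter
overrides, replicate count, and a root seed.  Scenarios serialize to/from
YAML or JSON and hash deterministically.

Aging enters through competences: under the reception-loss hypothesis
(H-reception, the paper's conclusion) every pre-aged cell has its reception
competence ``c`` reduced to ``competence_deficit``; under the
production-loss hypothesis (H-production) its production competence ``p``
is reduced instead.  A senescence-marker flag is drawn per cell at the
assayed marker fractions (>50% of pre-aged, <1% of young cells) and carried
as metadata.  Oxidative stress multiplies the intrinsic damage rate by
``sigma_stress``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .errors import ConfigurationError
from .geometry import ConstructGeometry
from .imaging import ImagingProtocol
from .model import ModelParams, TissueState, make_state

__all__ = [
    "DENSITIES",
    "AGING_DEFAULTS",
    "ScenarioConfig",
    "arm_seed",
    "initial_state_for",
]

DENSITIES = {"1K": 1_000, "10K": 10_000, "100K": 100_000}

#: Aging / stress defaults (see docs/methods.md for the calibration rationale).
AGING_DEFAULTS = {
    "senescent_fraction_aged": 0.6,    # beta-gal-positive fraction, pre-aged (>50%)
    "senescent_fraction_young": 0.005, # beta-gal-positive fraction, young (<1%)
    "competence_deficit": 0.005,       # residual c (H-reception) or p (H-production) of pre-aged cells
    "d_aged_factor": 1.0,              # optional intrinsic-damage multiplier for pre-aged cells
    "sigma_stress": 2.0,               # damage multiplier under 0.2 mM H2O2
    "conditioning_days": 2,            # donor culture days before the first media harvest
}

_MEDIA_REGIMES = ("none", "receive_young_100K", "receive_aged_100K")
_HYPOTHESES = ("reception", "production")


@dataclass
class ScenarioConfig:
    """One experimental arm: what to simulate and how to measure it."""

    density: str = "100K"
    age_class: str = "young"            # young | pre_aged
    stress: bool = False
    media: str = "none"                 # none | receive_young_100K | receive_aged_100K
    hypothesis: str = "reception"       # reception | production
    replicates: int = 3
    seed: int = 0
    params: dict = field(default_factory=dict)    # ModelParams overrides
    aging: dict = field(default_factory=dict)     # AGING_DEFAULTS overrides
    protocol: dict = field(default_factory=dict)  # ImagingProtocol overrides

    def __post_init__(self) -> None:
        if self.density not in DENSITIES:
            raise ConfigurationError(f"density must be one of {sorted(DENSITIES)}")
        if self.age_class not in ("young", "pre_aged"):
            raise ConfigurationError("age_class must be 'young' or 'pre_aged'")
        if self.media not in _MEDIA_REGIMES:
            raise ConfigurationError(f"media must be one of {_MEDIA_REGIMES}")
        if self.hypothesis not in _HYPOTHESES:
            raise ConfigurationError(f"hypothesis must be one of {_HYPOTHESES}")
        unknown = set(self.aging) - set(AGING_DEFAULTS)
        if unknown:
            raise ConfigurationError(f"unknown aging keys: {sorted(unknown)}")

    # ---------------------------------------------------------------- params
    @property
    def n_cells(self) -> int:
        return DENSITIES[self.density]

    def aging_value(self, key: str):
        return self.aging.get(key, AGING_DEFAULTS[key])

    def build_params(self) -> ModelParams:
        """ModelParams for this arm, with density/stress/age effects applied."""
        kw = dict(self.params)
        geometry = kw.pop("geometry", None)
        if isinstance(geometry, dict):
            geometry = ConstructGeometry(**geometry)
        kw.setdefault("dt", 1.0 / 12.0 if self.density == "1K" else 1.0)
        p = ModelParams(
            n_cells=self.n_cells,
            geometry=geometry or ConstructGeometry(),
            seed=self.seed,
            **kw,
        )
        if self.stress:
            p.sigma = self.aging_value("sigma_stress")
        if self.age_class == "pre_aged":
            p.d = min(1.0, p.d * self.aging_value("d_aged_factor"))
        return p

    def build_protocol(self) -> ImagingProtocol:
        kw = dict(self.protocol)
        if self.density == "1K":
            kw.setdefault("mode", "max_projection")
        return ImagingProtocol(**kw)

    def media_policy(self):
        """Media policy for a standard (non-conditioned) run.

        The protocol replaces the medium at every staining, i.e. daily, so
        baseline arms run with fresh medium each day.  Conditioned-media
        arms get an explicit per-day G schedule from the experiments module.
        """
        return "fresh"

    # ------------------------------------------------------------- serialize
    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def arm_seed(scenario: ScenarioConfig, replicate: int) -> np.random.SeedSequence:
    """Derived seed stream for one replicate of one arm.

    The stream depends on (seed, density, age class, stress, replicate) but
    deliberately NOT on the media regime or hypothesis, so conditioned-media
    arms are pathwise paired with their controls.
    """
    key = (
        scenario.seed,
        DENSITIES[scenario.density],
        0 if scenario.age_class == "young" else 1,
        int(scenario.stress),
        replicate,
    )
    return np.random.SeedSequence(key)


def initial_state_for(
    scenario: ScenarioConfig,
    params: ModelParams,
    seed,
) -> TissueState:
    """Initial tissue state with class- and hypothesis-dependent competences."""
    rng = np.random.default_rng(seed)
    n = params.n_cells
    if scenario.age_class == "young":
        sen_frac = scenario.aging_value("senescent_fraction_young")
        c = np.ones(n)
        p = np.ones(n)
    else:
        sen_frac = scenario.aging_value("senescent_fraction_aged")
        deficit = scenario.aging_value("competence_deficit")
        if scenario.hypothesis == "reception":
            c = np.full(n, deficit)
            p = np.ones(n)
        else:
            c = np.ones(n)
            p = np.full(n, deficit)
    senescent = rng.random(n) < sen_frac
    state = make_state(params, c=c, p=p, senescent=senescent,
                       age_class=scenario.age_class, seed=rng)
    return state
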