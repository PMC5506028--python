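"""Emulator of the dead-cell staining/imaging protocol.

The wet protocol stains dead cells daily, takes z-stacks at a few points of
the gel (each stack covering a fixed fraction of the footprint), and counts
stained cells either per optical slice (dense constructs) or on the stack's
maximum projection (sparse constructs).  This module converts ground-truth
tissue states into exactly those per-stack count records: cells that died
since the previous imaging and fall inside a stack footprint are binned by
z-slice and detected with probability ``detection_gain``, with optional
Poisson count jitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InconsistentStateError
from .geometry import ConstructGeometry
from .model import TissueState, run

__all__ = [
    "ImagingProtocol",
    "StackFootprint",
    "ImagingRecord",
    "assign_footprints",
    "middle_slice_indices",
    "image_day",
    "generate_experiment",
    "records_to_frame",
    "imaging_schedule",
]


@dataclass(frozen=True)
class ImagingProtocol:
    """Stack geometry and detection characteristics of one imaging session.

    ``stack_fov_fraction`` is the fraction of the gel footprint covered by a
    single stack (default 1/8); with the default 3 stacks, 3/8 of the gel is
    sampled each day.  ``middle_slices`` central slices are counted in
    ``slices`` mode; ``max_projection`` mode sums each stack over all slices.
    """

    n_stacks: int = 3
    stack_fov_fraction: float = 1.0 / 8.0
    n_slices: int = 10
    middle_slices: int = 3
    mode: str = "slices"  # "slices" | "max_projection"
    detection_gain: float = 1.0
    count_noise: str = "none"  # "none" | "poisson"

    def __post_init__(self) -> None:
        if self.n_stacks < 1:
            raise ConfigurationError("n_stacks must be >= 1")
        if not (0 < self.stack_fov_fraction <= 1):
            raise ConfigurationError("stack_fov_fraction must be in (0, 1]")
        if self.n_stacks * self.stack_fov_fraction > 1 + 1e-12:
            raise ConfigurationError("n_stacks * stack_fov_fraction must be <= 1")
        if not (1 <= self.middle_slices <= self.n_slices):
            raise ConfigurationError("middle_slices must be in [1, n_slices]")
        if self.mode not in ("slices", "max_projection"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if not (0 < self.detection_gain <= 1):
            raise ConfigurationError("detection_gain must be in (0, 1]")
        if self.count_noise not in ("none", "poisson"):
            raise ConfigurationError(f"unknown count_noise {self.count_noise!r}")


@dataclass(frozen=True)
class StackFootprint:
    """Axis-aligned rectangular footprint of one z-stack (µm)."""

    x0: float
    y0: float
    width: float
    height: float

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (
            (x >= self.x0) & (x < self.x0 + self.width)
            & (y >= self.y0) & (y < self.y0 + self.height)
        )

    def overlaps(self, other: "StackFootprint") -> bool:
        return not (
            self.x0 + self.width <= other.x0 or other.x0 + other.width <= self.x0
            or self.y0 + self.height <= other.y0 or other.y0 + other.height <= self.y0
        )


@dataclass(frozen=True)
class ImagingRecord:
    """Dead cells detected in one field since the previous imaging."""

    replicate_id: int
    day: float
    stack_id: int
    slice_id: object  # int slice index (1-based) or "projection"
    dead_count: int
    mode: str = "slices"

    def __post_init__(self) -> None:
        if self.dead_count < 0:
            raise ValueError("dead_count must be >= 0")


def assign_footprints(
    geometry: ConstructGeometry,
    protocol: ImagingProtocol,
    seed=None,
    max_tries: int = 10_000,
) -> list[StackFootprint]:
    """Place ``n_stacks`` disjoint square stack footprints at seeded offsets.

    Each footprint has area ``stack_fov_fraction * footprint_area``.  Raises
    ConfigurationError when disjoint placement cannot be achieved.
    """
    rng = np.random.default_rng(seed)
    side = geometry.side_um
    s = side * math.sqrt(protocol.stack_fov_fraction)
    if s > side + 1e-9:
        raise ConfigurationError("stack footprint larger than the gel")
    if abs(s - side) < 1e-9:
        if protocol.n_stacks > 1:
            raise ConfigurationError("cannot place more than one full-gel stack")
        return [StackFootprint(0.0, 0.0, side, side)]
    # square footprints via rejection sampling with full restarts: early
    # placements can corner the remaining space, so stuck configurations are
    # discarded wholesale
    for _ in range(max_tries // 50):
        placed: list[StackFootprint] = []
        for _ in range(50):
            fp = StackFootprint(rng.uniform(0, side - s), rng.uniform(0, side - s), s, s)
            if not any(fp.overlaps(q) for q in placed):
                placed.append(fp)
            if len(placed) == protocol.n_stacks:
                return placed
    # dense packings (e.g. 5 stacks of 1/8) cannot always be realized with
    # disjoint axis-aligned squares; fall back to full-height strips of the
    # same area at seeded random offsets, feasible whenever
    # n_stacks * fraction <= 1
    w = side * protocol.stack_fov_fraction
    free = side - protocol.n_stacks * w
    if free < -1e-9:
        raise ConfigurationError(
            f"could not place {protocol.n_stacks} disjoint footprints of "
            f"fraction {protocol.stack_fov_fraction}"
        )
    offsets = np.sort(rng.uniform(0.0, 1.0, protocol.n_stacks)) * free
    return [
        StackFootprint(offsets[i] + i * w, 0.0, w, side)
        for i in range(protocol.n_stacks)
    ]


def slice_edges(geometry: ConstructGeometry, protocol: ImagingProtocol) -> np.ndarray:
    """z boundaries partitioning the thickness into ``n_slices`` equal bins."""
    return np.linspace(0.0, geometry.thickness_um, protocol.n_slices + 1)


def middle_slice_indices(n_slices: int, middle_slices: int) -> list[int]:
    """1-based indices of the central slices used for counting.

    For the default 3-of-10 this is [4, 5, 6]; for 3-of-11, [5, 6, 7].
    """
    center = math.ceil(n_slices / 2)
    start = max(1, min(center - middle_slices // 2, n_slices - middle_slices + 1))
    return list(range(start, start + middle_slices))


def image_day(
    prev_state: TissueState,
    state: TissueState,
    footprints: Sequence[StackFootprint],
    protocol: ImagingProtocol,
    rng: np.random.Generator,
    geometry: ConstructGeometry | None = None,
    replicate_id: int = 0,
) -> list[ImagingRecord]:
    """Emulate one staining/imaging session.

    Counts cells that died in (prev_state.day, state.day] inside each stack
    footprint, each detected with probability ``detection_gain``; ``slices``
    mode emits the central slices' counts per stack, ``max_projection`` mode
    one summed count per stack.
    """
    if prev_state.n_cells != state.n_cells or prev_state.positions is not state.positions and not np.array_equal(prev_state.positions, state.positions):
        raise InconsistentStateError("states do not share cell identities")
    geometry = geometry or ConstructGeometry()
    new_dead = prev_state.alive & ~state.alive
    pos = state.positions
    edges = slice_edges(geometry, protocol)
    mids = middle_slice_indices(protocol.n_slices, protocol.middle_slices)

    records: list[ImagingRecord] = []
    for stack_id, fp in enumerate(footprints, start=1):
        mask = new_dead & fp.contains(pos[:, 0], pos[:, 1])
        idx = np.flatnonzero(mask)
        if protocol.detection_gain < 1.0 and len(idx) > 0:
            idx = idx[rng.random(len(idx)) < protocol.detection_gain]
        z = pos[idx, 2]
        # slice index, 1-based; clip so z == thickness lands in the top slice
        zi = np.clip(np.digitize(z, edges[1:-1]) + 1, 1, protocol.n_slices)

        def _noisy(count: int) -> int:
            if protocol.count_noise == "poisson":
                return int(rng.poisson(count))
            return int(count)

        if protocol.mode == "slices":
            for sl in mids:
                records.append(
                    ImagingRecord(replicate_id, state.day, stack_id, sl,
                                  _noisy(int((zi == sl).sum())), "slices")
                )
        else:
            records.append(
                ImagingRecord(replicate_id, state.day, stack_id, "projection",
                              _noisy(len(idx)), "max_projection")
            )
    return records


def records_to_frame(records: Sequence[ImagingRecord]) -> pd.DataFrame:
    """Tabulate records with columns replicate, time_h, day, stack, slice, mode, dead_count."""
    return pd.DataFrame(
        {
            "replicate": [r.replicate_id for r in records],
            "time_h": [r.day * 24.0 for r in records],
            "day": [r.day for r in records],
            "stack": [r.stack_id for r in records],
            "slice": [r.slice_id for r in records],
            "mode": [r.mode for r in records],
            "dead_count": [r.dead_count for r in records],
        }
    )


def imaging_schedule(t_end: float, sub_daily_day1: bool = False) -> np.ndarray:
    """Imaging times in days up to ``t_end``.

    Dense constructs are imaged every 24 h.  Sparse (1K) constructs are
    additionally stained at 2, 4, 6 and 20 h on the first day.
    """
    days = np.arange(1.0, math.floor(t_end + 1e-9) + 1.0)
    if not sub_daily_day1:
        return days
    extra = np.array([2, 4, 6, 20]) / 24.0
    return np.concatenate([extra[extra < t_end], days])


def generate_experiment(
    scenario,
    n_replicates: int | None = None,
    media_policies=None,
):
    """Run the simulator and emulate daily imaging for one scenario.

    Returns ``(records DataFrame, truth)`` where ``truth`` is a list of
    per-replicate dicts holding the ground-truth PopulationTrajectory, the
    footprints used, and the initial state.  Replicates use distinct derived
    seed streams.  ``media_policies`` optionally overrides the medium policy
    per replicate (used for conditioned-media arms).  See
    :mod:`tissuefail.scenarios` for the scenario object.
    """
    from .scenarios import ScenarioConfig, arm_seed, initial_state_for

    assert isinstance(scenario, ScenarioConfig)
    reps = n_replicates if n_replicates is not None else scenario.replicates
    params = scenario.build_params()
    protocol = scenario.build_protocol()
    sub_daily = scenario.density == "1K"

    all_records: list[ImagingRecord] = []
    truth = []
    for rep in range(reps):
        ss = arm_seed(scenario, rep)
        place_seed, run_seed, image_seed, fp_seed = ss.spawn(4)
        state = initial_state_for(scenario, params, place_seed)
        policy = media_policies[rep] if media_policies is not None else scenario.media_policy()
        traj, snaps = run(
            params,
            state,
            media_policy=policy,
            rng=np.random.default_rng(run_seed),
            record_states=True,
        )
        footprints = assign_footprints(params.geometry, protocol, fp_seed)
        img_rng = np.random.default_rng(image_seed)
        sched = imaging_schedule(traj.times[-1], sub_daily_day1=sub_daily)
        # snapshots are indexed by step; map scheduled times onto steps
        time_to_idx = {round(t, 6): i for i, t in enumerate(traj.times)}
        prev_idx = 0
        for t in sched:
            key = round(float(t), 6)
            if key not in time_to_idx:
                continue
            i = time_to_idx[key]
            recs = image_day(
                snaps[prev_idx], snaps[i], footprints, protocol, img_rng,
                geometry=params.geometry, replicate_id=rep,
            )
            all_records.extend(recs)
            prev_idx = i
        truth.append({"trajectory": traj, "footprints": footprints, "initial_state": snaps[0]})

    return records_to_frame(all_records), truth
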