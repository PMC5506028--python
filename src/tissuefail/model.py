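"""Stochastic interdependent-failure simulator for engineered tissue constructs.

The model couples three independently switchable failure channels acting on
cells fixed in a hydrogel slab (no division, no migration):

* **intrinsic damage** — each functional cell fails per step with a baseline
  probability derived from the daily damage rate ``d`` (times a stress
  multiplier ``sigma``);
* **cooperative support** — functional neighbours within an interaction radius
  ``lambda_int`` and a shared-medium factor pool ``G`` reduce the intrinsic
  hazard through a support score ``s_i = c_i * (f_i + w_global * G)``, where
  ``f_i`` is the fraction of graph neighbours that are functional and ``c_i``
  the cell's reception competence;
* **threshold cascades** — a functional cell with at least one neighbour whose
  functional-neighbour fraction has dropped below ``theta`` fails, and such
  failures are swept synchronously to a fixed point, producing the abrupt
  tissue-level collapse characteristic of interdependence networks.

``beta = 0`` disables the cooperative hazard reduction and ``theta = 0``
disables cascades; with both off (and ``r = 0``) survival is i.i.d. Bernoulli
per day and the population decays exponentially — the non-interacting null.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .geometry import ConstructGeometry

__all__ = [
    "ModelParams",
    "TissueState",
    "PopulationTrajectory",
    "InteractionGraph",
    "place_cells",
    "build_interaction_graph",
    "support",
    "step_day",
    "run",
    "transfer_medium",
    "make_state",
]


@dataclass
class ModelParams:
    """Parameters of the interdependence model.

    Rates are per day; lengths in µm.  Defaults are the package's calibrated
    reference parameterization (see docs/methods.md).
    """

    n_cells: int
    geometry: ConstructGeometry = field(default_factory=ConstructGeometry)
    d: float = 0.2          # intrinsic daily failure probability per functional cell
    r: float = 0.0          # daily repair probability per failed cell
    sigma: float = 1.0      # stress multiplier on d (>= 1 under oxidative stress)
    lambda_int: float = 40.0  # interaction radius, µm
    theta: float = 0.05     # minimum functional-neighbour fraction before cascade failure
    beta: float = 0.8       # hazard-reduction strength of support
    w_global: float = 2.0   # weight of the shared-medium factor in support
    delta: float = 0.3      # daily decay fraction of the medium factor
    dt: float = 1.0         # days per step
    t_max: float = 60.0     # days
    seed: int = 0
    n_ref: int = 100_000    # reference cell count normalizing medium production

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not (0.0 <= self.d <= 1.0):
            raise ValueError("d must be in [0, 1]")
        if not (0.0 <= self.r <= 1.0):
            raise ValueError("r must be in [0, 1]")
        if not (0.0 <= self.theta <= 1.0):
            raise ValueError("theta must be in [0, 1]")
        if self.lambda_int < 0:
            raise ValueError("lambda_int must be >= 0")
        if self.sigma < 0 or self.beta < 0 or self.w_global < 0:
            raise ValueError("sigma, beta, w_global must be >= 0")
        if not (0.0 <= self.delta <= 1.0):
            raise ValueError("delta must be in [0, 1]")
        if self.dt <= 0 or self.t_max <= 0:
            raise ValueError("dt and t_max must be > 0")


@dataclass
class TissueState:
    """State of one construct at one time.

    Cell attributes are stored as parallel arrays of length ``n_cells``:
    positions (µm), alive flags, reception competence ``c``, production
    competence ``p`` (both in [0, 1]), and a senescence-marker flag.
    ``G`` is the pooled cooperative-factor level of the shared medium
    (arbitrary units, >= 0) and ``day`` the elapsed time in days.
    """

    positions: np.ndarray
    alive: np.ndarray
    c: np.ndarray
    p: np.ndarray
    senescent: np.ndarray
    age_class: str = "young"
    G: float = 0.0
    day: float = 0.0

    @property
    def n_cells(self) -> int:
        return len(self.alive)

    @property
    def n_live(self) -> int:
        return int(self.alive.sum())

    def light_copy(self) -> "TissueState":
        """Copy sharing the immutable per-cell arrays, with its own alive flags."""
        return replace(self, alive=self.alive.copy())


@dataclass
class PopulationTrajectory:
    """Per-step live-cell counts of one construct replicate."""

    times: np.ndarray       # days
    n: np.ndarray           # live counts
    new_deaths: np.ndarray  # net count decrease per interval (len = len(times) - 1)
    G: np.ndarray           # medium factor at each time
    censored: bool = False  # t_max reached before the 2% threshold

    @property
    def n0(self) -> int:
        return int(self.n[0])


def place_cells(n: int, geometry: ConstructGeometry, seed=None) -> np.ndarray:
    """Place ``n`` cells uniformly and independently inside the slab.

    ``seed`` may be an int, a SeedSequence, or a Generator.  Returns an
    ``(n, 3)`` float array of (x, y, z) in µm.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    pos = rng.random((n, 3))
    pos[:, 0] *= geometry.side_um
    pos[:, 1] *= geometry.side_um
    pos[:, 2] *= geometry.thickness_um
    return pos


class InteractionGraph:
    """Undirected fixed-radius interaction graph over static cell positions.

    Two cells interact iff their Euclidean distance is <= ``lambda_int``.
    Built once per construct (positions never change) with a k-d tree; the
    adjacency is held as CSR for fast repeated neighbour counts.
    """

    def __init__(self, adjacency: sparse.csr_matrix):
        self.adjacency = adjacency
        self.degree = np.asarray(adjacency.sum(axis=1)).ravel().astype(np.int64)

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    def neighbors(self, i: int) -> np.ndarray:
        a = self.adjacency
        return a.indices[a.indptr[i]:a.indptr[i + 1]]

    def functional_counts(self, alive: np.ndarray) -> np.ndarray:
        """Number of functional (alive) neighbours of every cell."""
        return self.adjacency @ alive.astype(np.float64)

    def functional_fraction(self, alive: np.ndarray) -> np.ndarray:
        """Fraction of each cell's neighbours that are functional (0 if isolated)."""
        f = np.zeros(self.n)
        has = self.degree > 0
        f[has] = self.functional_counts(alive)[has] / self.degree[has]
        return f


def build_interaction_graph(positions: np.ndarray, lambda_int: float) -> InteractionGraph:
    """Build the interaction graph: i~j iff ||x_i - x_j|| <= lambda_int, i != j."""
    if lambda_int < 0:
        raise ValueError("lambda_int must be >= 0")
    n = len(positions)
    if n == 0 or lambda_int == 0:
        return InteractionGraph(sparse.csr_matrix((n, n)))
    tree = cKDTree(positions)
    pairs = tree.query_pairs(r=lambda_int, output_type="ndarray")
    if len(pairs) == 0:
        return InteractionGraph(sparse.csr_matrix((n, n)))
    i = np.concatenate([pairs[:, 0], pairs[:, 1]])
    j = np.concatenate([pairs[:, 1], pairs[:, 0]])
    adj = sparse.csr_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
    return InteractionGraph(adj)


def support(state: TissueState, graph: InteractionGraph, params: ModelParams) -> np.ndarray:
    """Support score s_i = c_i * (f_i + w_global * G) for every cell.

    ``f_i`` is the functional fraction of i's neighbourhood (0 for isolated
    cells).  s_i >= 0 and s_i = 0 whenever c_i = 0.
    """
    f = graph.functional_fraction(state.alive)
    return state.c * (f + params.w_global * state.G)


def _cascade(alive: np.ndarray, graph: InteractionGraph, theta: float) -> np.ndarray:
    """Synchronous cascade sweeps to a fixed point.

    Each sweep kills every functional cell that has >= 1 neighbour and whose
    functional-neighbour fraction is below theta; sweeps repeat until no such
    cell remains.  Synchronous updating makes the fixed point independent of
    cell ordering.
    """
    if theta <= 0 or graph.n_edges == 0:
        return alive
    has_nb = graph.degree > 0
    while True:
        f = graph.functional_fraction(alive)
        violating = alive & has_nb & (f < theta)
        if not violating.any():
            return alive
        alive = alive & ~violating


def step_day(
    state: TissueState,
    graph: InteractionGraph,
    params: ModelParams,
    rng: np.random.Generator,
) -> TissueState:
    """Advance the tissue by one step of ``params.dt`` days.

    Order: (1) intrinsic failure with support-modulated hazard
    ``q_i = 1 - (1 - d*sigma)^(exp(-beta*s_i) * dt)``; (2) threshold-cascade
    sweeps to a fixed point; (3) repair of failed cells with probability
    ``r*dt``; (4) medium-factor update
    ``G <- G*(1 - delta*dt) + dt * sum_functional(p_i) / n_ref``.

    One uniform draw is consumed per cell per step regardless of its state so
    that trajectories with different theta/beta but the same seed remain
    pathwise coupled (used by the monotonicity tests).
    """
    n = state.n_cells
    alive = state.alive.copy()

    # (1) intrinsic failure
    s = support(state, graph, params)
    base = np.clip(1.0 - params.d * params.sigma, 0.0, 1.0)
    q = 1.0 - base ** (np.exp(-params.beta * s) * params.dt)
    u = rng.random(n)
    alive &= ~(u < q)

    # (2) cascade sweeps
    alive = _cascade(alive, graph, params.theta)

    # (3) repair
    if params.r > 0:
        u2 = rng.random(n)
        alive |= (~alive) & (u2 < params.r * params.dt)

    # (4) medium update: production scales with the number of functional
    # producers per (fixed) construct volume, normalized so a fully viable
    # reference-density construct produces one unit per day
    denom = max(params.n_ref, 1)
    G = state.G * (1.0 - params.delta * params.dt) + params.dt * float(state.p[alive].sum()) / denom

    return replace(state, alive=alive, G=G, day=state.day + params.dt)


def make_state(
    params: ModelParams,
    *,
    c=1.0,
    p=1.0,
    senescent=None,
    age_class: str = "young",
    seed=None,
) -> TissueState:
    """Construct an initial tissue state with uniformly placed cells.

    ``c`` and ``p`` may be scalars or arrays of length n_cells.
    """
    n = params.n_cells
    positions = place_cells(n, params.geometry, seed if seed is not None else params.seed)
    c_arr = np.broadcast_to(np.asarray(c, dtype=float), (n,)).copy()
    p_arr = np.broadcast_to(np.asarray(p, dtype=float), (n,)).copy()
    if not ((c_arr >= 0).all() and (c_arr <= 1).all() and (p_arr >= 0).all() and (p_arr <= 1).all()):
        raise ValueError("c and p must lie in [0, 1]")
    sen = np.zeros(n, dtype=bool) if senescent is None else np.asarray(senescent, dtype=bool)
    return TissueState(
        positions=positions,
        alive=np.ones(n, dtype=bool),
        c=c_arr,
        p=p_arr,
        senescent=sen,
        age_class=age_class,
    )


def _media_G_for_day(media_policy, day_index: int, current_G: float):
    """Resolve the medium level at an integer day boundary.

    ``media_policy``: None/"accumulate" (no intervention), "fresh" (daily
    replacement with plain medium, G = 0), or a sequence of per-day G values
    (conditioned medium; 0 beyond the end of the schedule).
    """
    if media_policy is None or (isinstance(media_policy, str) and media_policy == "accumulate"):
        return current_G
    if isinstance(media_policy, str):
        if media_policy == "fresh":
            return 0.0
        raise ValueError(f"unknown media policy {media_policy!r}")
    sched = np.asarray(media_policy, dtype=float)
    return float(sched[day_index]) if day_index < len(sched) else 0.0


def run(
    params: ModelParams,
    state: TissueState | None = None,
    *,
    media_policy=None,
    rng: np.random.Generator | None = None,
    record_states: bool = False,
    death_threshold: float = 0.02,
):
    """Simulate a construct until <= 2% of cells remain alive or ``t_max``.

    Parameters
    ----------
    state
        Initial state; defaults to all-young, fully competent cells placed
        with ``params.seed``.
    media_policy
        None/"accumulate", "fresh" (G reset to 0 at every integer-day
        boundary, emulating daily medium replacement), or a per-day sequence
        of G values (conditioned-medium schedule).
    record_states
        If True, a light state snapshot is kept at every step (shared
        positions, copied alive flags).

    Returns
    -------
    (PopulationTrajectory, list[TissueState])
        Trajectory flagged ``censored=True`` when t_max was reached before
        the live fraction dropped to the threshold.  Snapshots are
        ``[initial, after step 1, ...]`` when requested, else
        ``[initial, final]``.
    """
    if state is None:
        state = make_state(params, seed=params.seed)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    graph = build_interaction_graph(state.positions, params.lambda_int)

    threshold = death_threshold * params.n_cells
    times = [state.day]
    counts = [state.n_live]
    Gs = [state.G]
    snapshots = [state.light_copy()]

    eps = 1e-6
    day_index = int(round(state.day))
    while state.day < params.t_max - eps and state.n_live > threshold:
        # medium intervention at integer-day boundaries (including day 0)
        if abs(state.day - round(state.day)) < eps:
            day_index = int(round(state.day))
            state = replace(state, G=_media_G_for_day(media_policy, day_index, state.G))
        state = step_day(state, graph, params, rng)
        times.append(state.day)
        counts.append(state.n_live)
        Gs.append(state.G)
        if record_states:
            snapshots.append(state.light_copy())

    if not record_states:
        snapshots.append(state.light_copy())

    n = np.array(counts, dtype=float)
    traj = PopulationTrajectory(
        times=np.array(times, dtype=float),
        n=n,
        new_deaths=-np.diff(n),
        G=np.array(Gs, dtype=float),
        censored=state.n_live > threshold,
    )
    return traj, snapshots


def transfer_medium(donor: TissueState, recipient: TissueState) -> TissueState:
    """Replace the recipient's medium with the donor's conditioned medium.

    Only the pooled factor level G is carried over; all other recipient
    fields are unchanged.
    """
    return replace(recipient, G=donor.G)
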