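"""Continuous-time stochastic simulation of personalized Boolean models.

Dynamics are asynchronous continuous-time Boolean dynamics (the standard
stochastic logical-model semantics): each non-forced node whose current
value disagrees with its rule's evaluation is eligible to flip, with an
exponential waiting time at the node's up rate (0→1 flips, when the rule
evaluates to 1) or down rate (1→0 flips, when the rule evaluates to 0).
Forced nodes never flip.  The resulting jump process is simulated either by
a Gillespie ensemble (Monte Carlo estimate of per-node activity, i.e. the
probability of being ON at each time) or solved exactly from the master
equation over the 2^n state space of non-forced nodes.

Per-node activity curves are integrated by the trapezoid rule into the AUC
used by the knockout statistic (see :mod:`boolomics.perturb`).  The
trapezoid of the ensemble-mean curve equals the mean of per-trajectory
trapezoids exactly, so a single AUC implementation covers both readings.

Time is in arbitrary units throughout; rates are reciprocal arbitrary time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import expm_multiply

from .logic import BooleanNetwork, truth_table, write_rules

if TYPE_CHECKING:  # pragma: no cover
    from .personalize import PersonalizedModel

__all__ = [
    "TransitionRates",
    "SimulationConfig",
    "ActivityCurve",
    "SteadyState",
    "TrajectoryPath",
    "gillespie_trajectory",
    "estimate_activity",
    "exact_master_equation",
    "exact_distribution",
    "detect_steady_state",
    "compute_auc",
    "activity_frame",
    "auc_frame",
]

EXACT_STATE_CAP = 12  # default limit on non-forced nodes for the exact solver


@dataclass(frozen=True)
class TransitionRates:
    """Per-node flip rates: ``up`` for 0→1 (rule ON), ``down`` for 1→0 (rule OFF)."""

    up: Mapping[str, float]
    down: Mapping[str, float]

    def __post_init__(self):
        object.__setattr__(self, "up", dict(self.up))
        object.__setattr__(self, "down", dict(self.down))
        if set(self.up) != set(self.down):
            raise ValueError("up and down rates must cover the same node set")
        for name, rates in (("up", self.up), ("down", self.down)):
            for node, r in rates.items():
                if not np.isfinite(r) or r <= 0:
                    raise ValueError(
                        f"{name} rate for {node!r} must be strictly positive and finite, got {r}"
                    )


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation window, grid, ensemble size, seed and steady-state detection.

    ``steady_window`` is the trailing fraction of the grid over which the
    activity spread must stay within ``steady_tol`` to call steady state.
    """

    t_max: float = 50.0
    n_grid: int = 101
    n_trajectories: int = 5000
    seed: int = 0
    steady_tol: float = 0.01
    steady_window: float = 0.2

    def __post_init__(self):
        if not (self.t_max > 0):
            raise ValueError("t_max must be positive")
        if self.n_grid < 2:
            raise ValueError("n_grid must be at least 2")
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be at least 1")
        if not (self.steady_tol > 0):
            raise ValueError("steady_tol must be positive")
        if not (0 < self.steady_window < 1):
            raise ValueError("steady_window must lie in (0, 1)")

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.t_max, self.n_grid)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "t_max": float(self.t_max),
                    "n_grid": int(self.n_grid),
                    "n_trajectories": int(self.n_trajectories),
                    "seed": int(self.seed),
                    "steady_tol": float(self.steady_tol),
                    "steady_window": float(self.steady_window),
                },
                fh,
            )


@dataclass(frozen=True)
class ActivityCurve:
    """Probability-of-ON for one node on a time grid, with optional MC stderr."""

    node: str
    times: np.ndarray
    activity: np.ndarray
    stderr: Optional[np.ndarray] = None

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        activity = np.asarray(self.activity, dtype=float)
        if times.ndim != 1 or times.shape != activity.shape:
            raise ValueError("times and activity must be 1-D arrays of equal length")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(activity < -1e-9) or np.any(activity > 1 + 1e-9):
            raise ValueError("activity values must lie in [0, 1]")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "activity", np.clip(activity, 0.0, 1.0))
        if self.stderr is not None:
            object.__setattr__(self, "stderr", np.asarray(self.stderr, dtype=float))


@dataclass(frozen=True)
class SteadyState:
    reached: bool
    level: float


@dataclass(frozen=True)
class TrajectoryPath:
    """Piecewise-constant state path: state ``states[i]`` holds on [times[i], times[i+1])."""

    nodes: Tuple[str, ...]
    times: np.ndarray
    states: np.ndarray  # (n_jumps + 1, n_nodes), uint8

    def state_at(self, t: float) -> np.ndarray:
        i = int(np.searchsorted(self.times, t, side="right")) - 1
        return self.states[max(i, 0)]


# ---------------------------------------------------------------------------
# Compiled representation
# ---------------------------------------------------------------------------


class _Compiled:
    """Arrays for fast rule evaluation: truth tables, dependents, rates."""

    def __init__(self, model: "PersonalizedModel"):
        net = model.network
        self.names: Tuple[str, ...] = net.nodes
        n = len(self.names)
        self.n = n
        index = {name: i for i, name in enumerate(self.names)}

        self.forced = np.zeros(n, dtype=bool)
        self.forced_values = np.zeros(n, dtype=np.uint8)
        for node, v in model.forcings.items():
            self.forced[index[node]] = True
            self.forced_values[index[node]] = v

        self.reg_idx: List[np.ndarray] = []
        self.tables: List[np.ndarray] = []
        self.shifts: List[np.ndarray] = []
        dependents: List[set] = [set() for _ in range(n)]
        for i, rule in enumerate(net.rules):
            order = rule.regulators
            self.reg_idx.append(np.array([index[r] for r in order], dtype=np.intp))
            self.tables.append(truth_table(rule, order))
            self.shifts.append(np.arange(len(order), dtype=np.intp))
            for r in order:
                dependents[index[r]].add(i)
        self.dependents = [np.array(sorted(d), dtype=np.intp) for d in dependents]

        self.up = np.zeros(n)
        self.down = np.zeros(n)
        for node in self.names:
            i = index[node]
            if not self.forced[i]:
                self.up[i] = model.rates.up[node]
                self.down[i] = model.rates.down[node]

        self.init_p = np.empty(n)
        for node, p in model.initial_p_on.items():
            self.init_p[index[node]] = p

    def rule_value(self, state: np.ndarray, i: int) -> int:
        idx = int((state[self.reg_idx[i]].astype(np.intp) << self.shifts[i]).sum())
        return int(self.tables[i][idx])

    def all_rule_values(self, state: np.ndarray) -> np.ndarray:
        return np.array([self.rule_value(state, i) for i in range(self.n)], dtype=np.uint8)


def _rng(seed: int, stream: int) -> np.random.Generator:
    # counter-based stream derivation: trajectory i is reproducible in isolation
    return np.random.default_rng([int(seed), int(stream)])


def _initial_state(comp: _Compiled, rng: np.random.Generator) -> np.ndarray:
    state = (rng.random(comp.n) < comp.init_p).astype(np.uint8)
    state[comp.forced] = comp.forced_values[comp.forced]
    return state


def _propensities(comp: _Compiled, state: np.ndarray, rv: np.ndarray) -> np.ndarray:
    prop = np.where(
        (state == 0) & (rv == 1), comp.up, np.where((state == 1) & (rv == 0), comp.down, 0.0)
    )
    prop[comp.forced] = 0.0
    return prop


def _simulate(comp, rng, t_max, grid=None, counts=None, record=False):
    """Run one trajectory.

    If ``grid``/``counts`` are given, add per-grid-point node occupancy into
    ``counts`` (shape n_nodes × n_grid).  If ``record``, return the full
    piecewise-constant path (times, states).
    """
    state = _initial_state(comp, rng)
    rv = comp.all_rule_values(state)
    prop = _propensities(comp, state, rv)
    t = 0.0
    gi = 0
    times = [0.0]
    states = [state.copy()] if record else None
    n_grid = len(grid) if grid is not None else 0

    while True:
        total = prop.sum()
        if total <= 0.0:
            break  # absorbing: state holds until t_max
        t_next = t + rng.exponential(1.0 / total)
        if counts is not None and gi < n_grid:
            j = int(np.searchsorted(grid, min(t_next, t_max), side="left"))
            if j > gi:
                counts[:, gi:j] += state[:, None]
                gi = j
        if t_next >= t_max:
            t = t_max
            break
        # pick the flipping node proportionally to its propensity
        r = rng.random() * total
        k = int(np.searchsorted(np.cumsum(prop), r, side="right"))
        k = min(k, comp.n - 1)
        state[k] ^= 1
        affected = comp.dependents[k]
        for d in affected:
            rv[d] = comp.rule_value(state, d)
        touch = np.append(affected, k)
        prop[touch] = _propensities(comp, state, rv)[touch]
        t = t_next
        times.append(t)
        if record:
            states.append(state.copy())

    if counts is not None and gi < n_grid:
        counts[:, gi:] += state[:, None]
    if record:
        return np.array(times), np.array(states, dtype=np.uint8)
    return None


def gillespie_trajectory(
    model: "PersonalizedModel", config: SimulationConfig, trajectory_index: int
) -> TrajectoryPath:
    """One exact-jump trajectory; bit-identical for identical (seed, index)."""
    comp = _Compiled(model)
    rng = _rng(config.seed, trajectory_index)
    times, states = _simulate(comp, rng, config.t_max, record=True)
    return TrajectoryPath(comp.names, times, states)


def estimate_activity(
    model: "PersonalizedModel", config: SimulationConfig
) -> Dict[str, ActivityCurve]:
    """Monte Carlo activity curves: ensemble fraction ON at each grid time.

    stderr is the binomial standard error sqrt(a(1-a)/n).
    """
    comp = _Compiled(model)
    grid = config.times
    counts = np.zeros((comp.n, config.n_grid))
    for i in range(config.n_trajectories):
        _simulate(comp, _rng(config.seed, i), config.t_max, grid=grid, counts=counts)
    activity = counts / config.n_trajectories
    stderr = np.sqrt(activity * (1.0 - activity) / config.n_trajectories)
    curves = {}
    for j, node in enumerate(comp.names):
        if comp.forced[j]:
            a = np.full(config.n_grid, float(comp.forced_values[j]))
            s = np.zeros(config.n_grid)
        else:
            a, s = activity[j], stderr[j]
        curves[node] = ActivityCurve(node, grid, a, s)
    return curves


# ---------------------------------------------------------------------------
# Exact master-equation solver
# ---------------------------------------------------------------------------

_STRUCTURE_CACHE: Dict[Tuple[str, Tuple[Tuple[str, int], ...]], tuple] = {}


def _transition_structure(model: "PersonalizedModel"):
    """Fixed (rows, cols, node, direction) transition skeleton for a network+forcings.

    Cached on the rule text plus forcing assignment: patients sharing a
    network and forcing set differ only in rates and initial probabilities,
    which are applied on top of the skeleton by the caller.
    """
    key = (write_rules(model.network), tuple(sorted(model.forcings.items())))
    hit = _STRUCTURE_CACHE.get(key)
    if hit is not None:
        return hit

    comp = _Compiled(model)
    free = np.flatnonzero(~comp.forced)
    nf = len(free)
    S = 1 << nf
    bits = ((np.arange(S)[:, None] >> np.arange(nf)) & 1).astype(np.uint8)  # S × nf
    full = np.empty((S, comp.n), dtype=np.uint8)
    full[:, free] = bits
    full[:, comp.forced] = comp.forced_values[comp.forced]

    rows_parts, cols_parts, node_parts, up_parts = [], [], [], []
    states = np.arange(S)
    for j, i in enumerate(free):
        regs = comp.reg_idx[i]
        idx = (full[:, regs].astype(np.intp) << comp.shifts[i]).sum(axis=1)
        rv = comp.tables[i][idx]
        cur = bits[:, j]
        up_mask = (cur == 0) & (rv == 1)
        dn_mask = (cur == 1) & (rv == 0)
        for mask, is_up in ((up_mask, True), (dn_mask, False)):
            src = states[mask]
            if src.size == 0:
                continue
            rows_parts.append(src ^ (1 << j))
            cols_parts.append(src)
            node_parts.append(np.full(src.size, i, dtype=np.intp))
            up_parts.append(np.full(src.size, is_up))

    if rows_parts:
        rows = np.concatenate(rows_parts)
        cols = np.concatenate(cols_parts)
        node_of = np.concatenate(node_parts)
        is_up = np.concatenate(up_parts)
    else:
        rows = cols = node_of = np.empty(0, dtype=np.intp)
        is_up = np.empty(0, dtype=bool)
    result = (comp.names, comp.forced, free, bits, rows, cols, node_of, is_up)
    if len(_STRUCTURE_CACHE) > 64:
        _STRUCTURE_CACHE.clear()
    _STRUCTURE_CACHE[key] = result
    return result


def exact_distribution(
    model: "PersonalizedModel", config: SimulationConfig, cap: int = EXACT_STATE_CAP
):
    """Transient distribution of the jump process on the time grid.

    Returns ``(times, P, free_nodes, bits)`` where ``P[t_i, s]`` is the
    probability of free-node bit pattern ``s`` at grid time ``t_i``.
    """
    n_free = len(model.network.nodes) - len(model.forcings)
    if n_free > cap:
        raise ValueError(
            f"{n_free} non-forced nodes exceed the exact-solver cap of {cap}; "
            "use the Monte Carlo estimator (estimate_activity) instead"
        )
    names, forced, free, bits, rows, cols, node_of, is_up = _transition_structure(model)
    S = 1 << len(free)

    # rates and initial probabilities come from *this* model, not the cache
    n = len(names)
    up = np.zeros(n)
    down = np.zeros(n)
    for node, r in model.rates.up.items():
        up[names.index(node)] = r
    for node, r in model.rates.down.items():
        down[names.index(node)] = r
    init_p = np.array([model.initial_p_on[node] for node in names])

    data = np.where(is_up, up[node_of], down[node_of])
    # dp/dt = Q p : off-diagonal Q[to, from] = rate, diagonal balances columns
    diag = np.zeros(S)
    np.subtract.at(diag, cols, data)
    q = coo_matrix(
        (np.concatenate([data, diag]), (np.concatenate([rows, np.arange(S)]), np.concatenate([cols, np.arange(S)]))),
        shape=(S, S),
    ).tocsr()

    p0 = np.ones(S)
    for j, i in enumerate(free):
        pj = init_p[i]
        p0 *= np.where(bits[:, j] == 1, pj, 1.0 - pj)

    P = expm_multiply(q, p0, start=0.0, stop=config.t_max, num=config.n_grid, endpoint=True)
    free_nodes = tuple(names[i] for i in free)
    return config.times, np.asarray(P), free_nodes, bits


def exact_master_equation(
    model: "PersonalizedModel", config: SimulationConfig, cap: int = EXACT_STATE_CAP
) -> Dict[str, ActivityCurve]:
    """Exact per-node activity curves from the master equation (deterministic)."""
    times, P, free_nodes, bits = exact_distribution(model, config, cap=cap)
    curves: Dict[str, ActivityCurve] = {}
    for j, node in enumerate(free_nodes):
        a = P @ bits[:, j].astype(float)
        curves[node] = ActivityCurve(node, times, np.clip(a, 0.0, 1.0))
    for node, v in model.forcings.items():
        curves[node] = ActivityCurve(node, times, np.full(len(times), float(v)))
    return {node: curves[node] for node in model.network.nodes}


# ---------------------------------------------------------------------------
# Curve summaries
# ---------------------------------------------------------------------------


def detect_steady_state(curve: ActivityCurve, config: SimulationConfig) -> SteadyState:
    """Steady iff activity spread over the trailing window is within tolerance."""
    t0, t1 = curve.times[0], curve.times[-1]
    sel = curve.times >= t1 - config.steady_window * (t1 - t0)
    window = curve.activity[sel]
    reached = bool(window.max() - window.min() <= config.steady_tol)
    return SteadyState(reached, float(window.mean()))


def compute_auc(curve: ActivityCurve) -> float:
    """Trapezoidal integral of activity over the curve's time window."""
    if len(curve.times) < 2:
        raise ValueError("AUC requires at least 2 grid points")
    return float(np.trapezoid(curve.activity, curve.times))


def activity_frame(
    curves: Mapping[str, ActivityCurve], sample: Optional[str] = None
) -> pd.DataFrame:
    """Long-format (sample, node, time, activity[, stderr]) table."""
    rows = []
    for node, c in curves.items():
        df = pd.DataFrame({"node": node, "time": c.times, "activity": c.activity})
        if c.stderr is not None:
            df["stderr"] = c.stderr
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    if sample is not None:
        out.insert(0, "sample", sample)
    return out


def auc_frame(
    curves: Mapping[str, ActivityCurve], sample: Optional[str] = None
) -> pd.DataFrame:
    out = pd.DataFrame(
        {"node": list(curves.keys()), "auc": [compute_auc(c) for c in curves.values()]}
    )
    if sample is not None:
        out.insert(0, "sample", sample)
    return out
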