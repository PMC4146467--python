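"""Synchronous dynamics: trajectories, attractors, basins, robustness scans.

Under the synchronous update rule every non-input node simultaneously reads
its regulators' states at time *t* and takes the tabulated output at
*t + 1*; input nodes hold their value; clamped nodes take their clamp value
at every step from *t = 1* onward.  The configuration space is finite, so
every trajectory ends on a periodic attractor; the number of steps before
the trajectory first enters its cycle is the transient.

Two independent code paths compute the same dynamics:

* :func:`step` / :func:`find_attractor` — plain-Python reference versions
  (per-node table lookups, hash-map cycle detection);
* :class:`Engine` — a vectorized implementation operating on integer state
  codes, optionally through a precomputed full transition map, used by
  basin statistics and ensemble averaging.

The reference versions double as oracles for the vectorized path in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np

from .network import LogicalNetwork, NetworkState
from .perturbations import PerturbationSpec, WT

__all__ = [
    "Trajectory",
    "AttractorRecord",
    "AttractorCatalogue",
    "ICPolicy",
    "Engine",
    "step",
    "simulate",
    "find_attractor",
    "basin_statistics",
    "max_transient",
    "rule_perturbation_scan",
    "ComparisonRecord",
]

#: largest configuration-space size for which a full transition map is built
MAP_LIMIT = 1 << 24


# ---------------------------------------------------------------------------
# reference (scalar) implementation


def step(
    net: LogicalNetwork,
    state: NetworkState | Sequence[int],
    clamps: PerturbationSpec = WT,
) -> NetworkState:
    """One synchronous update (all reads before any write)."""
    if not isinstance(state, NetworkState):
        state = NetworkState(state)
    state.validate_for(net)
    clamps.validate_for(net)
    clamp = clamps.as_dict()
    values = state.values
    out = []
    for i, node in enumerate(net.nodes):
        if node.name in clamp:
            out.append(clamp[node.name])
        elif node.is_input:
            out.append(values[i])
        else:
            tab = net.tables[node.name]
            combo = tuple(values[net.index(r)] for r in node.regulators)
            out.append(int(tab.outputs[tab.row_index(combo)]))
    return NetworkState(out)


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered sequence of states under a fixed clamp set."""

    states: tuple[NetworkState, ...]
    clamps: PerturbationSpec = WT

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, t: int) -> NetworkState:
        return self.states[t]

    def node_series(self, net: LogicalNetwork, name: str) -> np.ndarray:
        i = net.index(name)
        return np.array([s[i] for s in self.states], dtype=np.int8)


def simulate(
    net: LogicalNetwork,
    initial: NetworkState | Sequence[int],
    t_max: int,
    clamps: PerturbationSpec = WT,
) -> Trajectory:
    """Trajectory of length ``t_max + 1`` starting at ``initial``."""
    if t_max < 0:
        raise ValueError("t_max must be >= 0")
    if not isinstance(initial, NetworkState):
        initial = NetworkState(initial)
    initial.validate_for(net)
    engine = Engine(net, clamps, build_map=False)
    vals = initial.as_array()[None, :]
    states = [initial]
    for _ in range(t_max):
        vals = engine.step_values(vals)
        states.append(NetworkState(vals[0]))
    return Trajectory(tuple(states), clamps)


@dataclass(frozen=True)
class AttractorRecord:
    """A minimal cycle, stored starting from its canonical representative.

    The canonical representative is the lexicographically smallest state
    vector on the cycle, so two independently detected attractors are equal
    iff their records compare equal.
    """

    cycle: tuple[NetworkState, ...]

    @property
    def period(self) -> int:
        return len(self.cycle)

    @property
    def representative(self) -> NetworkState:
        return self.cycle[0]

    def node_cycle(self, net: LogicalNetwork, name: str) -> np.ndarray:
        i = net.index(name)
        return np.array([s[i] for s in self.cycle], dtype=np.int8)

    def cycle_mean(self, net: LogicalNetwork, name: str) -> float:
        """Time average of one node's level over the cycle."""
        return float(self.node_cycle(net, name).mean())


def find_attractor(
    net: LogicalNetwork,
    initial: NetworkState | Sequence[int],
    clamps: PerturbationSpec = WT,
) -> tuple[int, AttractorRecord]:
    """Exact transient length and attractor by hash-map state revisit.

    Returns ``(transient, record)`` where ``transient`` is the first time
    index at which the trajectory is on the returned cycle.  The period is
    minimal because the cycle closes at the *first* revisit of any state.
    """
    if not isinstance(initial, NetworkState):
        initial = NetworkState(initial)
    initial.validate_for(net)
    seen: dict[tuple[int, ...], int] = {}
    path: list[NetworkState] = []
    state = initial
    t = 0
    while state.values not in seen:
        seen[state.values] = t
        path.append(state)
        state = step(net, state, clamps)
        t += 1
    start = seen[state.values]
    cycle = path[start:]
    k = min(range(len(cycle)), key=lambda j: cycle[j].values)
    cycle = tuple(cycle[k:] + cycle[:k])
    return start, AttractorRecord(cycle)


# ---------------------------------------------------------------------------
# vectorized engine


class Engine:
    """Vectorized synchronous-update engine over integer state codes.

    States are encoded in mixed radix with node 0 as the most significant
    digit, so the integer order of codes coincides with lexicographic order
    of state vectors.  When the configuration space has at most
    :data:`MAP_LIMIT` states a full transition map (one ``int64`` per state)
    is precomputed, after which a time step is a single gather.
    """

    def __init__(
        self,
        net: LogicalNetwork,
        clamps: PerturbationSpec = WT,
        build_map: bool | None = None,
    ):
        clamps.validate_for(net)
        self.net = net
        self.clamps = clamps
        self.n = net.n_nodes
        self.arities = net.arities
        w = np.ones(self.n, dtype=np.int64)
        for i in range(self.n - 2, -1, -1):
            w[i] = w[i + 1] * self.arities[i + 1]
        self.state_weights = w
        self.n_states = int(w[0] * self.arities[0]) if self.n else 1
        self._tables: list[tuple[np.ndarray, np.ndarray, np.ndarray] | None] = []
        clamp = clamps.as_dict()
        self._clamp_idx = np.array(
            [net.index(name) for name in clamp], dtype=np.int64
        )
        self._clamp_vals = np.array(list(clamp.values()), dtype=np.int8)
        for node in net.nodes:
            if node.is_input:
                self._tables.append(None)
                continue
            tab = net.tables[node.name]
            reg_idx = np.array([net.index(r) for r in node.regulators], dtype=np.int64)
            rw = np.ones(len(reg_idx), dtype=np.int64)
            for i in range(len(reg_idx) - 2, -1, -1):
                rw[i] = rw[i + 1] * tab.reg_arities[i + 1]
            self._tables.append((reg_idx, rw, tab.outputs))
        if build_map is None:
            build_map = self.n_states <= MAP_LIMIT
        self._map: np.ndarray | None = None
        if build_map:
            if self.n_states > MAP_LIMIT:
                raise ValueError(
                    f"state space of {self.n_states} states exceeds map limit {MAP_LIMIT}"
                )
            self._map = self._build_map()

    # -- state coding -----------------------------------------------------
    def encode(self, values: np.ndarray) -> np.ndarray:
        """(M, N) value array -> (M,) int64 codes."""
        return np.asarray(values, dtype=np.int64) @ self.state_weights

    def decode(self, codes: np.ndarray) -> np.ndarray:
        """(M,) codes -> (M, N) int8 value array."""
        codes = np.asarray(codes, dtype=np.int64)
        out = np.empty((codes.size, self.n), dtype=np.int8)
        for i in range(self.n):
            out[:, i] = (codes // self.state_weights[i]) % self.arities[i]
        return out

    # -- stepping ---------------------------------------------------------
    def step_values(self, values: np.ndarray) -> np.ndarray:
        """Synchronous update of an (M, N) batch of state vectors."""
        values = np.asarray(values, dtype=np.int8)
        out = np.empty_like(values)
        for i, entry in enumerate(self._tables):
            if entry is None:
                out[:, i] = values[:, i]
            else:
                reg_idx, rw, outputs = entry
                idx = values[:, reg_idx].astype(np.int64) @ rw
                out[:, i] = outputs[idx]
        if self._clamp_idx.size:
            out[:, self._clamp_idx] = self._clamp_vals
        return out

    def step_codes(self, codes: np.ndarray) -> np.ndarray:
        if self._map is not None:
            return self._map[codes]
        return self.encode(self.step_values(self.decode(codes)))

    def advance(self, codes: np.ndarray, t: int) -> np.ndarray:
        for _ in range(t):
            codes = self.step_codes(codes)
        return codes

    def _build_map(self, chunk: int = 1 << 20) -> np.ndarray:
        nxt = np.empty(self.n_states, dtype=np.int64)
        for lo in range(0, self.n_states, chunk):
            hi = min(lo + chunk, self.n_states)
            codes = np.arange(lo, hi, dtype=np.int64)
            nxt[lo:hi] = self.encode(self.step_values(self.decode(codes)))
        return nxt

    def node_digit(self, codes: np.ndarray, name: str) -> np.ndarray:
        """Extract one node's level from a code array."""
        i = self.net.index(name)
        return ((np.asarray(codes, dtype=np.int64) // self.state_weights[i])
                % self.arities[i]).astype(np.int8)


# ---------------------------------------------------------------------------
# initial-condition policies


@dataclass(frozen=True)
class ICPolicy:
    """Initial-condition space: some nodes fixed (and clamped), the rest free.

    Fixed nodes are pinned to their value for the whole evolution and are
    excluded from the free dimensions of the initial-condition space; free
    nodes are drawn independently and uniformly over their levels.  The
    speract-activated policy of the SASP analyses fixes the ligand node at 1.
    """

    fixed: tuple[tuple[str, int], ...] = ()

    def as_clamps(self, label: str = "policy") -> PerturbationSpec:
        return PerturbationSpec(tuple(self.fixed), label)

    def free_indices(self, net: LogicalNetwork) -> np.ndarray:
        fixed_names = {n for n, _ in self.fixed}
        return np.array(
            [i for i, node in enumerate(net.nodes) if node.name not in fixed_names],
            dtype=np.int64,
        )

    def space_size(self, net: LogicalNetwork) -> int:
        free = self.free_indices(net)
        return int(math.prod(int(net.arities[i]) for i in free))

    def _fixed_code(self, engine: Engine) -> int:
        code = 0
        for name, value in self.fixed:
            i = engine.net.index(name)
            if not 0 <= value < engine.net.nodes[i].arity:
                raise ValueError(f"fixed value {name}={value} out of range")
            code += value * int(engine.state_weights[i])
        return code

    def sample_codes(self, engine: Engine, n: int, rng: np.random.Generator) -> np.ndarray:
        if n < 1:
            raise ValueError("sample size must be >= 1")
        net = engine.net
        codes = np.full(n, self._fixed_code(engine), dtype=np.int64)
        for i in self.free_indices(net):
            digits = rng.integers(0, int(net.arities[i]), size=n, dtype=np.int64)
            codes += digits * engine.state_weights[i]
        return codes

    def enumerate_codes(self, engine: Engine) -> np.ndarray:
        net = engine.net
        free = self.free_indices(net)
        total = self.space_size(net)
        codes = np.full(total, self._fixed_code(engine), dtype=np.int64)
        div = 1
        for i in free[::-1]:
            a = int(net.arities[i])
            digits = (np.arange(total, dtype=np.int64) // div) % a
            codes += digits * engine.state_weights[i]
            div *= a
        return codes


# ---------------------------------------------------------------------------
# basin statistics


@dataclass
class AttractorCatalogue:
    """Attractors with basin fractions and transient statistics."""

    records: list[AttractorRecord]
    basin_counts: np.ndarray
    transient_max: int
    transient_mean: float
    exhaustive: bool
    n_ic: int
    seed: int | None = None
    clamps: PerturbationSpec = WT
    transient_counts: np.ndarray | None = None  # histogram indexed by length

    @property
    def basin_fractions(self) -> np.ndarray:
        return self.basin_counts / self.basin_counts.sum()

    def transient_fraction_le(self, k: int) -> float:
        """Fraction of covered initial conditions with transient <= k."""
        if self.transient_counts is None:
            raise ValueError("transient histogram not recorded")
        return float(self.transient_counts[: k + 1].sum() / self.n_ic)

    @property
    def periods(self) -> list[int]:
        return [r.period for r in self.records]

    def fraction_by_period(self, period: int) -> float:
        return float(
            sum(
                f
                for r, f in zip(self.records, self.basin_fractions)
                if r.period == period
            )
        )

    def to_frame(self):
        """Tabular export: one row per attractor."""
        import pandas as pd

        return pd.DataFrame(
            {
                "attractor": range(len(self.records)),
                "period": self.periods,
                "basin_count": self.basin_counts,
                "basin_fraction": self.basin_fractions,
            }
        )


def max_transient(catalogue: AttractorCatalogue) -> int:
    """Maximum transient over the covered initial conditions."""
    if not catalogue.records:
        raise ValueError("empty catalogue")
    return catalogue.transient_max


def _masked_advance(engine: Engine, codes: np.ndarray, active: np.ndarray) -> None:
    codes[active] = engine.step_codes(codes[active])


def _analyse_codes(
    engine: Engine, codes0: np.ndarray, p_max: int = 512, t_guard: int = 1 << 20
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-IC (period, transient, canonical cycle code), fully vectorized.

    A probe copy of each trajectory is advanced until it provably sits on
    its cycle, the minimal period is read off as the first return time of
    the probe state, the transient as the first index at which the
    trajectory meets its own image one period ahead, and the canonical code
    as the smallest state code on the cycle.
    """
    m = codes0.size
    period = np.zeros(m, dtype=np.int64)
    t_probe = 256
    probe = engine.advance(codes0.copy(), t_probe)
    while True:
        ref = probe.copy()
        cur = probe.copy()
        active = np.ones(m, dtype=bool)
        for p in range(1, p_max + 1):
            _masked_advance(engine, cur, active)
            hit = active & (cur == ref)
            period[hit] = p
            active &= ~hit
            if not active.any():
                break
        if not active.any():
            break
        # unresolved: probe not yet on cycle (transient > t_probe) or the
        # period exceeds p_max; double both budgets and retry
        if t_probe > t_guard:
            raise RuntimeError("cycle detection budget exhausted")
        probe = engine.advance(probe, t_probe)
        t_probe *= 2
        p_max *= 2
    max_p = int(period.max())
    # b = codes0 advanced by exactly period[i] steps
    b = codes0.copy()
    for k in range(1, max_p + 1):
        _masked_advance(engine, b, period >= k)
    a = codes0.copy()
    transient = np.zeros(m, dtype=np.int64)
    active = a != b
    t = 0
    while active.any():
        t += 1
        if t > t_guard:
            raise RuntimeError("transient detection budget exhausted")
        _masked_advance(engine, a, active)
        _masked_advance(engine, b, active)
        met = active & (a == b)
        transient[met] = t
        active &= ~met
    # canonical code: minimum over the cycle starting at the entry state a
    canon = a.copy()
    cur = a.copy()
    for k in range(1, max_p):
        mask = k < period
        if not mask.any():
            break
        _masked_advance(engine, cur, mask)
        np.minimum(canon, cur, out=canon, where=mask)
    return period, transient, canon


def _record_from_code(engine: Engine, code: int) -> AttractorRecord:
    codes = [int(code)]
    cur = np.array([code], dtype=np.int64)
    while True:
        cur = engine.step_codes(cur)
        if int(cur[0]) == codes[0]:
            break
        codes.append(int(cur[0]))
    states = tuple(NetworkState(v) for v in engine.decode(np.array(codes)))
    return AttractorRecord(states)


def basin_statistics(
    net: LogicalNetwork,
    clamps: PerturbationSpec = WT,
    ic_policy: ICPolicy | None = None,
    mode: str = "sample",
    n: int = 100_000,
    seed: int | None = None,
    engine: Engine | None = None,
) -> AttractorCatalogue:
    """Group initial conditions by terminal attractor.

    ``mode="exhaustive"`` enumerates the policy's whole initial-condition
    space (basin fractions are then exact rationals); ``mode="sample"``
    draws ``n`` initial conditions uniformly with replacement (``seed``
    required).  Policy-fixed nodes are clamped during the evolution in
    addition to ``clamps``.
    """
    policy = ic_policy or ICPolicy()
    if engine is None:
        from .perturbations import combine

        eff = combine(clamps, policy.as_clamps(), label=clamps.label)
        engine = Engine(net, eff)
    if mode == "sample":
        if n < 1:
            raise ValueError("sample size must be >= 1")
        if seed is None:
            raise ValueError("seed is required in sample mode")
        rng = np.random.default_rng(seed)
        codes0 = policy.sample_codes(engine, n, rng)
        exhaustive = False
    elif mode == "exhaustive":
        codes0 = policy.enumerate_codes(engine)
        exhaustive = True
    else:
        raise ValueError(f"unknown mode {mode!r}")
    period, transient, canon = _analyse_codes(engine, codes0)
    uniq, counts = np.unique(canon, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    uniq, counts = uniq[order], counts[order]
    records = [_record_from_code(engine, int(c)) for c in uniq]
    return AttractorCatalogue(
        records=records,
        basin_counts=counts,
        transient_max=int(transient.max()),
        transient_mean=float(transient.mean()),
        exhaustive=exhaustive,
        n_ic=int(codes0.size),
        seed=seed,
        clamps=clamps,
        transient_counts=np.bincount(transient),
    )


# ---------------------------------------------------------------------------
# truth-table robustness scan


@dataclass(frozen=True)
class ComparisonRecord:
    """Observable value before and after a one-row truth-table rewrite."""

    node: str
    row: int
    old_output: int
    new_output: int
    reference: Any
    perturbed: Any

    @property
    def changed(self) -> bool:
        return self.reference != self.perturbed


def rule_perturbation_scan(
    net: LogicalNetwork,
    node: str,
    row: int,
    new_output: int,
    observable: Callable[[LogicalNetwork], Any],
    reference: Any | None = None,
) -> ComparisonRecord:
    """Observable of the one-row-modified network alongside the original.

    ``observable`` maps a network to any comparable summary (basin
    fractions, attractor periods, calcium metrics ...).  Passing a
    precomputed ``reference`` avoids recomputing the unmodified observable
    inside a sweep over all rows of all nodes.
    """
    modified = net.replace_rule(node, row, new_output)
    old = int(net.tables[node].outputs[row])
    if reference is None:
        reference = observable(net)
    return ComparisonRecord(
        node=node,
        row=row,
        old_output=old,
        new_output=int(new_output),
        reference=reference,
        perturbed=observable(modified),
    )
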