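"""Generators for random and constructed logical networks.

These emulate the model class of the pathway network — directed regulatory
graphs with mixed node arities {2, 3} and complete truth tables — so that
every pipeline stage (parsing, dynamics, basins, spectra) can be exercised
on networks with known or controllable structure, independently of the
bundled pathway reconstruction.
"""

from __future__ import annotations

import math
from itertools import product
from typing import Iterable, Sequence

import numpy as np

from .network import LogicalNetwork, NodeSpec, RegulatoryTable

__all__ = [
    "random_network",
    "signed_random_network",
    "ring_fixture",
    "multi_ring_fixture",
]


def _resolve_in_degree(in_degree, n_nodes: int, rng: np.random.Generator) -> int:
    if isinstance(in_degree, tuple):
        lo, hi = in_degree
        k = int(rng.integers(lo, hi + 1))
    else:
        k = int(in_degree)
    if not 1 <= k <= n_nodes:
        raise ValueError(f"in_degree {k} infeasible for {n_nodes} nodes")
    return k


def random_network(
    n_nodes: int,
    arity_choices: Sequence[int] = (2, 3),
    in_degree: int | tuple[int, int] = 2,
    seed: int | None = None,
) -> LogicalNetwork:
    """Random network: uniform regulators, uniform truth-table outputs.

    Regulators are drawn uniformly without replacement; each truth-table
    output uniformly over the target's levels.  ``in_degree`` may be a
    fixed integer or an inclusive ``(lo, hi)`` range sampled per node.
    Reproducible for a fixed ``seed``.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    rng = np.random.default_rng(seed)
    names = [f"n{i}" for i in range(n_nodes)]
    arities = {name: int(rng.choice(list(arity_choices))) for name in names}
    nodes, tables = [], {}
    for name in names:
        k = _resolve_in_degree(in_degree, n_nodes, rng)
        regs = tuple(rng.choice(names, size=k, replace=False))
        nodes.append(NodeSpec(name, arities[name], regs))
        reg_arities = tuple(arities[r] for r in regs)
        outputs = rng.integers(
            0, arities[name], size=math.prod(reg_arities)
        ).astype(np.int8)
        tables[name] = RegulatoryTable(name, reg_arities, outputs)
    return LogicalNetwork(nodes, tables, metadata=f"random_network(seed={seed})")


def signed_random_network(
    n_nodes: int,
    arity_choices: Sequence[int] = (2, 3),
    in_degree: int | tuple[int, int] = 2,
    seed: int | None = None,
    activator_prob: float = 0.5,
    self_inactivation: bool = False,
) -> LogicalNetwork:
    """Random network whose tables follow a signed threshold-balance rule.

    Each edge is independently an activator (probability ``activator_prob``)
    or an inhibitor.  The balance rule, frozen here as the test scaffold's
    single documented convention, is:

    * a regulator is *active* when its level is >= 1;
    * score = (# active activators) - (# active inhibitors), minus 1 when
      ``self_inactivation`` is set and the target (prepended as an extra
      regulator) is active;
    * output = arity - 1 if score > 0, 0 if score < 0, and on a tie the
      target's own level if it regulates itself, else 0.

    The rule makes outputs monotone in every activator and antitone in
    every inhibitor.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    rng = np.random.default_rng(seed)
    names = [f"n{i}" for i in range(n_nodes)]
    arities = {name: int(rng.choice(list(arity_choices))) for name in names}
    nodes, tables = [], {}
    for name in names:
        k = _resolve_in_degree(in_degree, n_nodes, rng)
        regs = list(rng.choice(names, size=k, replace=False))
        signs = [
            1 if rng.random() < activator_prob else -1 for _ in regs
        ]
        if self_inactivation and name not in regs:
            regs.insert(0, name)
            signs.insert(0, -1)
        regs = tuple(regs)
        self_pos = regs.index(name) if name in regs else None
        reg_arities = tuple(arities[r] for r in regs)
        a = arities[name]
        outputs = np.empty(math.prod(reg_arities), dtype=np.int8)
        for idx, combo in enumerate(product(*(range(x) for x in reg_arities))):
            score = sum(s for s, v in zip(signs, combo) if v >= 1)
            if score > 0:
                outputs[idx] = a - 1
            elif score < 0:
                outputs[idx] = 0
            else:
                outputs[idx] = combo[self_pos] if self_pos is not None else 0
        nodes.append(NodeSpec(name, a, regs))
        tables[name] = RegulatoryTable(name, reg_arities, outputs)
    return LogicalNetwork(
        nodes, tables, metadata=f"signed_random_network(seed={seed})"
    )


def ring_fixture(p: int, prefix: str = "r") -> LogicalNetwork:
    """Cyclic shift register of ``p`` binary nodes (identity for p = 1).

    From the one-hot initial condition (node 0 at 1, the rest 0) the
    dynamics is an exact p-cycle, giving closed-form oracles for attractor
    detection, spectra and module lengths.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    names = [f"{prefix}{i}" for i in range(p)]
    nodes, tables = [], {}
    for i, name in enumerate(names):
        src = names[(i - 1) % p]
        nodes.append(NodeSpec(name, 2, (src,)))
        tables[name] = RegulatoryTable(name, (2,), np.array([0, 1], dtype=np.int8))
    return LogicalNetwork(nodes, tables, metadata=f"ring_fixture({p})")


def one_hot_ic(net: LogicalNetwork) -> list[int]:
    """Initial condition lighting the first node of each ring component."""
    values = [0] * net.n_nodes
    seen_prefixes: set[str] = set()
    for i, node in enumerate(net.nodes):
        prefix = node.name.rstrip("0123456789")
        if node.name == prefix + "0" and prefix not in seen_prefixes:
            values[i] = 1
            seen_prefixes.add(prefix)
    return values


def multi_ring_fixture(periods: Iterable[int]) -> LogicalNetwork:
    """Disjoint union of shift-register rings, one per requested period.

    From the combined one-hot initial condition the network's attractor
    period is the least common multiple of the component periods.
    """
    nodes, tables = [], {}
    for j, p in enumerate(periods):
        ring = ring_fixture(p, prefix=f"r{j}_")
        nodes.extend(ring.nodes)
        tables.update(ring.tables)
    return LogicalNetwork(nodes, tables, metadata="multi_ring_fixture")
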