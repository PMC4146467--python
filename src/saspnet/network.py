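"""Multi-valued logical networks: containers, validation and text-file I/O.

A logical network is a set of named nodes, each carrying a small integer
state (binary ``{0,1}`` or ternary ``{0,1,2}``), together with one complete
regulatory truth table per regulated node.  The table of node *i* lists, for
every combination of its regulators' states at time *t*, the state the node
takes at *t + 1* under the synchronous update rule implemented in
:mod:`saspnet.dynamics`.

Networks are serialized as a directory of plain-text files, one per node::

    # optional comment lines
    node: Ca
    arity: 3
    regulators: LVA HVA cAMPCC CaP NCE dCa Ca
    0 0 0 0 0 0 0 0
    0 0 0 0 0 0 1 0
    ...

Each body row holds one regulator-state combination (columns in header
order) followed by the regulated node's next state.  Rows may appear in any
order but must enumerate every combination exactly once.  A node with no
``regulators`` entry is an *input node*: it has no table and simply holds
its value between updates (its level is set by the initial condition or by
an external clamp).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "NodeSpec",
    "RegulatoryTable",
    "LogicalNetwork",
    "NetworkState",
    "NetworkFormatError",
    "NetworkValidationError",
    "Violation",
    "ValidationReport",
    "load_network",
    "save_network",
    "validate_network",
]


class NetworkFormatError(ValueError):
    """Raised when a network directory or node file cannot be parsed."""


class NetworkValidationError(ValueError):
    """Raised when a structurally parseable network violates an invariant."""


_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_+\-]*$")


@dataclass(frozen=True)
class NodeSpec:
    """One node of a logical network.

    Parameters
    ----------
    name:
        Identifier, unique within the network.
    arity:
        Number of discrete levels the node can take; 2 or 3.
    regulators:
        Ordered regulator names.  The order fixes the truth-table column
        order and is preserved across save/load round trips.  Empty for
        input nodes.
    role_tag:
        Free-form label (e.g. ``"channel"``, ``"voltage"``); not used by the
        dynamics.
    """

    name: str
    arity: int
    regulators: tuple[str, ...] = ()
    role_tag: str = ""

    def __post_init__(self) -> None:
        if self.arity not in (2, 3):
            raise NetworkValidationError(
                f"node {self.name!r}: arity must be 2 or 3, got {self.arity}"
            )
        if not _NAME_RE.match(self.name):
            raise NetworkValidationError(f"invalid node name {self.name!r}")
        object.__setattr__(self, "regulators", tuple(self.regulators))

    @property
    def is_input(self) -> bool:
        return not self.regulators


@dataclass(frozen=True)
class RegulatoryTable:
    """Complete truth table for one regulated node.

    ``outputs[k]`` is the node's next state for the regulator combination
    whose mixed-radix rank is ``k`` (first regulator most significant).
    ``reg_arities`` are the arities of the regulators, in column order.
    """

    target: str
    reg_arities: tuple[int, ...]
    outputs: np.ndarray  # shape (prod(reg_arities),), int8

    def __post_init__(self) -> None:
        out = np.asarray(self.outputs, dtype=np.int8)
        expected = int(math.prod(self.reg_arities))
        if out.shape != (expected,):
            raise NetworkValidationError(
                f"table for {self.target!r}: expected {expected} rows, got {out.shape}"
            )
        object.__setattr__(self, "outputs", out)
        object.__setattr__(self, "reg_arities", tuple(int(a) for a in self.reg_arities))

    @property
    def n_rows(self) -> int:
        return int(self.outputs.size)

    def row_index(self, combo: Sequence[int]) -> int:
        """Mixed-radix rank of a regulator-state combination."""
        idx = 0
        for v, a in zip(combo, self.reg_arities, strict=True):
            if not 0 <= v < a:
                raise ValueError(f"regulator value {v} out of range [0,{a})")
            idx = idx * a + v
        return idx

    def combo(self, index: int) -> tuple[int, ...]:
        """Inverse of :meth:`row_index`."""
        vals = []
        for a in reversed(self.reg_arities):
            vals.append(index % a)
            index //= a
        return tuple(reversed(vals))

    def rows(self) -> Iterator[tuple[tuple[int, ...], int]]:
        for k in range(self.n_rows):
            yield self.combo(k), int(self.outputs[k])

    def __eq__(self, other: object) -> bool:  # ndarray defeats dataclass eq
        if not isinstance(other, RegulatoryTable):
            return NotImplemented
        return (
            self.target == other.target
            and self.reg_arities == other.reg_arities
            and np.array_equal(self.outputs, other.outputs)
        )


@dataclass
class LogicalNetwork:
    """A multi-valued logical network: nodes plus one table per non-input node."""

    nodes: list[NodeSpec]
    tables: dict[str, RegulatoryTable]
    metadata: str = ""

    def __post_init__(self) -> None:
        self._index = {n.name: i for i, n in enumerate(self.nodes)}
        if len(self._index) != len(self.nodes):
            raise NetworkValidationError("duplicate node names")

    # -- conveniences -----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def names(self) -> list[str]:
        return [n.name for n in self.nodes]

    @property
    def arities(self) -> np.ndarray:
        return np.array([n.arity for n in self.nodes], dtype=np.int64)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown node {name!r}") from None

    def node(self, name: str) -> NodeSpec:
        return self.nodes[self.index(name)]

    @property
    def n_states(self) -> int:
        """Size of the full configuration space (product of arities)."""
        return int(math.prod(int(n.arity) for n in self.nodes))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LogicalNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.tables == other.tables

    def replace_rule(self, node: str, row: int, new_output: int) -> "LogicalNetwork":
        """Copy of the network with one truth-table row rewritten."""
        tab = self.tables[node]
        if not 0 <= row < tab.n_rows:
            raise IndexError(f"row {row} out of range for {node!r} ({tab.n_rows} rows)")
        if not 0 <= new_output < self.node(node).arity:
            raise ValueError(
                f"output {new_output} out of range for {node!r} (arity {self.node(node).arity})"
            )
        outputs = tab.outputs.copy()
        outputs[row] = new_output
        tables = dict(self.tables)
        tables[node] = RegulatoryTable(node, tab.reg_arities, outputs)
        return LogicalNetwork(list(self.nodes), tables, self.metadata)


@dataclass(frozen=True)
class NetworkState:
    """One configuration of all node values, in network node order."""

    values: tuple[int, ...]

    def __init__(self, values: Sequence[int]):
        object.__setattr__(self, "values", tuple(int(v) for v in values))

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, i: int) -> int:
        return self.values[i]

    def as_array(self) -> np.ndarray:
        return np.array(self.values, dtype=np.int8)

    def validate_for(self, net: LogicalNetwork) -> None:
        if len(self.values) != net.n_nodes:
            raise NetworkValidationError(
                f"state length {len(self.values)} != node count {net.n_nodes}"
            )
        for v, node in zip(self.values, net.nodes):
            if not 0 <= v < node.arity:
                raise NetworkValidationError(
                    f"value {v} for node {node.name!r} outside [0,{node.arity})"
                )


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Violation:
    kind: str
    message: str

    def __str__(self) -> str:
        return f"[{self.kind}] {self.message}"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.ok:
            return "network valid"
        return "\n".join(str(v) for v in self.violations)


def validate_network(net: LogicalNetwork) -> ValidationReport:
    """Check every structural invariant; returns a report, never raises.

    The report is empty iff the network is valid: arities in {2, 3}, every
    regulator resolves to a declared node, every non-input node has a
    complete table whose column arities match the regulators' declared
    arities, and all outputs lie in the target's range.
    """
    issues: list[Violation] = []
    names = set(net.names)
    for node in net.nodes:
        if node.arity not in (2, 3):
            issues.append(Violation("arity", f"{node.name}: arity {node.arity}"))
        for r in node.regulators:
            if r not in names:
                issues.append(
                    Violation(
                        "unresolved-regulator",
                        f"{node.name}: regulator {r!r} is not a declared node",
                    )
                )
        if node.regulators:
            tab = net.tables.get(node.name)
            if tab is None:
                issues.append(
                    Violation("missing-table", f"{node.name}: regulated node has no table")
                )
                continue
            want = tuple(
                net.node(r).arity for r in node.regulators if r in names
            )
            if len(want) == len(node.regulators) and tab.reg_arities != want:
                issues.append(
                    Violation(
                        "table-arity-mismatch",
                        f"{node.name}: table column arities {tab.reg_arities} "
                        f"!= regulator arities {want}",
                    )
                )
            bad = (tab.outputs < 0) | (tab.outputs >= node.arity)
            if bad.any():
                k = int(np.argmax(bad))
                issues.append(
                    Violation(
                        "range",
                        f"{node.name}: output {int(tab.outputs[k])} at combination "
                        f"{tab.combo(k)} outside [0,{node.arity})",
                    )
                )
        else:
            if node.name in net.tables:
                issues.append(
                    Violation("spurious-table", f"{node.name}: input node has a table")
                )
    for tname in net.tables:
        if tname not in names:
            issues.append(Violation("unresolved-target", f"table for unknown node {tname!r}"))
    return ValidationReport(issues)


# ---------------------------------------------------------------------------
# text dialect I/O


def _parse_node_file(path: Path) -> tuple[str, int, tuple[str, ...], list[tuple[tuple[int, ...], int]]]:
    name = arity = None
    regulators: tuple[str, ...] | None = None
    rows: list[tuple[tuple[int, ...], int]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("node:"):
                name = line.split(":", 1)[1].strip()
            elif line.startswith("arity:"):
                try:
                    arity = int(line.split(":", 1)[1])
                except ValueError:
                    raise NetworkFormatError(f"{path}:{lineno}: bad arity line {line!r}")
            elif line.startswith("regulators:"):
                regulators = tuple(line.split(":", 1)[1].split())
            else:
                if regulators is None:
                    raise NetworkFormatError(
                        f"{path}:{lineno}: table row before 'regulators:' header"
                    )
                parts = line.split()
                if len(parts) != len(regulators) + 1:
                    raise NetworkFormatError(
                        f"{path}:{lineno}: expected {len(regulators) + 1} columns, "
                        f"got {len(parts)}"
                    )
                try:
                    ints = [int(p) for p in parts]
                except ValueError:
                    raise NetworkFormatError(f"{path}:{lineno}: non-integer entry in {line!r}")
                rows.append((tuple(ints[:-1]), ints[-1]))
    if name is None:
        raise NetworkFormatError(f"{path}: missing 'node:' header")
    if arity is None:
        raise NetworkFormatError(f"{path}: missing 'arity:' header")
    if regulators is None:
        raise NetworkFormatError(f"{path}: missing 'regulators:' header")
    return name, arity, regulators, rows


def load_network(directory: str | Path, metadata: str | None = None) -> LogicalNetwork:
    """Load a network from a directory of per-node text files.

    Files are read in sorted name order; node order in the returned network
    follows that order.  Raises :class:`NetworkFormatError` on unparseable
    files and :class:`NetworkValidationError` on incomplete or duplicated
    table rows, out-of-range outputs, or regulators that name no file.
    """
    directory = Path(directory)
    manifest = directory / "NODES"
    if manifest.exists():
        order = manifest.read_text(encoding="utf-8").split()
        paths = []
        for name in order:
            p = directory / f"{name}.txt"
            if not p.exists():
                raise NetworkFormatError(
                    f"node {name!r} listed in {manifest} has no file {p.name}"
                )
            paths.append(p)
    else:
        paths = sorted(directory.glob("*.txt"))
    if not paths:
        raise NetworkFormatError(f"no node files (*.txt) in {directory}")
    parsed = [_parse_node_file(p) for p in paths]
    arity_of = {name: arity for name, arity, _, _ in parsed}
    nodes = []
    tables: dict[str, RegulatoryTable] = {}
    for path, (name, arity, regulators, rows) in zip(paths, parsed):
        for r in regulators:
            if r not in arity_of:
                raise NetworkValidationError(
                    f"{path.name}: regulator {r!r} has no node file in {directory}"
                )
        nodes.append(NodeSpec(name=name, arity=arity, regulators=regulators))
        if not regulators:
            if rows:
                raise NetworkFormatError(
                    f"{path.name}: input node (no regulators) must have no table rows"
                )
            continue
        reg_arities = tuple(arity_of[r] for r in regulators)
        n_rows = math.prod(reg_arities)
        outputs = np.full(n_rows, -1, dtype=np.int8)
        tab = RegulatoryTable(name, reg_arities, np.zeros(n_rows, dtype=np.int8))
        seen = np.zeros(n_rows, dtype=bool)
        for combo, out in rows:
            try:
                k = tab.row_index(combo)
            except ValueError as exc:
                raise NetworkValidationError(f"{path.name}: {exc} in row {combo}") from None
            if seen[k]:
                raise NetworkValidationError(
                    f"{path.name}: duplicated regulator combination {combo}"
                )
            if not 0 <= out < arity:
                raise NetworkValidationError(
                    f"{path.name}: output {out} for combination {combo} outside [0,{arity})"
                )
            seen[k] = True
            outputs[k] = out
        if not seen.all():
            missing = tab.combo(int(np.argmin(seen)))
            raise NetworkValidationError(
                f"{path.name}: incomplete table; missing combination {missing} "
                f"({int(seen.sum())}/{n_rows} rows present)"
            )
        tables[name] = RegulatoryTable(name, reg_arities, outputs)
    meta = metadata if metadata is not None else f"loaded from {directory}"
    net = LogicalNetwork(nodes=nodes, tables=tables, metadata=meta)
    report = validate_network(net)
    if not report.ok:
        raise NetworkValidationError(str(report))
    return net


def save_network(net: LogicalNetwork, directory: str | Path) -> None:
    """Write one text file per node; ``load_network`` then reproduces ``net``.

    A ``NODES`` manifest records node order so the round trip reproduces the
    network exactly (nodes, regulator order and tables bit-identical).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "NODES").write_text(
        "\n".join(n.name for n in net.nodes) + "\n", encoding="utf-8"
    )
    for node in net.nodes:
        path = directory / f"{node.name}.txt"
        with open(path, "w", encoding="utf-8") as fh:
            if net.metadata:
                for line in net.metadata.splitlines():
                    fh.write(f"# {line}\n")
            fh.write(f"node: {node.name}\n")
            fh.write(f"arity: {node.arity}\n")
            fh.write(f"regulators: {' '.join(node.regulators)}\n")
            if node.regulators:
                tab = net.tables[node.name]
                for combo, out in tab.rows():
                    fh.write(" ".join(str(v) for v in combo) + f" {out}\n")
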