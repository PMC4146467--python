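"""In-silico interventions: node clamping and the niflumic-acid scenario suite.

A perturbation clamps a set of nodes to fixed levels for the whole network
evolution.  Knocking a channel out clamps it to 0 (closed even when its
regulators are active); constitutive activation clamps it to 1 (permanently
open).  Clamps take effect from the first update onward: the initial
condition may hold any level for a clamped node, which keeps the
initial-condition space identical across scenarios and makes basin
statistics comparable.

Niflumic acid (NFA) hits three channels of the speract pathway at once —
HCN, CaCC and CaKC.  Because pharmacology leaves open whether NFA blocks or
activates the Ca2+-dependent K+ channel, every combination is examined under
two scenarios: CaKC clamped closed (scenario 1) or clamped open (scenario 2).
"""

from __future__ import annotations

from dataclasses import dataclass

from .network import LogicalNetwork

__all__ = [
    "PerturbationSpec",
    "knockout",
    "constitutive_activation",
    "combine",
    "scenario_suite",
    "WT",
]


@dataclass(frozen=True)
class PerturbationSpec:
    """A set of (node, level) clamps plus a human-readable scenario label."""

    clamps: tuple[tuple[str, int], ...] = ()
    label: str = "WT"

    def __post_init__(self) -> None:
        names = [n for n, _ in self.clamps]
        if len(set(names)) != len(names):
            raise ValueError(f"node clamped more than once in {self.label!r}")
        object.__setattr__(self, "clamps", tuple(sorted(self.clamps)))

    @property
    def is_wild_type(self) -> bool:
        return not self.clamps

    def as_dict(self) -> dict[str, int]:
        return dict(self.clamps)

    def validate_for(self, net: LogicalNetwork) -> None:
        for name, value in self.clamps:
            node = net.node(name)  # raises KeyError for unknown nodes
            if not 0 <= value < node.arity:
                raise ValueError(
                    f"clamp {name}={value} outside [0,{node.arity})"
                )

    def __str__(self) -> str:
        return self.label


WT = PerturbationSpec((), "WT")


def knockout(node: str) -> PerturbationSpec:
    """Clamp ``node`` to 0 for all t >= 1 (channel blocked)."""
    return PerturbationSpec(((node, 0),), f"{node}-")


def constitutive_activation(node: str) -> PerturbationSpec:
    """Clamp ``node`` to 1 for all t >= 1 (channel permanently open)."""
    return PerturbationSpec(((node, 1),), f"{node}+")


def combine(*specs: PerturbationSpec, label: str | None = None) -> PerturbationSpec:
    """Union of clamp sets; order-independent.  Raises on conflicting clamps."""
    clamps: dict[str, int] = {}
    for spec in specs:
        for name, value in spec.clamps:
            if clamps.get(name, value) != value:
                raise ValueError(f"conflicting clamps for {name!r}")
            clamps[name] = value
    if label is None:
        label = "".join(s.label for s in specs if not s.is_wild_type) or "WT"
    return PerturbationSpec(tuple(clamps.items()), label)


def scenario_suite() -> list[PerturbationSpec]:
    """The 12 NFA scenarios: WT, singles, pairs, and the two triples.

    Knockouts of HCN, CaCC and CaKC individually, in the three pairs, and
    all together (scenario 1); plus CaKC activation alone, with each single
    knockout, and with both (scenario 2).
    """
    hcn, cacc, cakc = knockout("HCN"), knockout("CaCC"), knockout("CaKC")
    cakc_on = constitutive_activation("CaKC")
    return [
        WT,
        hcn,
        cacc,
        cakc,
        cakc_on,
        combine(hcn, cacc),
        combine(hcn, cakc),
        combine(cacc, cakc),
        combine(hcn, cakc_on),
        combine(cacc, cakc_on),
        combine(hcn, cacc, cakc),      # scenario 1: NFA blocks all three
        combine(hcn, cacc, cakc_on),   # scenario 2: NFA activates CaKC
    ]
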