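"""Reconstructed 21-node logical network of the speract-activated pathway.

The original model's truth tables were published as supplementary text
files that are not redistributable here, so this module *reconstructs* the
network programmatically from the published wiring diagram and the
activating/inhibiting nature of every link, using explicit physiological
balance rules.  The reconstruction is synthetic: it reproduces the
documented architecture exactly (21 nodes, four ternary nodes — membrane
potential V, the LVA and HVA calcium channels, and intracellular calcium —
and a 432-row calcium table) but its individual table entries are this
package's own encoding of the described mechanism, not a transcription.
The bundled fixture directory is named ``sasp_synthetic`` for this reason.

Mechanism encoded (one level per time step):

* speract -> receptor -> guanylate cyclase -> cGMP, with phosphodiesterase
  (PDE) induced by cGMP and then persistently active: the cGMP signal is a
  single adapting pulse, after which the K+-selective cyclic-nucleotide-
  gated channel (KCNG) closes again.  The upstream arm therefore settles to
  a fixed point and the sustained oscillations are generated downstream
  (the published perturbation periods share no common divisor, which rules
  out a common upstream pacemaker);
* K+ efflux (KCNG or CaKC open) and Cl- current (CaCC) hyperpolarize V;
  away from depolarization the Na+/H+ exchanger (NHE) and HCN stay active,
  and Na+ influx through HCN depolarizes V back;
* the voltage-gated Ca2+ channels are a three-state machine
  (inactive/closed/open): the low-threshold channel (LVA) fires exactly at
  the resting level and recovers from inactivation at or below rest, the
  high-threshold channel (HVA) fires only at depolarization and recovers
  only at hyperpolarization; both inactivate immediately after one open
  step.  Their open states feed the aggregate Ca2+ permeability node dCa,
  which depolarizes V;
* calcium integrates influx (LVA open, HVA open, cAMP-gated channel cAMPCC
  downstream of NHE) against extrusion (Ca2+ pump CaP above the tonic
  level, Na+/Ca2+ exchanger NCE facilitated by hyperpolarization) and its
  own self-inactivation, decaying on a balanced tie; raised calcium opens
  the Cl- channel CaCC (tonic threshold) and the K+ channel CaKC
  (supratonic threshold), which re-hyperpolarize V and restart the cycle.

Identification: the free constants of these balance rules (thresholds,
recovery voltages, tie behavior) were selected by matching the qualitative
attractor periodicities reported for the wild type and the channel-clamp
scenarios; see docs/methods.md for the selection protocol and the residual
discrepancies of the reconstruction.
"""

from __future__ import annotations

import math
from importlib import resources
from itertools import product
from pathlib import Path
from typing import Callable

import numpy as np

from .network import LogicalNetwork, NodeSpec, RegulatoryTable

__all__ = [
    "NODE_ORDER",
    "TERNARY_NODES",
    "SPERACT_ACTIVATED",
    "build_sasp_network",
    "load_sasp",
    "write_fixture",
]

#: node order of the reconstruction (signal flow order)
NODE_ORDER = [
    "Speract", "SR", "GC", "cGMP", "PDE", "KCNG", "NHE", "HCN", "cAMPCC",
    "LVA", "HVA", "CaCC", "CaKC", "CaP", "NCE", "dK", "dNa", "dCl", "dCa",
    "V", "Ca",
]

TERNARY_NODES = {"V", "LVA", "HVA", "Ca"}

_PROVENANCE = (
    "synthetic reconstruction of the speract-activated signaling pathway "
    "network from the published wiring diagram and physiological balance "
    "rules (not a transcription of the original supplementary tables)"
)


def _clip(v: int, arity: int) -> int:
    return max(0, min(arity - 1, v))


def _gated_cav(fire_level: int, recover_max: int) -> Callable[[int, int], int]:
    """Voltage-gated Ca2+ channel state machine (0 inactive, 1 closed, 2 open).

    A closed channel fires (opens for exactly one step) when V sits exactly
    at ``fire_level``; an open channel inactivates immediately; an inactive
    channel recovers to closed while V <= ``recover_max``.  LVA fires at the
    resting level (1) and recovers at or below rest; HVA fires only at
    depolarization (2) and recovers only at hyperpolarization (0).
    """

    def rule(v: int, ch: int) -> int:
        if ch == 0:
            return 1 if v <= recover_max else 0  # recovery from inactivation
        if ch == 1:
            return 2 if v == fire_level else 1
        return 0  # open channel inactivates after one step

    return rule


def _v_rule(dna: int, dca: int, dk: int, dcl: int, v: int) -> int:
    """Membrane potential: one level toward the dominant current balance.

    Depolarizing drive = Na+ influx + Ca2+ influx; hyperpolarizing drive =
    K+ efflux + Cl- influx.  On a tie the potential relaxes one level
    toward resting (leak).
    """
    net_drive = (dna + dca) - (dk + dcl)
    if net_drive > 0:
        return _clip(v + 1, 3)
    if net_drive < 0:
        return _clip(v - 1, 3)
    return v + (1 if v < 1 else (0 if v == 1 else -1))


def _ca_rule(lva: int, hva: int, campcc: int, cap: int, nce: int, dca: int, ca: int) -> int:
    """Intracellular calcium: graded balance of influx vs extrusion.

    Influx counts each open Ca2+ conduit: LVA open, HVA open, cAMP-gated
    channel open.  The aggregate permeability node dCa is read but carries
    no independent weight — it reports the same channel openings one step
    delayed, and double-counting them broadens every calcium transient.
    Extrusion counts the pump, the exchanger and calcium's own
    self-inactivation (active whenever calcium is above basal).  Calcium
    moves one level in the direction of the balance and decays one level on
    a tie (ongoing sequestration).
    """
    influx = (lva == 2) + (hva == 2) + campcc
    efflux = cap + nce + (1 if ca >= 1 else 0)
    net_drive = influx - efflux
    if net_drive > 0:
        return _clip(ca + 1, 3)
    if net_drive < 0:
        return _clip(ca - 1, 3)
    return _clip(ca - 1, 3)


#: regulators (ordered) and update rule per node; None = input-like identity
_RULES: dict[str, tuple[tuple[str, ...], Callable[..., int]]] = {
    # ligand and receptor arm
    "Speract": (("Speract",), lambda s: s),  # externally set; holds its value
    "SR": (("Speract",), lambda s: s),
    "GC": (("SR",), lambda sr: sr),
    # cGMP arm: PDE, once induced, stays active (persistent degradation),
    # so cGMP is a single adapting pulse; it holds only while unregulated
    "cGMP": (
        ("GC", "PDE", "cGMP"),
        lambda gc, pde, c: 1 if (gc == 1 and pde == 0) else (c if (gc == 0 and pde == 0) else 0),
    ),
    "PDE": (("cGMP", "PDE"), lambda c, p: 1 if (c or p) else 0),
    "KCNG": (("cGMP",), lambda c: c),
    # voltage-dependent elements: NHE and HCN are active away from
    # depolarization; the cAMP-arm facilitation of HCN (via NHE) is not
    # separable at this resolution, so the NHE input reads as redundant
    "NHE": (("V",), lambda v: 1 if v <= 1 else 0),
    "HCN": (("V", "NHE"), lambda v, nhe: 1 if v <= 1 else 0),
    "cAMPCC": (("NHE",), lambda nhe: nhe),
    "LVA": (("V", "LVA"), _gated_cav(fire_level=1, recover_max=1)),
    "HVA": (("V", "HVA"), _gated_cav(fire_level=2, recover_max=0)),
    # calcium-dependent channels and extrusion
    "CaCC": (("Ca",), lambda ca: 1 if ca >= 1 else 0),
    "CaKC": (("Ca",), lambda ca: 1 if ca == 2 else 0),
    "CaP": (("Ca",), lambda ca: 1 if ca == 2 else 0),
    "NCE": (
        ("Ca", "V"),
        lambda ca, v: 1 if (ca == 2 or (ca == 1 and v == 0)) else 0,
    ),
    # permeability-change nodes; dCa aggregates the voltage-gated Ca2+
    # conduits (the cAMP-gated flux acts on calcium but carries too little
    # charge to register in the voltage balance)
    "dK": (("KCNG", "CaKC"), lambda kcng, cakc: 1 if (kcng or cakc) else 0),
    "dNa": (("HCN",), lambda hcn: hcn),
    "dCl": (("CaCC",), lambda cacc: cacc),
    "dCa": (
        ("LVA", "HVA", "cAMPCC"),
        lambda lva, hva, campcc: 1 if (lva == 2 or hva == 2) else 0,
    ),
    # integrators
    "V": (("dNa", "dCa", "dK", "dCl", "V"), _v_rule),
    "Ca": (("LVA", "HVA", "cAMPCC", "CaP", "NCE", "dCa", "Ca"), _ca_rule),
}


def _arity(name: str) -> int:
    return 3 if name in TERNARY_NODES else 2


def build_sasp_network() -> LogicalNetwork:
    """Construct the reconstructed network by enumerating every rule."""
    nodes = []
    tables = {}
    for name in NODE_ORDER:
        regulators, rule = _RULES[name]
        nodes.append(
            NodeSpec(name=name, arity=_arity(name), regulators=regulators)
        )
        reg_arities = tuple(_arity(r) for r in regulators)
        n_rows = math.prod(reg_arities)
        outputs = np.empty(n_rows, dtype=np.int8)
        for k, combo in enumerate(product(*(range(a) for a in reg_arities))):
            outputs[k] = rule(*combo)
        tables[name] = RegulatoryTable(name, reg_arities, outputs)
    return LogicalNetwork(nodes=nodes, tables=tables, metadata=_PROVENANCE)


def write_fixture(directory: str | Path) -> None:
    """Regenerate the bundled text fixture from the builder."""
    from .network import save_network

    save_network(build_sasp_network(), directory)


def fixture_dir() -> Path:
    """Path of the bundled ``sasp_synthetic`` fixture directory."""
    return Path(resources.files("saspnet") / "data" / "sasp_synthetic")


def load_sasp() -> LogicalNetwork:
    """Load the bundled reconstructed network from its text fixture."""
    from .network import load_network

    return load_network(fixture_dir(), metadata=_PROVENANCE)


from .dynamics import ICPolicy  # noqa: E402  (no cycle: dynamics does not import sasp)

#: initial-condition policy of all pathway analyses: ligand pinned on,
#: every other node drawn independently and uniformly over its levels
SPERACT_ACTIVATED = ICPolicy(fixed=(("Speract", 1),))
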