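"""Build the pathway network, validate it, and check the bundled fixture.

Outputs
-------
results/network_summary.txt : node listing with arities, regulators and
    truth-table sizes, plus validation status and the fixture comparison.
"""

import argparse
from pathlib import Path

from saspnet.network import validate_network
from saspnet.sasp import TERNARY_NODES, build_sasp_network, load_sasp


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", default="results", type=Path)
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    net = build_sasp_network()
    report = validate_network(net)
    fixture = load_sasp()
    fixture_matches = [n.name for n in net.nodes] == [
        n.name for n in fixture.nodes
    ] and all(net.tables[n] == fixture.tables[n] for n in net.tables)

    lines = [
        f"nodes: {net.n_nodes}",
        f"ternary nodes: {sorted(n.name for n in net.nodes if n.arity == 3)}",
        f"state-space size: {net.n_states}",
        f"validation: {'OK' if report.ok else report.violations}",
        f"bundled fixture identical to builder: {fixture_matches}",
        "",
        f"{'node':8s} {'arity':5s} {'rows':5s} regulators",
    ]
    for node in net.nodes:
        table = net.tables[node.name]
        lines.append(
            f"{node.name:8s} {node.arity:<5d} {table.n_rows:<5d} "
            + ",".join(node.regulators)
        )
    text = "\n".join(lines) + "\n"
    (args.out_dir / "network_summary.txt").write_text(text)
    print(text)
    assert report.ok, "network failed validation"
    assert sum(n.arity == 3 for n in net.nodes) == len(TERNARY_NODES)


if __name__ == "__main__":
    main()
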