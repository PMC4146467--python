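"""Container, validation and text-dialect round-trip behaviour."""

import numpy as np
import pytest

from saspnet.network import (
    LogicalNetwork,
    NetworkFormatError,
    NetworkState,
    NetworkValidationError,
    NodeSpec,
    RegulatoryTable,
    load_network,
    save_network,
    validate_network,
)
from saspnet.synthetic import random_network


def test_arity_restricted_to_two_or_three():
    with pytest.raises(NetworkValidationError):
        NodeSpec("A", 4, ("A",))
    with pytest.raises(NetworkValidationError):
        NodeSpec("A", 1, ("A",))


def test_table_row_count_must_match_regulator_arities():
    with pytest.raises(NetworkValidationError):
        RegulatoryTable("A", (2, 3), np.zeros(5, np.int8))
    tab = RegulatoryTable("A", (2, 3), np.zeros(6, np.int8))
    assert tab.n_rows == 6
    # row_index and combo are inverse bijections over all rows
    for k in range(6):
        assert tab.row_index(tab.combo(k)) == k


def test_state_validation(identity_net):
    NetworkState([1]).validate_for(identity_net)
    with pytest.raises(NetworkValidationError):
        NetworkState([2]).validate_for(identity_net)
    with pytest.raises(NetworkValidationError):
        NetworkState([0, 0]).validate_for(identity_net)


def test_validator_reports_unresolved_regulator():
    net = LogicalNetwork(
        nodes=[NodeSpec("A", 2, ("Ghost",))],
        tables={"A": RegulatoryTable("A", (2,), np.array([0, 1], np.int8))},
    )
    report = validate_network(net)
    assert not report.ok
    assert any(v.kind == "unresolved-regulator" for v in report.violations)


def test_validator_reports_out_of_range_output():
    net = LogicalNetwork(
        nodes=[NodeSpec("A", 2, ("A",))],
        tables={"A": RegulatoryTable("A", (2,), np.array([0, 2], np.int8))},
    )
    report = validate_network(net)
    assert any(v.kind == "range" for v in report.violations)


def test_valid_random_networks_pass_validator():
    for seed in range(20):
        net = random_network(8, in_degree=(1, 3), seed=seed)
        assert validate_network(net).ok


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_round_trip_identity(tmp_path, seed):
    """Save then load reproduces nodes, regulator order and tables exactly."""
    net = random_network(5, in_degree=(1, 3), seed=seed)
    save_network(net, tmp_path / "net")
    reloaded = load_network(tmp_path / "net")
    assert reloaded == net
    assert [n.regulators for n in reloaded.nodes] == [n.regulators for n in net.nodes]
    assert [n.arity for n in reloaded.nodes] == [n.arity for n in net.nodes]


def test_row_storage_matches_declared_sizes():
    """Total stored rows = sum over nodes of the product of regulator arities."""
    net = random_network(7, in_degree=(1, 3), seed=3)
    total = sum(t.n_rows for t in net.tables.values())
    expected = sum(
        int(np.prod([net.node(r).arity for r in n.regulators]))
        for n in net.nodes
        if n.regulators
    )
    assert total == expected


def test_load_one_node_identity_network(tmp_path):
    d = tmp_path / "net"
    d.mkdir()
    (d / "A.txt").write_text("node: A\narity: 2\nregulators: A\n0 0\n1 1\n")
    net = load_network(d)
    assert net.n_nodes == 1
    assert list(net.tables["A"].outputs) == [0, 1]


def test_load_rejects_incomplete_table(tmp_path):
    d = tmp_path / "net"
    d.mkdir()
    (d / "A.txt").write_text("node: A\narity: 2\nregulators: A\n0 0\n")
    with pytest.raises(NetworkValidationError, match="missing combination"):
        load_network(d)


def test_load_rejects_duplicate_row(tmp_path):
    d = tmp_path / "net"
    d.mkdir()
    (d / "A.txt").write_text("node: A\narity: 2\nregulators: A\n0 0\n0 1\n")
    with pytest.raises(NetworkValidationError, match="duplicated"):
        load_network(d)


def test_load_rejects_out_of_range_output(tmp_path):
    d = tmp_path / "net"
    d.mkdir()
    (d / "A.txt").write_text("node: A\narity: 2\nregulators: A\n0 0\n1 2\n")
    with pytest.raises(NetworkValidationError, match="outside"):
        load_network(d)


def test_load_rejects_regulator_without_file(tmp_path):
    d = tmp_path / "net"
    d.mkdir()
    (d / "A.txt").write_text("node: A\narity: 2\nregulators: B\n0 0\n1 1\n")
    with pytest.raises(NetworkValidationError, match="B"):
        load_network(d)


def test_load_rejects_malformed_rows(tmp_path):
    d = tmp_path / "net"
    d.mkdir()
    (d / "A.txt").write_text("node: A\narity: 2\nregulators: A\n0 0 0\n1 1\n")
    with pytest.raises(NetworkFormatError, match="columns"):
        load_network(d)


def test_replace_rule_bounds_checking(identity_net):
    with pytest.raises(ValueError):
        identity_net.replace_rule("A", 0, 5)
    with pytest.raises(IndexError):
        identity_net.replace_rule("A", 9, 0)
    modified = identity_net.replace_rule("A", 0, 1)
    assert list(modified.tables["A"].outputs) == [1, 1]
    # original untouched
    assert list(identity_net.tables["A"].outputs) == [0, 1]
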