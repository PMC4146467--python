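import numpy as np
import pytest

from saspnet.network import LogicalNetwork, NodeSpec, RegulatoryTable


@pytest.fixture(scope="session")
def sasp():
    from saspnet.sasp import load_sasp

    return load_sasp()


@pytest.fixture(scope="session")
def sasp_engine(sasp):
    """Engine with the speract-activated clamp and a full transition map."""
    from saspnet.dynamics import Engine
    from saspnet.sasp import SPERACT_ACTIVATED

    return Engine(sasp, SPERACT_ACTIVATED.as_clamps("speract-on"))


def make_network(rules: dict[str, tuple[int, tuple[str, ...], callable]]) -> LogicalNetwork:
    """Build a small network from {name: (arity, regulators, rule)}."""
    from itertools import product

    nodes, tables = [], {}
    for name, (arity, regs, rule) in rules.items():
        nodes.append(NodeSpec(name, arity, regs))
        if regs:
            reg_arities = tuple(rules[r][0] for r in regs)
            outs = [
                rule(*combo)
                for combo in product(*(range(a) for a in reg_arities))
            ]
            tables[name] = RegulatoryTable(name, reg_arities, np.array(outs, np.int8))
    return LogicalNetwork(nodes, tables)


@pytest.fixture
def identity_net():
    """Single self-copying binary node."""
    return make_network({"A": (2, ("A",), lambda a: a)})


@pytest.fixture
def swap_net():
    """Two nodes copying each other: (0,1) -> (1,0)."""
    return make_network(
        {"A": (2, ("B",), lambda b: b), "B": (2, ("A",), lambda a: a)}
    )


@pytest.fixture
def constant_net():
    """Binary node forced to 1 whatever its state."""
    return make_network({"A": (2, ("A",), lambda a: 1)})
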