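"""Ensemble-averaged traces: exactness, reproducibility, summaries."""

import numpy as np
import pytest

from saspnet.dynamics import ICPolicy, basin_statistics
from saspnet.ensemble import compare_to_wt, ensemble_average, summarize
from saspnet.synthetic import random_network, ring_fixture
from tests.conftest import make_network


def test_constant_node_gives_flat_series(constant_net):
    series = ensemble_average(
        constant_net, node="A", n_ic=50, seed=0, t_max=30, transient=5
    )
    assert np.allclose(series.values, 1.0)


def test_series_within_node_range():
    net = random_network(5, arity_choices=(2, 3), in_degree=2, seed=12)
    name = net.nodes[0].name
    series = ensemble_average(net, node=name, n_ic=200, seed=3, t_max=50, transient=20)
    assert series.values.min() >= 0.0
    assert series.values.max() <= net.nodes[0].arity - 1


def test_seed_reproducibility_bitwise():
    net = random_network(6, in_degree=2, seed=9)
    kw = dict(node="n0", n_ic=500, t_max=40, transient=30)
    a = ensemble_average(net, seed=42, **kw)
    b = ensemble_average(net, seed=42, **kw)
    assert np.array_equal(a.values, b.values)
    # different seeds draw different initial-condition samples
    from saspnet.dynamics import Engine, ICPolicy

    engine = Engine(net, build_map=False)
    pol = ICPolicy()
    s1 = pol.sample_codes(engine, 500, np.random.default_rng(42))
    s2 = pol.sample_codes(engine, 500, np.random.default_rng(43))
    assert not np.array_equal(s1, s2)


def test_exhaustive_average_equals_basin_weighted_cycle_mean():
    """Linearity: the exact ensemble average of a steady-state series, averaged
    over one full module, equals the basin-fraction-weighted mean of each
    attractor's cycle average."""
    net = random_network(5, arity_choices=(2, 3), in_degree=(1, 3), seed=30)
    name = "n0"
    cat = basin_statistics(net, mode="exhaustive")
    expected = sum(
        f * rec.cycle_mean(net, name)
        for rec, f in zip(cat.records, cat.basin_fractions)
    )
    lcm = int(np.lcm.reduce(cat.periods))
    series = ensemble_average(
        net, node=name, mode="exhaustive", t_max=2 * lcm, transient=cat.transient_max
    )
    assert series.values[:lcm].mean() == pytest.approx(expected, abs=1e-12)


def test_eventual_periodicity_of_exhaustive_series():
    net = random_network(5, arity_choices=(2,), in_degree=2, seed=14)
    cat = basin_statistics(net, mode="exhaustive")
    lcm = int(np.lcm.reduce(cat.periods))
    series = ensemble_average(
        net, node="n1", mode="exhaustive", t_max=4 * lcm, transient=cat.transient_max
    )
    x = series.values
    assert np.allclose(x[: 3 * lcm], x[lcm : 4 * lcm])


def test_monte_carlo_converges_to_exhaustive():
    net = random_network(5, arity_choices=(2,), in_degree=2, seed=18)
    exact = ensemble_average(net, node="n2", mode="exhaustive", t_max=20, transient=40)
    approx = ensemble_average(net, node="n2", n_ic=40_000, seed=5, t_max=20, transient=40)
    # binomial-style Monte-Carlo error ~ n^(-1/2)
    assert np.max(np.abs(exact.values - approx.values)) < 0.02


def test_summarize_flat_series():
    stats = summarize(np.full(60, 1.5), window=50)
    assert stats.mean == stats.peak == 1.5
    assert stats.amplitude == 0.0
    assert stats.interpeak_interval == float("inf")


def test_summarize_alternating_series():
    x = np.tile([0.5, 1.5], 30)
    stats = summarize(x, window=50)
    assert stats.amplitude == pytest.approx(1.0)
    assert stats.peak == pytest.approx(1.5)
    assert stats.mean == pytest.approx(1.0)
    assert stats.interpeak_interval == pytest.approx(2.0)


def test_summarize_requires_window_of_data():
    with pytest.raises(ValueError):
        summarize(np.zeros(10), window=50)


def test_compare_to_wt_arrows():
    base = summarize(np.tile([0.0, 1.0], 30), window=50)
    assert compare_to_wt(base, base) == type(compare_to_wt(base, base))(
        "equal", "equal", "equal"
    )
    higher = summarize(np.tile([0.0, 2.0], 30), window=50)
    arrows = compare_to_wt(base, higher)
    assert arrows.amplitude == "up" and arrows.peak == "up" and arrows.mean == "up"
    lower = summarize(np.tile([0.0, 0.5], 30), window=50)
    arrows = compare_to_wt(base, lower)
    assert arrows.peak == "down"


def test_compare_rejects_mismatched_windows():
    a = summarize(np.zeros(60), window=50)
    b = summarize(np.zeros(60), window=40)
    with pytest.raises(ValueError):
        compare_to_wt(a, b)


def test_policy_restricts_ensemble_space():
    """With every node fixed the ensemble is a single trajectory."""
    net = ring_fixture(4)
    policy = ICPolicy(fixed=tuple((f"r{i}", 1 if i == 0 else 0) for i in range(4)))
    series = ensemble_average(
        net, node="r0", mode="exhaustive", ic_policy=policy, t_max=8, transient=0
    )
    # policy clamps hold every node fixed, so the trace is constant
    assert np.allclose(series.values, series.values[0])
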