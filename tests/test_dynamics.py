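"""Synchronous update, attractor detection and basin statistics."""

import math

import numpy as np
import pytest

from saspnet.dynamics import (
    Engine,
    ICPolicy,
    basin_statistics,
    find_attractor,
    max_transient,
    rule_perturbation_scan,
    simulate,
    step,
)
from saspnet.network import NetworkState
from saspnet.perturbations import WT, PerturbationSpec, knockout
from saspnet.synthetic import (
    multi_ring_fixture,
    one_hot_ic,
    random_network,
    ring_fixture,
)


def test_identity_network_fixed_point(identity_net):
    assert step(identity_net, [1]).values == (1,)
    assert step(identity_net, [0]).values == (0,)


def test_swap_network_swaps(swap_net):
    assert step(swap_net, [0, 1]).values == (1, 0)
    assert step(swap_net, [1, 0]).values == (0, 1)


def test_update_is_simultaneous(swap_net):
    """(1,1) and (0,0) are fixed points of the mutual copy: reads precede writes."""
    assert step(swap_net, [1, 1]).values == (1, 1)
    assert step(swap_net, [0, 0]).values == (0, 0)


def test_step_rejects_mismatched_state(identity_net):
    with pytest.raises(Exception):
        step(identity_net, [0, 1])


@pytest.mark.parametrize("seed", range(5))
def test_vectorized_step_matches_reference(seed):
    """The Engine batch path reproduces independent per-node table lookups."""
    net = random_network(6, in_degree=(1, 3), seed=seed)
    engine = Engine(net, build_map=False)
    rng = np.random.default_rng(seed)
    vals = np.stack(
        [rng.integers(0, net.arities[i], size=32) for i in range(net.n_nodes)],
        axis=1,
    ).astype(np.int8)
    batch = engine.step_values(vals)
    for row_in, row_out in zip(vals, batch):
        assert tuple(row_out) == step(net, list(row_in)).values


@pytest.mark.parametrize("seed", range(3))
def test_transition_map_agrees_with_direct_stepping(seed):
    net = random_network(5, in_degree=(1, 2), seed=seed)
    with_map = Engine(net, build_map=True)
    without = Engine(net, build_map=False)
    codes = np.arange(with_map.n_states, dtype=np.int64)
    assert np.array_equal(with_map.step_codes(codes), without.step_codes(codes))


def test_encode_decode_roundtrip_and_lex_order():
    net = random_network(5, in_degree=2, seed=7)
    engine = Engine(net, build_map=False)
    codes = np.arange(engine.n_states, dtype=np.int64)
    assert np.array_equal(engine.encode(engine.decode(codes)), codes)
    # integer order of codes == lexicographic order of state vectors
    vals = engine.decode(codes)
    order = np.lexsort(vals[:, ::-1].T)
    assert np.array_equal(order, codes)


def test_simulate_t_zero_returns_initial(identity_net):
    traj = simulate(identity_net, [1], 0)
    assert len(traj) == 1 and traj[0].values == (1,)


def test_simulate_matches_stepwise_replay():
    net = random_network(3, in_degree=(1, 2), seed=11)
    init = [0] * 3
    traj = simulate(net, init, 20)
    state = NetworkState(init)
    for t in range(21):
        assert traj[t].values == state.values
        state = step(net, state)


def test_simulate_is_deterministic():
    net = random_network(4, in_degree=2, seed=5)
    a = simulate(net, [0, 1, 0, 1], 30)
    b = simulate(net, [0, 1, 0, 1], 30)
    assert all(x.values == y.values for x, y in zip(a.states, b.states))


def test_constant_network_attractor(constant_net):
    transient, rec = find_attractor(constant_net, [1])
    assert (transient, rec.period) == (0, 1)
    transient, rec = find_attractor(constant_net, [0])
    assert (transient, rec.period) == (1, 1)


@pytest.mark.parametrize("p", range(1, 13))
def test_ring_attractor_period(p):
    """One-hot shift register has an exact p-cycle; period is minimal."""
    net = ring_fixture(p)
    transient, rec = find_attractor(net, one_hot_ic(net))
    assert transient == 0
    assert rec.period == p
    # closure: one step maps each cycle member to the next
    for j, state in enumerate(rec.cycle):
        assert step(net, state).values == rec.cycle[(j + 1) % p].values
    # minimality: no proper divisor of p also maps the cycle onto itself
    for d in range(1, p):
        if p % d == 0:
            assert rec.cycle[d % p].values != rec.cycle[0].values


def test_attractor_representative_is_lexicographic_minimum():
    net = ring_fixture(5)
    _, rec = find_attractor(net, one_hot_ic(net))
    assert rec.representative.values == min(s.values for s in rec.cycle)


def test_multi_ring_period_is_lcm():
    net = multi_ring_fixture([8, 9])
    _, rec = find_attractor(net, one_hot_ic(net))
    assert rec.period == 72


def test_basin_constant_network(constant_net):
    cat = basin_statistics(constant_net, mode="exhaustive")
    assert len(cat.records) == 1
    assert cat.basin_fractions[0] == 1.0
    assert cat.n_ic == 2


def test_basin_exhaustive_matches_brute_force():
    """Vectorized basin analysis agrees with per-IC hash-map detection."""
    net = random_network(4, arity_choices=(2, 3), in_degree=(1, 3), seed=21)
    cat = basin_statistics(net, mode="exhaustive")
    from collections import Counter

    engine = Engine(net, build_map=False)
    counter: Counter = Counter()
    transients = []
    for code in range(net.n_states):
        state = list(engine.decode(np.array([code]))[0])
        transient, rec = find_attractor(net, state)
        counter[tuple(s.values for s in rec.cycle)] += 1
        transients.append(transient)
    assert cat.n_ic == net.n_states
    got = {
        tuple(s.values for s in r.cycle): c
        for r, c in zip(cat.records, cat.basin_counts)
    }
    assert got == dict(counter)
    assert cat.transient_max == max(transients)
    assert cat.transient_mean == pytest.approx(np.mean(transients))
    assert cat.basin_counts.sum() == net.n_states


def test_basin_sample_converges_to_exhaustive():
    """Sampled fractions within 3 binomial SEs of exact fractions."""
    net = random_network(6, arity_choices=(2,), in_degree=(1, 3), seed=33)
    exact = basin_statistics(net, mode="exhaustive")
    n = 20_000
    sampled = basin_statistics(net, mode="sample", n=n, seed=99)
    exact_by_rep = {
        r.representative.values: f
        for r, f in zip(exact.records, exact.basin_fractions)
    }
    for rec, frac in zip(sampled.records, sampled.basin_fractions):
        f = exact_by_rep[rec.representative.values]
        se = math.sqrt(f * (1 - f) / n)
        assert abs(frac - f) <= max(3 * se, 1e-12)


def test_basin_sampling_is_seed_reproducible():
    net = random_network(5, in_degree=2, seed=4)
    a = basin_statistics(net, mode="sample", n=500, seed=7)
    b = basin_statistics(net, mode="sample", n=500, seed=7)
    assert np.array_equal(a.basin_counts, b.basin_counts)
    assert a.transient_max == b.transient_max


def test_basin_sample_requires_seed_and_positive_n():
    net = ring_fixture(2)
    with pytest.raises(ValueError):
        basin_statistics(net, mode="sample", n=0, seed=1)
    with pytest.raises(ValueError):
        basin_statistics(net, mode="sample", n=10)


def test_max_transient_accessor(constant_net):
    cat = basin_statistics(constant_net, mode="exhaustive")
    assert max_transient(cat) == 1  # state 0 needs one step to reach the fixed point


def test_ic_policy_fixes_dimensions():
    net = random_network(5, arity_choices=(2,), in_degree=2, seed=8)
    policy = ICPolicy(fixed=(("n0", 1),))
    engine = Engine(net, policy.as_clamps(), build_map=False)
    codes = policy.enumerate_codes(engine)
    assert codes.size == 16  # 2**4 free dimensions
    assert np.all(engine.node_digit(codes, "n0") == 1)
    rng = np.random.default_rng(0)
    sampled = policy.sample_codes(engine, 50, rng)
    assert np.all(engine.node_digit(sampled, "n0") == 1)


def test_rule_perturbation_noop_leaves_observable_unchanged():
    net = random_network(4, in_degree=2, seed=2)
    obs = lambda n: tuple(
        sorted(basin_statistics(n, mode="exhaustive").periods)
    )
    row = 1
    same = int(net.tables["n0"].outputs[row])
    rec = rule_perturbation_scan(net, "n0", row, same, obs)
    assert not rec.changed


def test_rule_perturbation_scan_reports_both_sides():
    net = ring_fixture(3)
    obs = lambda n: tuple(sorted(basin_statistics(n, mode="exhaustive").periods))
    rec = rule_perturbation_scan(net, "r0", 0, 1, obs)
    assert rec.old_output == 0 and rec.new_output == 1
    assert rec.reference == obs(ring_fixture(3))


def test_rule_perturbation_rejects_out_of_range():
    net = ring_fixture(3)
    with pytest.raises(ValueError):
        rule_perturbation_scan(net, "r0", 0, 2, lambda n: None)
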