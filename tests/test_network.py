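"""Unit and property tests for the threshold-network perturbation model."""

import itertools

import numpy as np
import pytest

from volvoloss.network import (
    NoViableNetworkError,
    RegulatoryNetwork,
    SimulationConfig,
    ViableNetworkSet,
    connectivity_sweep,
    delete_genes,
    duplicate_genes,
    find_fixed_point,
    hamming,
    run_ensemble,
    sample_modular_adjacency,
    sample_network,
    sample_state,
    sample_viable_network,
    sign_threshold,
    update_state,
)


# --- elementary operations -------------------------------------------------


@pytest.mark.parametrize("x,expected", [(3.2, 1), (-0.5, -1), (0.0, 1)])
def test_sign_threshold_values(x, expected):
    assert sign_threshold(x) == expected


@pytest.mark.parametrize("bad", [float("nan"), float("inf"), float("-inf")])
def test_sign_threshold_rejects_nonfinite(bad):
    with pytest.raises(ValueError):
        sign_threshold(bad)


def test_sample_state_reproducible_and_balanced():
    a = sample_state(4, np.random.default_rng(7))
    b = sample_state(4, np.random.default_rng(7))
    np.testing.assert_array_equal(a, b)
    assert set(np.unique(a)) <= {-1, 1}
    big = sample_state(10_000, np.random.default_rng(1))
    # binomial 99% interval at n = 10^4
    assert abs((big == 1).mean() - 0.5) < 0.02
    assert sample_state(1, np.random.default_rng(0))[0] in (-1, 1)
    with pytest.raises(ValueError):
        sample_state(0, np.random.default_rng(0))


def test_sample_network_dense_mask_statistics():
    full = sample_network(10, 1.0, rng=np.random.default_rng(0))
    assert np.count_nonzero(full.weights) == 100
    half = sample_network(50, 0.5, rng=np.random.default_rng(1))
    frac = np.count_nonzero(half.weights) / 2500
    assert abs(frac - 0.5) < 0.03  # binomial interval for 2500 draws
    pooled = np.concatenate(
        [sample_network(20, 1.0, rng=np.random.default_rng(s)).weights.ravel() for s in range(3)]
    )
    se = 1 / np.sqrt(pooled.size)
    assert abs(pooled.mean()) < 3 * se
    assert abs(pooled.var() - 1.0) < 3 * np.sqrt(2 / pooled.size)
    with pytest.raises(ValueError):
        sample_network(5, 0.0)
    with pytest.raises(ValueError):
        sample_network(5, 1.2)


def test_sample_network_exact_count_mask():
    net = sample_network(20, 0.3, rng=np.random.default_rng(0), exact_count=True)
    assert np.count_nonzero(net.weights) == round(0.3 * 400)


def test_modular_adjacency_block_structure():
    rng = np.random.default_rng(0)
    one = sample_modular_adjacency(10, 1, rng=rng, p_in=1.0)
    assert one.all()  # single module containing everything
    singletons = sample_modular_adjacency(10, 10, rng=rng, p_in=1.0, p_out=0.0)
    assert np.array_equal(singletons, np.eye(10, dtype=np.int8))
    dens_in, dens_out = [], []
    for s in range(20):
        adj = sample_modular_adjacency(20, 4, rng=np.random.default_rng(s))
        blocks = np.array_split(np.arange(20), 4)
        mask = np.zeros((20, 20), bool)
        for b in blocks:
            mask[np.ix_(b, b)] = True
        dens_in.append(adj[mask].mean())
        dens_out.append(adj[~mask].mean())
    assert np.mean(dens_in) > np.mean(dens_out)
    with pytest.raises(ValueError):
        sample_modular_adjacency(5, 6, rng=rng)


def test_update_state_basic_maps():
    assert np.array_equal(update_state([1, -1], [[1, 0], [0, 1]]), [1, -1])
    assert np.array_equal(update_state([1, -1], [[0, 1], [1, 0]]), [-1, 1])
    w = np.ones((3, 3))
    w[1, :] = 0
    w[:, 1] = 0
    out = update_state([1, 0, -1], w, deleted=np.array([False, True, False]))
    assert out[1] == 0
    with pytest.raises(ValueError):
        update_state([1, -1, 1], [[1, 0], [0, 1]])


def test_find_fixed_point_identity_and_cycle():
    res = find_fixed_point([1, -1], [[1, 0], [0, 1]])
    assert res.converged and res.steps == 0
    np.testing.assert_array_equal(res.equilibrium, [1, -1])
    cyc = find_fixed_point([1, -1], [[0, 1], [1, 0]], max_iters=100)
    assert not cyc.converged and cyc.equilibrium is None


def _enumerate_oracle(w, s0, max_iters=100):
    """Brute-force classification via the full {-1,+1}^N transition graph."""
    n = len(s0)
    def step(s):
        h = w @ np.array(s, dtype=float)
        return tuple(-1 if x < 0 else 1 for x in h)
    transitions = {s: step(s) for s in itertools.product((-1, 1), repeat=n)}
    cur = tuple(s0)
    for t in range(max_iters):
        nxt = transitions[cur]
        if nxt == cur:
            return True, cur, t
        cur = nxt
    return False, None, max_iters


def test_fixed_point_matches_state_space_enumeration():
    rng = np.random.default_rng(123)
    for _ in range(100):
        w = rng.standard_normal((3, 3))
        s0 = sample_state(3, rng)
        got = find_fixed_point(s0, w)
        conv, eq, steps = _enumerate_oracle(w, s0)
        assert got.converged == conv
        if conv:
            assert tuple(got.equilibrium) == eq
            assert got.steps == steps


# --- viability sampling ----------------------------------------------------


def _n1_config(attempts=60):
    return SimulationConfig(
        n_genes=1, k_values=(), max_rejection_attempts=attempts, seed=0
    )


def test_viable_network_n1_analytic_cases():
    """For N = 1 only S_eq = S(0) is reachable, via w > 0 when S(0) = +1."""
    successes = attempts = 0
    for seed in range(60):
        rng = np.random.default_rng(seed)
        peek = np.random.default_rng(seed)
        s0 = sample_state(1, peek)[0]
        seq = sample_state(1, peek)[0]
        if s0 == seq:
            viable = sample_viable_network(_n1_config(), rng)
            assert viable.network.weights[0, 0] * 1 > 0  # w11 > 0 either way
            np.testing.assert_array_equal(viable.equilibrium, viable.initial)
            successes += 1
            attempts += viable.attempts_used
        else:
            with pytest.raises(NoViableNetworkError):
                sample_viable_network(_n1_config(), rng)
    # acceptance probability per draw is 1/2 => mean attempts ~ 2
    assert 1.3 < attempts / successes < 3.0


def test_viable_network_fixed_point_contract():
    cfg = SimulationConfig(n_genes=5, k_values=(1,), max_rejection_attempts=100_000, seed=3)
    rng = np.random.default_rng(11)
    viable = sample_viable_network(cfg, rng)
    np.testing.assert_array_equal(
        update_state(viable.equilibrium, viable.network), viable.equilibrium
    )


# --- perturbations ---------------------------------------------------------


def _viable(n=4, seed=0):
    rng = np.random.default_rng(seed)
    w = rng.standard_normal((n, n))
    s = sample_state(n, rng)
    return ViableNetworkSet(s, RegulatoryNetwork(w), s.copy())


def test_delete_genes_zeroes_rows_columns_and_state():
    viable = _viable(3)
    s0, net, idx = delete_genes(viable, 1, np.random.default_rng(5))
    (i,) = idx
    assert not net.weights[i, :].any() and not net.weights[:, i].any()
    assert s0[i] == 0
    keep = [j for j in range(3) if j != i]
    np.testing.assert_array_equal(
        net.weights[np.ix_(keep, keep)], viable.network.weights[np.ix_(keep, keep)]
    )
    np.testing.assert_array_equal(s0[keep], viable.initial[keep])


def test_delete_all_genes_gives_zero_system():
    viable = _viable(3)
    s0, net, idx = delete_genes(viable, 3, np.random.default_rng(0))
    assert not net.weights.any() and not s0.any()
    with pytest.raises(ValueError):
        delete_genes(viable, 4, np.random.default_rng(0))


def test_delete_genes_off_state_variant():
    viable = _viable(3)
    s0, _, idx = delete_genes(viable, 2, np.random.default_rng(1), deleted_state=-1)
    assert all(s0[i] == -1 for i in idx)


def test_duplicate_single_gene_structure():
    a = 0.7
    viable = ViableNetworkSet(
        np.array([1], dtype=np.int8), RegulatoryNetwork([[a]]), np.array([1], dtype=np.int8)
    )
    s0, net, idx = duplicate_genes(viable, 1, np.random.default_rng(0))
    np.testing.assert_allclose(net.weights, [[a, a], [a, a]])
    np.testing.assert_array_equal(s0, [1, 1])


def test_duplicate_copy_tracks_original():
    viable = _viable(5, seed=2)
    s0, net, idx = duplicate_genes(viable, 2, np.random.default_rng(3))
    n = 5
    state = s0
    for _ in range(10):
        state = update_state(state, net)
        for j, orig in enumerate(idx):
            assert state[n + j] == state[orig]
    # original block equals the source network
    np.testing.assert_array_equal(net.weights[:n, :n], viable.network.weights)


def test_hamming_counts_and_errors():
    assert hamming([1, 1, -1], [1, -1, -1]) == 1
    assert hamming([1, -1], [1, -1]) == 0
    assert hamming([0, 0, 1], [1, -1, 1]) == 2
    with pytest.raises(ValueError):
        hamming([1], [1, -1])


# --- ensembles -------------------------------------------------------------


SMALL = SimulationConfig(n_genes=6, k_values=(1, 2, 3), trials_per_k=80, seed=9)


def test_ensemble_deterministic_under_seed():
    a = run_ensemble(SMALL, "deletion")
    b = run_ensemble(SMALL, "deletion")
    assert a == b


def test_ensemble_proportions_and_floor():
    for mode in ("deletion", "duplication"):
        for res, extra in run_ensemble(SMALL, mode, return_trials=True):
            assert 0.0 <= res.proportion_novel_stable <= 1.0
            assert res.n_nonconverged <= res.trials
            if mode == "deletion":
                conv = extra["converged"]
                assert (extra["d_h"][conv] >= res.k).all()


def test_ensemble_k_sweep_independent_of_other_k():
    """Each k uses its own substream: a subset sweep reproduces the full one."""
    full = run_ensemble(SMALL, "duplication")
    import dataclasses

    only_k2 = run_ensemble(dataclasses.replace(SMALL, k_values=(2,)), "duplication")
    assert only_k2[0] == full[1]


def test_connectivity_sweep_matches_run_ensemble():
    cfg = SimulationConfig(n_genes=6, k_values=(2,), trials_per_k=50, seed=4)
    sweep = connectivity_sweep(cfg, [1.0], fixed_k=2)
    direct = run_ensemble(cfg, "deletion")
    assert sweep[0] == direct[0]
    low = connectivity_sweep(cfg, [0.3], fixed_k=2)[0]
    assert 0.0 <= low.proportion_novel_stable <= 1.0


def test_perturbed_nonconvergence_grows_with_connectivity():
    """Near-decoupled sparse networks relax to fixed points far more readily
    than fully connected ones after a deletion."""
    results = connectivity_sweep(
        SimulationConfig(n_genes=10, k_values=(2,), trials_per_k=200, seed=4),
        [0.1, 1.0],
        fixed_k=2,
    )
    assert results[0].n_nonconverged < results[1].n_nonconverged


def test_modular_topology_ensemble_runs():
    cfg = SimulationConfig(
        n_genes=8, k_values=(2,), trials_per_k=30, topology="modular", seed=2
    )
    res = run_ensemble(cfg, "deletion")[0]
    assert res.trials == 30 and 0.0 <= res.proportion_novel_stable <= 1.0


def test_deletion_exceeds_duplication_pooled_intermediate_k():
    """Directional claim: gene deletion yields novel stable states more often
    than duplication, pooled over intermediate k among converged trials."""
    from scipy.stats import fisher_exact

    cfg = SimulationConfig(
        n_genes=10, k_values=(2, 3, 4, 5, 6, 7), trials_per_k=300, seed=0
    )
    novel = {}
    conv_n = {}
    for mode in ("deletion", "duplication"):
        novel[mode] = conv_n[mode] = 0
        for res, extra in run_ensemble(cfg, mode, return_trials=True):
            novel[mode] += int(extra["novel"].sum())
            conv_n[mode] += int(extra["converged"].sum())
    table = [
        [novel["deletion"], conv_n["deletion"] - novel["deletion"]],
        [novel["duplication"], conv_n["duplication"] - novel["duplication"]],
    ]
    _, p = fisher_exact(table, alternative="greater")
    assert (
        novel["deletion"] / conv_n["deletion"]
        > novel["duplication"] / conv_n["duplication"]
    )
    assert p < 0.01


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n_genes=5, k_values=(5,))
    with pytest.raises(ValueError):
        SimulationConfig(connectivity=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(trials_per_k=0)
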