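"""Multilocus HMM: oracle equivalence, EM behavior, phasing, order selection."""

import itertools
import math

import numpy as np
import pytest

from polymap import simulate as sim
from polymap.core import haldane_inv
from polymap.haplotypes import genotype_posteriors
from polymap.hmm import (
    EmissionModel,
    PhasedMap,
    compare_orders,
    drop_inflating_markers,
    insert_constrained_markers,
    multipoint_loglik,
    phase_markers,
    reestimate_rfs,
)


# ---------------------------------------------------------------------------
# independent brute-force oracle: exhaustive enumeration over state paths


def _oracle_loglik_and_marginals(pm, dosage, m, eps):
    """Likelihood and per-marker state marginals by explicit path enumeration."""
    k = m // 2
    gams = list(itertools.combinations(range(m), k))
    G = len(gams)
    z = pm.n_markers

    def trans(r):
        T = np.zeros((G, G))
        for i, a in enumerate(gams):
            for j, b in enumerate(gams):
                l = len(set(a) - set(b))
                T[i, j] = r ** l * (1 - r) ** (k - l) / math.comb(m - k, l)
        return T

    Ts = [trans(r) for r in pm.rf]
    states = [(i, j) for i in range(G) for j in range(G)]

    def emit(t, obs_d, si):
        gP, gQ = states[si]
        d = int(
            pm.phase_P[t][list(gams[gP])].sum() + pm.phase_Q[t][list(gams[gQ])].sum()
        )
        if np.isnan(obs_d):
            return 1.0
        if d == int(obs_d):
            return 1.0 - eps
        return eps / m if eps > 0 else 0.0

    total_ll = 0.0
    marginals = np.zeros((z, len(states)))
    n = dosage.shape[1]
    for ind in range(n):
        like = 0.0
        marg = np.zeros((z, len(states)))
        for path in itertools.product(range(len(states)), repeat=z):
            p = 1.0 / len(states)
            for t in range(z):
                p *= emit(t, dosage[t, ind], path[t])
                if t > 0:
                    aP, aQ = states[path[t - 1]]
                    bP, bQ = states[path[t]]
                    p *= Ts[t - 1][aP, bP] * Ts[t - 1][aQ, bQ]
            like += p
            for t in range(z):
                marg[t, path[t]] += p
        total_ll += np.log(like)
        marginals += marg / like
    return total_ll, marginals / n


def _tiny_instance(m, z, n, seed):
    rng = np.random.default_rng(seed)
    parents = sim.simulate_parents(m, z, 10.0 * (z - 1), seed=rng)
    truth = sim.simulate_population(parents, n, seed=rng)
    obs = sim.observe_dosages(truth, seed=rng)
    rf = np.clip(haldane_inv(np.diff(parents[0].positions_cM)), 1e-6, 0.4999)
    pm = PhasedMap(
        np.arange(z),
        parents[0].allele_matrix.astype(np.int8),
        parents[1].allele_matrix.astype(np.int8),
        rf,
    )
    return pm, obs


@pytest.mark.parametrize("m,z,n,seed", [(2, 3, 4, 0), (2, 4, 5, 1), (4, 3, 3, 2)])
def test_multipoint_loglik_matches_path_enumeration(m, z, n, seed):
    pm, obs = _tiny_instance(m, z, n, seed)
    eps = 0.02
    ll = multipoint_loglik(pm, obs, EmissionModel("dosage", eps))
    oracle_ll, _ = _oracle_loglik_and_marginals(pm, obs.dosage, m, eps)
    assert abs(ll - oracle_ll) < 1e-8


@pytest.mark.parametrize("m,z,n,seed", [(2, 3, 3, 3), (4, 3, 2, 4)])
def test_posteriors_match_path_enumeration(m, z, n, seed):
    pm, obs = _tiny_instance(m, z, n, seed)
    eps = 0.05
    post = genotype_posteriors(pm, obs, EmissionModel("dosage", eps))
    _, oracle_marg = _oracle_loglik_and_marginals(pm, obs.dosage, m, eps)
    G = post.post.shape[2]
    ours = post.post.mean(axis=1).reshape(z, G * G)
    np.testing.assert_allclose(ours, oracle_marg, atol=1e-9)


def test_loglik_deterministic_and_gauge_invariant(tetra_clean):
    parents, _, obs = tetra_clean
    rf = np.clip(haldane_inv(np.diff(parents[0].positions_cM)), 1e-6, 0.4999)
    pm = PhasedMap(
        np.arange(parents[0].n_markers),
        parents[0].allele_matrix.astype(np.int8),
        parents[1].allele_matrix.astype(np.int8),
        rf,
    )
    em = EmissionModel("dosage", 0.01)
    ll1 = multipoint_loglik(pm, obs, em)
    ll2 = multipoint_loglik(pm, obs, em)
    assert ll1 == ll2
    rng = np.random.default_rng(0)
    for _ in range(3):
        perm = rng.permutation(4)
        pm2 = PhasedMap(pm.markers, pm.phase_P[:, perm], pm.phase_Q, pm.rf)
        assert abs(multipoint_loglik(pm2, obs, em) - ll1) < 1e-8


def test_em_monotone_and_recovers_rf(tetra_clean):
    parents, _, obs = tetra_clean
    z = parents[0].n_markers
    pm = PhasedMap(
        np.arange(z),
        parents[0].allele_matrix.astype(np.int8),
        parents[1].allele_matrix.astype(np.int8),
        np.full(z - 1, 0.2),
    )
    em = EmissionModel("dosage", 0.0)
    lls = []
    cur = pm
    for _ in range(15):
        cur = reestimate_rfs(cur, obs, em, tol=0.0, max_iter=1)
        lls.append(cur.loglik)
    assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))
    true_r = haldane_inv(np.diff(parents[0].positions_cM))
    assert np.abs(cur.rf - true_r).mean() < 0.05


def test_zero_recombination_data_collapses_rfs():
    rng = np.random.default_rng(9)
    parents = sim.simulate_parents(4, 6, 1e-6, seed=rng)
    truth = sim.simulate_population(parents, 100, seed=rng)
    obs = sim.observe_dosages(truth, seed=rng)
    z = 6
    pm = PhasedMap(
        np.arange(z),
        parents[0].allele_matrix.astype(np.int8),
        parents[1].allele_matrix.astype(np.int8),
        np.full(z - 1, 0.1),
    )
    pm = reestimate_rfs(pm, obs, EmissionModel("dosage", 0.0), tol=1e-6, max_iter=60)
    assert pm.rf.max() < 0.01


def _canon(A):
    return np.array(sorted(map(tuple, A.T))).T


def test_phase_markers_recovers_truth(tetra_clean):
    parents, _, obs = tetra_clean
    pm = phase_markers(
        range(parents[0].n_markers), obs, emission=EmissionModel("dosage", 0.01)
    )
    assert not pm.dropped
    np.testing.assert_array_equal(
        _canon(pm.phase_P), _canon(parents[0].allele_matrix[pm.markers])
    )
    np.testing.assert_array_equal(
        _canon(pm.phase_Q), _canon(parents[1].allele_matrix[pm.markers])
    )


def test_compare_orders_prefers_truth(tetra_clean):
    parents, _, obs = tetra_clean
    z = parents[0].n_markers
    true_order = list(range(z))
    swapped = true_order.copy()
    swapped[3], swapped[6] = swapped[6], swapped[3]
    em = EmissionModel("dosage", 0.01)
    best, _, lls = compare_orders([swapped, true_order], obs, em)
    assert best == 1
    assert lls[1] > lls[0]


def test_compare_orders_resolves_block_orientation(tetra_clean):
    parents, _, obs = tetra_clean
    z = parents[0].n_markers
    true_order = list(range(z))
    inverted = true_order[:3] + true_order[3:7][::-1] + true_order[7:]
    em = EmissionModel("dosage", 0.01)
    best, _, lls = compare_orders([inverted, true_order], obs, em)
    assert best == 1


def test_compare_orders_tie_keeps_first(tetra_clean):
    _, _, obs = tetra_clean
    order = list(range(obs.n_markers))
    em = EmissionModel("dosage", 0.01)
    best, _, lls = compare_orders([order, order], obs, em)
    assert best == 0
    assert abs(lls[0] - lls[1]) < 1e-6


class TestInsertConstrainedMarkers:
    def test_anchored_marker_lands_near_truth(self, tetra_clean):
        parents, _, obs = tetra_clean
        z = parents[0].n_markers
        em = EmissionModel("dosage", 0.01)
        held_out = 5
        order = [t for t in range(z) if t != held_out]
        pm = phase_markers(order, obs, emission=em)
        pm = reestimate_rfs(pm, obs, em, tol=1e-3, max_iter=30)
        # anchor interval: between its true neighbors, with slack
        slot_truth = list(pm.markers).index(held_out - 1) + 1
        pm2, skipped = insert_constrained_markers(
            pm, [(held_out, (max(0, slot_truth - 2), slot_truth + 2))], obs, em
        )
        assert not skipped
        assert held_out in pm2.markers
        got_slot = list(pm2.markers).index(held_out)
        assert abs(got_slot - slot_truth) <= 1

    def test_empty_interval_skipped(self, tetra_clean):
        parents, _, obs = tetra_clean
        em = EmissionModel("dosage", 0.01)
        order = list(range(parents[0].n_markers - 1))
        pm = phase_markers(order, obs, emission=em)
        pm2, skipped = insert_constrained_markers(
            pm, [(parents[0].n_markers - 1, (4, 2))], obs, em
        )
        assert skipped == [parents[0].n_markers - 1]
        assert pm2.n_markers == pm.n_markers


class TestDropInflatingMarkers:
    def test_noise_marker_removed_clean_kept(self):
        rng = np.random.default_rng(15)
        parents = sim.simulate_parents(4, 10, 27.0, seed=rng)
        truth = sim.simulate_population(parents, 200, seed=rng)
        obs = sim.observe_dosages(truth, seed=rng)
        # corrupt one marker with heavy independent noise
        bad = 5
        obs.dosage[bad] = rng.integers(0, 5, obs.n_individuals).astype(float)
        obs.posterior = None
        em = EmissionModel("dosage", 0.05)
        pm = phase_markers(range(10), obs, emission=em)
        pm = reestimate_rfs(pm, obs, em, tol=1e-3, max_iter=40)
        pruned, removed = drop_inflating_markers(pm, obs, em, max_expansion_cM=2.0)
        assert bad in [mk for mk, _ in removed]

    def test_clean_map_untouched(self):
        # density matters: leave-one-out length noise shrinks with n and
        # marker spacing, so the screen is checked where it is designed
        # to operate (dense map, decent sample)
        rng = np.random.default_rng(50)
        parents = sim.simulate_parents(4, 10, 13.5, seed=rng)
        truth = sim.simulate_population(parents, 300, seed=rng)
        obs = sim.observe_dosages(truth, seed=rng)
        em = EmissionModel("dosage", 0.01)
        pm = phase_markers(range(10), obs, emission=em)
        pm = reestimate_rfs(pm, obs, em, tol=1e-3, max_iter=40)
        _, removed = drop_inflating_markers(pm, obs, em, max_expansion_cM=2.0)
        assert removed == []

    def test_minimum_marker_floor(self, tetra_clean):
        parents, _, obs = tetra_clean
        em = EmissionModel("dosage", 0.01)
        pm = phase_markers(range(parents[0].n_markers), obs, emission=em)
        pm = reestimate_rfs(pm, obs, em, tol=1e-2, max_iter=10)
        pruned, _ = drop_inflating_markers(
            pm, obs, em, max_expansion_cM=0.0, min_markers=8
        )
        assert pruned.n_markers >= 8
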