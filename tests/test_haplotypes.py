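"""Genotype posteriors, homolog inheritance profiles and GIC."""

import numpy as np
import pytest

from polymap import simulate as sim
from polymap.core import enumerate_gametes
from polymap.haplotypes import (
    GenotypePosterior,
    flag_outlier_individuals,
    genotype_posteriors,
    gic,
    homolog_probabilities,
)
from polymap.hmm import EmissionModel, PhasedMap


def _true_map(parents):
    from polymap.core import haldane_inv

    rf = haldane_inv(np.diff(parents[0].positions_cM))
    return PhasedMap(
        np.arange(parents[0].n_markers),
        parents[0].allele_matrix.astype(np.int8),
        parents[1].allele_matrix.astype(np.int8),
        np.clip(rf, 1e-6, 0.4999),
    )


def _point_posterior(m, z, n, gP, gQ):
    G = len(enumerate_gametes(m))
    post = np.zeros((z, n, G, G))
    post[:, :, gP, gQ] = 1.0
    return GenotypePosterior(
        post, np.ones(n, dtype=bool), np.arange(z), np.linspace(0, 10, z)
    )


def test_posteriors_normalized_and_accurate(hexa_clean):
    parents, truth, obs = hexa_clean
    pm = _true_map(parents)
    post = genotype_posteriors(pm, obs, EmissionModel("dosage", 0.0))
    np.testing.assert_allclose(post.post.sum(axis=(2, 3)), 1.0, atol=1e-9)
    # MAP state equals simulated truth at most positions on clean data
    gams = {g: i for i, g in enumerate(enumerate_gametes(6))}
    hit = tot = 0
    for i in range(min(60, truth.n_individuals)):
        sp = truth.meioses_P[i].sources
        sq = truth.meioses_Q[i].sources
        for t in range(pm.n_markers):
            gi = gams[tuple(sorted(sp[:, t]))]
            gj = gams[tuple(sorted(sq[:, t]))]
            flat = post.post[t, i].argmax()
            hit += flat == gi * len(gams) + gj
            tot += 1
    # 400-state MAP on a sparse random-spectrum map; homolog-level
    # accuracy (what downstream uses) is much higher and is checked at
    # mapping density in the acceptance suite
    assert hit / tot > 0.3


def test_profile_sums_to_k_and_bounds(hexa_clean):
    parents, _, obs = hexa_clean
    pm = _true_map(parents)
    post = genotype_posteriors(pm, obs, EmissionModel("dosage", 0.0))
    prof = homolog_probabilities(post, pm)
    np.testing.assert_allclose(prof.prob_P.sum(axis=2), 3.0, atol=1e-8)
    np.testing.assert_allclose(prof.prob_Q.sum(axis=2), 3.0, atol=1e-8)
    assert prof.prob_P.min() >= -1e-12 and prof.prob_P.max() <= 1 + 1e-12


def test_concentrated_posterior_gives_indicator_profile():
    m, z, n = 6, 5, 3
    post = _point_posterior(m, z, n, gP=0, gQ=7)
    pm = PhasedMap(
        np.arange(z),
        np.zeros((z, m), np.int8),
        np.zeros((z, m), np.int8),
        np.full(z - 1, 0.01),
    )
    prof = homolog_probabilities(post, pm)
    gams = enumerate_gametes(m)
    expP = np.zeros(m)
    expP[list(gams[0])] = 1.0
    expQ = np.zeros(m)
    expQ[list(gams[7])] = 1.0
    np.testing.assert_allclose(prof.prob_P[0, 0], expP)
    np.testing.assert_allclose(prof.prob_Q[0, 0], expQ)


def test_uniform_posterior_gives_half_everywhere_and_zero_gic():
    m, z, n = 6, 4, 5
    G = len(enumerate_gametes(m))
    post = GenotypePosterior(
        np.full((z, n, G, G), 1.0 / G ** 2),
        np.ones(n, dtype=bool),
        np.arange(z),
        np.linspace(0, 5, z),
    )
    pm = PhasedMap(
        np.arange(z), np.zeros((z, m), np.int8), np.zeros((z, m), np.int8),
        np.full(z - 1, 0.01),
    )
    prof = homolog_probabilities(post, pm)
    np.testing.assert_allclose(prof.prob_P, 0.5, atol=1e-12)
    gP, gQ = gic(prof)
    np.testing.assert_allclose(gP, 0.0, atol=1e-12)


def test_certain_profile_gives_full_gic():
    post = _point_posterior(6, 4, 5, 0, 0)
    pm = PhasedMap(
        np.arange(4), np.zeros((4, 6), np.int8), np.zeros((4, 6), np.int8),
        np.full(3, 0.01),
    )
    prof = homolog_probabilities(post, pm)
    gP, _ = gic(prof)
    np.testing.assert_allclose(gP, 1.0, atol=1e-12)


def test_duplicate_homologs_have_zero_gic():
    """Two homologs with identical allele content cannot be told apart."""
    rng = np.random.default_rng(23)
    z, m = 12, 6
    A = rng.integers(0, 2, (z, m)).astype(np.int8)
    A[:, 1] = A[:, 0]  # homologs 0 and 1 identical
    pos = np.linspace(0.0, 30.0, z)
    parP = sim.PhasedParent(A, pos)
    parQ = sim.PhasedParent(rng.integers(0, 2, (z, m)).astype(np.int8), pos.copy())
    truth = sim.simulate_population((parP, parQ), 120, seed=rng)
    obs = sim.observe_dosages(truth, seed=rng)
    pm = _true_map((parP, parQ))
    post = genotype_posteriors(pm, obs, EmissionModel("dosage", 0.0))
    prof = homolog_probabilities(post, pm)
    gP, _ = gic(prof)
    # the duplicated pair is ambiguous exactly when one of the two is
    # inherited (p = 1/2), so its GIC is strongly depressed relative to
    # the distinguishable homologs
    dup = gP[:, :2].mean()
    unique = gP[:, 2:].mean()
    assert dup < 0.5
    assert unique - dup > 0.25
    np.testing.assert_allclose(prof.prob_P[:, :, 0], prof.prob_P[:, :, 1], atol=1e-9)


def _rotating_simplex_parents(z=24, length=36.0, m=6):
    """Maximally informative cross for tracing parent P: each marker is
    simplex on a rotating P homolog and parent Q is nulliplex, so the
    offspring dosage directly reveals whether that homolog was inherited."""
    A = np.zeros((z, m), dtype=np.int8)
    for t in range(z):
        A[t, t % m] = 1
    pos = np.linspace(0.0, length, z)
    return sim.PhasedParent(A, pos), sim.PhasedParent(np.zeros((z, m), np.int8), pos.copy())


def test_crossover_shows_in_profile():
    parents = _rotating_simplex_parents()
    rng = np.random.default_rng(31)
    truth = sim.simulate_population(parents, 80, seed=rng)
    obs = sim.observe_dosages(truth, seed=rng)
    pm = _true_map(parents)
    post = genotype_posteriors(pm, obs, EmissionModel("dosage", 0.0))
    prof = homolog_probabilities(post, pm)
    checked = passed = 0
    for i, rec in enumerate(truth.meioses_P):
        changes = np.argwhere(rec.sources[:, :-1] != rec.sources[:, 1:])
        if len(changes) != 1:
            continue
        c, t = changes[0]
        if t < 3 or t > pm.n_markers - 4:
            continue  # terminal exchanges have one-sided information
        h_before = rec.sources[c, t]
        h_after = rec.sources[c, t + 1]
        hit = (
            prof.prob_P[t - 2, i, h_before] > 0.5
            and prof.prob_P[t + 3, i, h_after] > 0.5
        )
        passed += hit
        checked += 1
    assert checked >= 5
    assert passed / checked >= 0.8


def test_outlier_flagging():
    counts = np.r_[np.full(50, 3.0), [40.0, 35.0]]
    flags = flag_outlier_individuals(counts)
    assert flags.sum() == 2
    assert flags[-2:].all()
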