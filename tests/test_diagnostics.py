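"""Crossover heuristic, valency classification and preferential pairing."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from polymap import simulate as sim
from polymap.core import (
    consistent_configurations,
    enumerate_gametes,
    enumerate_pairing_configurations,
    gamete_index,
    haldane_inv,
)
from polymap.diagnostics import (
    build_chains,
    detect_crossovers,
    pairing_posterior,
    preferential_pairing_test,
    valency_summary,
)
from polymap.haplotypes import (
    GenotypePosterior,
    HaplotypeProfile,
    genotype_posteriors,
    homolog_probabilities,
)
from polymap.hmm import EmissionModel, PhasedMap


def _true_map(parents):
    rf = np.clip(haldane_inv(np.diff(parents[0].positions_cM)), 1e-6, 0.4999)
    return PhasedMap(
        np.arange(parents[0].n_markers),
        parents[0].allele_matrix.astype(np.int8),
        parents[1].allele_matrix.astype(np.int8),
        rf,
    )


def _profile_from_binary(BP, positions):
    """HaplotypeProfile for one individual from a hard P-homolog matrix."""
    z, m = BP.shape
    prob_P = BP.astype(float)[:, None, :]
    prob_Q = np.full((z, 1, m), 0.5)
    return HaplotypeProfile(prob_P, prob_Q, positions, np.ones(1, dtype=bool))


class _NoData:
    """Stand-in observation object for profile-only crossover tests."""

    def __init__(self, z, n, m):
        self.m = m
        self.dosage = np.full((z, n), np.nan)
        self.posterior = None
        self.dP = np.zeros(z, dtype=int)
        self.dQ = np.zeros(z, dtype=int)
        self.n_markers = z
        self.n_individuals = n


def _informative_pm(z, rf=0.01):
    """Map whose parental phase keeps every homolog locally distinguishable."""
    A = np.zeros((z, 6), dtype=np.int8)
    for t in range(z):
        A[t, t % 6] = 1
    return PhasedMap(np.arange(z), A, A.copy(), np.full(z - 1, rf))


def _clean_gamete_profile(z, positions, segments):
    """Binary profile carrying 3 homologs with crossovers as specified.

    ``segments``: list of (homolog set) per marker index range.
    """
    B = np.zeros((z, 6), dtype=bool)
    for (start, stop, homs) in segments:
        for h in homs:
            B[start:stop, h] = True
    return B


class TestDetectCrossovers:
    def test_single_crossover_called_within_2cM(self):
        z = 101
        positions = np.linspace(0.0, 100.0, z)
        B = _clean_gamete_profile(
            z, positions, [(0, 41, (0, 2, 4)), (41, z, (1, 2, 4))]
        )
        prof = _profile_from_binary(B, positions)
        pm = _informative_pm(z)
        calls, conclusive = detect_crossovers(
            prof, pm, _NoData(z, 1, 6), EmissionModel("dosage", 0.0),
            reestimate=False,
        )
        pcalls = calls[(calls["parent"] == "P") & calls["conclusive"]]
        assert len(pcalls) == 1
        true_pos = 0.5 * (positions[40] + positions[41])
        assert abs(pcalls.iloc[0]["position_cM"] - true_pos) <= 2.0
        assert {pcalls.iloc[0]["homolog_out"], pcalls.iloc[0]["homolog_in"]} == {"a", "b"}

    def test_short_blip_removed_no_call(self):
        z = 101
        positions = np.linspace(0.0, 100.0, z)
        B = _clean_gamete_profile(
            z, positions,
            [(0, 50, (0, 2, 4)), (50, 55, (1, 2, 4)), (55, z, (0, 2, 4))],
        )  # 5 cM blip on homolog 0 -> removed by the 10 cM rule
        prof = _profile_from_binary(B, positions)
        pm = _informative_pm(z)
        calls, _ = detect_crossovers(
            prof, pm, _NoData(z, 1, 6), EmissionModel("dosage", 0.0),
            reestimate=False,
        )
        assert len(calls[(calls["parent"] == "P") & calls["conclusive"]]) == 0

    def test_low_retention_inconclusive(self):
        z = 50
        positions = np.linspace(0.0, 49.0, z)
        rng = np.random.default_rng(0)
        # fragmented profile: alternating 1-2 cM segments everywhere
        B = np.zeros((z, 6), dtype=bool)
        for h in range(6):
            B[:, h] = rng.random(z) < 0.5
        prof = _profile_from_binary(B, positions)
        pm = _informative_pm(z)
        calls, conclusive = detect_crossovers(
            prof, pm, _NoData(z, 1, 6), EmissionModel("dosage", 0.0),
            reestimate=False,
        )
        assert not conclusive[0, 0]

    def test_close_exchanges_inconclusive(self):
        z = 301
        positions = np.linspace(0.0, 60.0, z)  # 0.2 cM spacing
        B = _clean_gamete_profile(
            z, positions,
            [(0, 150, (0, 2, 4)), (150, 152, (1, 2, 4)), (152, z, (1, 3, 4))],
        )
        prof = _profile_from_binary(B, positions)
        pm = _informative_pm(z, rf=0.001)
        calls, _ = detect_crossovers(
            prof, pm, _NoData(z, 1, 6), EmissionModel("dosage", 0.0),
            reestimate=False, min_segment_cM=0.0,
        )
        pc = calls[calls["parent"] == "P"]
        # the two exchanges are 0.4 cM apart -> both inconclusive
        assert len(pc) == 2
        assert not pc["conclusive"].any()

    def test_empty_profile_rejected(self):
        prof = HaplotypeProfile(
            np.zeros((0, 0, 6)), np.zeros((0, 0, 6)), np.array([]), np.array([], bool)
        )
        with pytest.raises(ValueError):
            detect_crossovers(
                prof, None, _NoData(0, 0, 6), EmissionModel("dosage", 0.0)
            )


class TestChainsAndValency:
    def _calls(self, rows):
        return pd.DataFrame(
            rows,
            columns=["individual", "parent", "position_cM",
                     "homolog_out", "homolog_in", "conclusive"],
        )

    def test_single_pair_is_bivalent(self):
        calls = self._calls([(0, "P", 10.0, "a", "b", True)])
        chains = build_chains(calls, 6)
        assert chains.iloc[0]["max_chain"] == 2

    def test_linked_pairs_form_trivalent_signature(self):
        calls = self._calls(
            [(0, "P", 10.0, "a", "b", True), (0, "P", 30.0, "b", "c", True)]
        )
        chains = build_chains(calls, 6)
        assert chains.iloc[0]["max_chain"] == 3

    def test_inconclusive_calls_excluded(self):
        calls = self._calls(
            [(0, "P", 10.0, "a", "b", True), (0, "P", 30.0, "b", "c", False)]
        )
        chains = build_chains(calls, 6)
        assert chains.iloc[0]["max_chain"] == 2

    def test_valency_summary_percentages(self):
        chains = pd.DataFrame(
            {
                "individual": [0, 1, 2, 3],
                "parent": ["P"] * 4,
                "max_chain": [2, 2, 3, 1],
            }
        )
        conclusive = np.ones((4, 2), dtype=bool)
        summ = valency_summary(chains, conclusive)
        p = summ[summ["parent"] == "P"]
        assert abs(p["percent"].sum() - 100.0) < 1e-9
        assert p.loc[p["chain_size"] == 2, "percent"].iloc[0] == 50.0


class TestPairingPosterior:
    def _uniform_posterior(self, z=4, n=6, m=6):
        G = len(enumerate_gametes(m))
        return GenotypePosterior(
            np.full((z, n, G, G), 1.0 / G ** 2),
            np.ones(n, dtype=bool),
            np.arange(z),
            np.linspace(0, 10, z),
        )

    def _pm(self, z=4, m=6):
        return PhasedMap(
            np.arange(z), np.zeros((z, m), np.int8), np.zeros((z, m), np.int8),
            np.full(z - 1, 0.01),
        )

    def test_uniform_posterior_gives_uniform_configs_and_point2_pairs(self):
        pp = pairing_posterior(self._uniform_posterior(), self._pm(), "P")
        np.testing.assert_allclose(pp.config_profile, 1.0 / 15.0, atol=1e-12)
        np.testing.assert_allclose(pp.pair_profile, 0.2, atol=1e-12)
        assert (pp.config_p > 0.999).all()

    def test_profiles_are_distributions(self):
        rng = np.random.default_rng(3)
        z, n, m = 3, 5, 6
        G = len(enumerate_gametes(m))
        raw = rng.random((z, n, G, G))
        raw /= raw.sum(axis=(2, 3), keepdims=True)
        post = GenotypePosterior(
            raw, np.ones(n, dtype=bool), np.arange(z), np.linspace(0, 5, z)
        )
        pp = pairing_posterior(post, self._pm(z), "P")
        np.testing.assert_allclose(pp.config_profile.sum(axis=1), 1.0, atol=1e-9)
        # for any fixed homolog the pair probabilities over its partners sum to 1
        for h in range(m):
            cols = [
                i for i, (a, b) in enumerate(itertools.combinations(range(m), 2))
                if h in (a, b)
            ]
            np.testing.assert_allclose(
                pp.pair_profile[:, cols].sum(axis=1), 1.0, atol=1e-9
            )

    def test_concentrated_gamete_spreads_over_consistent_configs(self):
        m, z, n = 6, 2, 4
        G = len(enumerate_gametes(m))
        g = gamete_index((0, 2, 4), m)
        post = np.zeros((z, n, G, G))
        post[:, :, g, :] = 1.0 / G  # P gamete fixed, Q uniform
        gp = GenotypePosterior(
            post, np.ones(n, dtype=bool), np.arange(z), np.linspace(0, 5, z)
        )
        pp = pairing_posterior(gp, self._pm(z), "P")
        cfgs = enumerate_pairing_configurations(m)
        consistent = set(consistent_configurations((0, 2, 4), m))
        k_fact = math.factorial(3)
        for ci, cfg in enumerate(cfgs):
            expected = 1.0 / k_fact if cfg in consistent else 0.0
            np.testing.assert_allclose(pp.config_profile[:, ci], expected, atol=1e-12)

    def test_chi2_requires_population(self):
        with pytest.raises(ValueError):
            preferential_pairing_test(np.full((2, 15), 1 / 15), np.full((2, 15), 0.2), 1, 6)


def test_simplex_repulsion_screen_matches_random_pairing():
    from polymap.diagnostics import simplex_repulsion_screen

    rng = np.random.default_rng(55)
    z, m = 30, 6
    A = np.zeros((z, m), dtype=np.int8)
    for t in range(z):
        A[t, t % m] = 1  # all markers simplex in P, rotating homolog
    pos = np.linspace(0.0, 15.0, z)  # tightly linked
    parents = (sim.PhasedParent(A, pos), sim.PhasedParent(np.zeros((z, m), np.int8), pos.copy()))
    truth = sim.simulate_population(parents, 500, seed=rng)
    obs = sim.observe_dosages(truth, seed=rng)
    pm = _true_map(parents)
    df = simplex_repulsion_screen(obs, pm, "P")
    assert len(df) > 0
    # under random pairing the co-carriage of tightly linked repulsion
    # simplex pairs sits near k(k-1)/(m(m-1)) = 0.2
    near = df[df["distance_cM"] < 3.0]
    assert abs(near["frac_both"].mean() - 0.2) < 0.05


def test_pure_bivalent_simulation_yields_no_multivalent_chains():
    rng = np.random.default_rng(77)
    z, m = 40, 6
    A = np.zeros((z, m), dtype=np.int8)
    for t in range(z):
        A[t, t % m] = 1
    pos = np.linspace(0.0, 80.0, z)
    parents = (sim.PhasedParent(A, pos), sim.PhasedParent(np.zeros((z, m), np.int8), pos.copy()))
    truth = sim.simulate_population(parents, 60, p_multi=0.0, seed=rng)
    obs = sim.observe_dosages(truth, seed=rng)
    pm = _true_map(parents)
    em = EmissionModel("dosage", 0.0)
    post = genotype_posteriors(pm, obs, em)
    prof = homolog_probabilities(post, pm)
    calls, conclusive = detect_crossovers(prof, pm, obs, em)
    chains = build_chains(calls, m)
    assert (chains["max_chain"] <= 2).all()
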