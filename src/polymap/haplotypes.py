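"""Offspring genotype posteriors, homolog inheritance profiles and GIC.

Given a phased map, the forward-backward algorithm yields for every
individual and marker a posterior distribution over all ordered pairs
of parental gametes.  Summing that posterior over the states containing
a given parental homolog produces the homolog inheritance profile: the
probability, along the linkage group, that the individual inherited
that homolog.  The per-parent profiles sum to k = m/2 at every marker
(a gamete carries k homologs).

The genotypic information content (GIC) summarizes, per homolog and
position, how distinguishable that homolog's transmission is across
the population: 1 when every individual's inheritance is certain, 0
when every probability sits at 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from polymap.core import enumerate_gametes
from polymap.hmm import EmissionModel, PhasedMap, forward_backward

__all__ = [
    "GenotypePosterior",
    "HaplotypeProfile",
    "genotype_posteriors",
    "homolog_probabilities",
    "gic",
    "flag_outlier_individuals",
]


@dataclass
class GenotypePosterior:
    """Posterior over genotype states per (marker, individual).

    ``post[t, i]`` is a (G, G) matrix over (maternal gamete, paternal
    gamete) summing to 1.
    """

    post: np.ndarray  # (z, n, G, G)
    valid: np.ndarray  # (n,) individuals with usable sequences
    markers: np.ndarray
    positions_cM: np.ndarray


@dataclass
class HaplotypeProfile:
    """Per-individual inheritance probability curves for every homolog."""

    prob_P: np.ndarray  # (z, n, m)
    prob_Q: np.ndarray  # (z, n, m)
    positions_cM: np.ndarray
    valid: np.ndarray


@lru_cache(maxsize=None)
def _inclusion_matrix(m: int) -> np.ndarray:
    gams = enumerate_gametes(m)
    inc = np.zeros((len(gams), m), dtype=float)
    for gi, g in enumerate(gams):
        inc[gi, list(g)] = 1.0
    return inc


def genotype_posteriors(
    pm: PhasedMap, data, emission: EmissionModel
) -> GenotypePosterior:
    """Forward-backward genotype-state posteriors (normalized per position).

    Individuals with an impossible observation sequence receive a
    uniform posterior and are flagged invalid.
    """
    alpha, beta, _, _, valid = forward_backward(pm, data, emission)
    z = pm.n_markers
    n = data.n_individuals
    G = alpha[0].shape[1]
    post = np.empty((z, n, G, G))
    for t in range(z):
        g = alpha[t] * beta[t]
        norm = g.sum(axis=(1, 2), keepdims=True)
        post[t] = np.where(norm > 0, g / np.maximum(norm, 1e-300), 1.0 / G ** 2)
    post[:, ~valid] = 1.0 / G ** 2
    return GenotypePosterior(post, valid, pm.markers.copy(), pm.positions_cM)


def homolog_probabilities(
    posterior: GenotypePosterior, pm: PhasedMap
) -> HaplotypeProfile:
    """Per-homolog inheritance probabilities from the state posterior.

    P(homolog h | data) at a marker is the posterior mass of all states
    whose gamete (of the corresponding parent) contains h; each
    parent's probabilities sum to k at every marker.
    """
    m = pm.m
    inc = _inclusion_matrix(m)
    margP = posterior.post.sum(axis=3)  # (z, n, G)
    margQ = posterior.post.sum(axis=2)
    prob_P = margP @ inc
    prob_Q = margQ @ inc
    return HaplotypeProfile(prob_P, prob_Q, posterior.positions_cM, posterior.valid)


def gic(profile: HaplotypeProfile) -> tuple[np.ndarray, np.ndarray]:
    """Genotypic information content per homolog along the map.

    GIC_h(t) = 1 - (4 / n) * sum_i p_ih(t) (1 - p_ih(t)); 1 when every
    individual's inheritance of h is certain, 0 when all probabilities
    equal 1/2 (h indistinguishable from its duplicate).  Returns a
    (z, m) track per parent.
    """
    n = int(profile.valid.sum())
    if n == 0:
        raise ValueError("no valid individuals")
    out = []
    for prob in (profile.prob_P, profile.prob_Q):
        p = prob[:, profile.valid, :]
        out.append(1.0 - (4.0 / n) * (p * (1.0 - p)).sum(axis=1))
    return out[0], out[1]


def flag_outlier_individuals(
    crossover_counts: np.ndarray, n_mad: float = 5.0
) -> np.ndarray:
    """Flag individuals with implausibly many inferred crossovers.

    An individual is flagged when its genome-wide crossover count
    exceeds the population median by more than ``n_mad`` median
    absolute deviations — a screen for inconsistent genotypic profiles
    (sample swaps, contamination, selfs).
    """
    counts = np.asarray(crossover_counts, dtype=float)
    med = np.median(counts)
    mad = np.median(np.abs(counts - med))
    cut = med + n_mad * max(mad, 0.5)  # floor avoids zero-MAD degeneracy
    return counts > cut
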