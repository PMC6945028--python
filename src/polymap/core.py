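"""Ploidy-generic combinatorics and inheritance models.

Everything downstream (two-point estimation, HMM map construction,
meiotic diagnostics, the simulator) is built on the primitives defined
here: gamete enumeration, the gamete transition kernel under the
bivalent polysomic model, expected dosage segregation, bivalent pairing
configurations, the Haldane map function and the random end-pairing
valency distribution.

Conventions
-----------
A parent carries ``m`` homologs labelled ``0 .. m-1`` (displayed as
letters *a..f* for one parent and *g..l* for the other).  A gamete is a
sorted ``k = m/2`` subset of those labels — the homologs transmitted to
an offspring at a locus.  An offspring genotype state is an ordered
pair (maternal gamete, paternal gamete); for a hexaploid there are
C(6,3)^2 = 400 such states.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import numpy as np

__all__ = [
    "Ploidy",
    "enumerate_gametes",
    "gamete_index",
    "gamete_transition_matrix",
    "expected_segregation",
    "enumerate_pairing_configurations",
    "consistent_configurations",
    "consistency_matrix",
    "haldane",
    "haldane_inv",
    "random_end_pairing_valencies",
    "homolog_letters",
]

SUPPORTED_PLOIDIES = (2, 4, 6, 8)

_P_LETTERS = "abcdefgh"
_Q_LETTERS = "ghijklmn"


@dataclass(frozen=True)
class Ploidy:
    """Homolog count ``m`` of one parent and gamete size ``k = m/2``."""

    m: int

    def __post_init__(self) -> None:
        if self.m not in SUPPORTED_PLOIDIES:
            raise ValueError(
                f"unsupported ploidy m={self.m}; must be one of {SUPPORTED_PLOIDIES}"
            )

    @property
    def k(self) -> int:
        return self.m // 2

    @property
    def n_gametes(self) -> int:
        return math.comb(self.m, self.k)

    @property
    def n_states(self) -> int:
        """Ordered (maternal, paternal) gamete pairs."""
        return self.n_gametes ** 2


def _as_m(ploidy: "Ploidy | int") -> int:
    m = ploidy.m if isinstance(ploidy, Ploidy) else int(ploidy)
    if m not in SUPPORTED_PLOIDIES:
        raise ValueError(f"unsupported ploidy m={m}; must be one of {SUPPORTED_PLOIDIES}")
    return m


def homolog_letters(ploidy: "Ploidy | int", parent: str = "P") -> list[str]:
    """Display labels for a parent's homologs (P: a.., Q: g..)."""
    m = _as_m(ploidy)
    src = _P_LETTERS if parent.upper() == "P" else _Q_LETTERS
    return list(src[:m])


@lru_cache(maxsize=None)
def enumerate_gametes(ploidy: "Ploidy | int") -> tuple[tuple[int, ...], ...]:
    """All k-subsets of ``{0..m-1}`` in lexicographic order.

    The ordering is the stable enumeration used everywhere in the
    package (state indexing, serialization).
    """
    m = _as_m(ploidy)
    k = m // 2
    return tuple(itertools.combinations(range(m), k))


@lru_cache(maxsize=None)
def _gamete_lookup(m: int) -> dict[tuple[int, ...], int]:
    return {g: i for i, g in enumerate(enumerate_gametes(m))}


def gamete_index(gamete, ploidy: "Ploidy | int") -> int:
    """Index of a gamete in the stable enumeration."""
    m = _as_m(ploidy)
    return _gamete_lookup(m)[tuple(sorted(gamete))]


@lru_cache(maxsize=None)
def _exchange_counts(m: int) -> np.ndarray:
    """Matrix l[a, b] = |set(a) - set(b)| over the gamete enumeration."""
    gams = enumerate_gametes(m)
    sets = [frozenset(g) for g in gams]
    n = len(gams)
    l = np.empty((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(n):
            l[i, j] = len(sets[i] - sets[j])
    return l


def gamete_transition_matrix(ploidy: "Ploidy | int", r: float) -> np.ndarray:
    """Gamete-to-gamete transition kernel between two adjacent loci.

    Under the bivalent polysomic model the probability that gamete ``a``
    at one locus becomes gamete ``b`` at the next depends only on
    ``l = |a \\ b|``, the number of homologs exchanged:

        T(a, b) = r^l (1 - r)^(k - l) / C(m - k, l)

    where ``r`` is the recombination fraction of the interval.  The
    kernel is symmetric, doubly stochastic and reduces to the identity
    at r = 0; row sums are exactly 1 because there are
    C(k, l) * C(m - k, l) gametes at exchange distance l.
    """
    m = _as_m(ploidy)
    k = m // 2
    if not (0.0 <= r <= 0.5):
        raise ValueError(f"recombination fraction r={r} outside [0, 0.5]")
    l = _exchange_counts(m)
    lv = np.arange(k + 1, dtype=float)
    w = r ** lv * (1.0 - r) ** (k - lv)
    w /= np.array([math.comb(m - k, int(x)) for x in range(k + 1)], dtype=float)
    return w[l]


def expected_segregation(dP: int, dQ: int, ploidy: "Ploidy | int") -> np.ndarray:
    """Expected offspring dosage distribution under random bivalent pairing.

    A parent with dosage ``d`` transmits ``a`` copies of the alternative
    allele with hypergeometric probability
    ``H(a; d) = C(d, a) C(m - d, k - a) / C(m, k)``; the offspring dosage
    distribution is the convolution of the two parental gamete-dosage
    distributions.  For a triplex x triplex hexaploid cross this yields
    the 1:18:99:164:99:18:1 ratio.
    """
    m = _as_m(ploidy)
    k = m // 2
    for d in (dP, dQ):
        if not (0 <= d <= m):
            raise ValueError(f"parental dosage {d} outside 0..{m}")

    def gamete_dosage(d: int) -> np.ndarray:
        p = np.zeros(k + 1)
        for a in range(k + 1):
            p[a] = math.comb(d, a) * math.comb(m - d, k - a)
        return p / math.comb(m, k)

    return np.convolve(gamete_dosage(dP), gamete_dosage(dQ))


@lru_cache(maxsize=None)
def enumerate_pairing_configurations(
    ploidy: "Ploidy | int",
) -> tuple[frozenset[frozenset[int]], ...]:
    """All perfect matchings of the m homologs into k bivalents.

    There are m! / (k! 2^k) such pairing configurations — 15 for a
    hexaploid.  Order is deterministic (recursive pairing of the lowest
    unpaired homolog).
    """
    m = _as_m(ploidy)

    def matchings(labels: tuple[int, ...]):
        if not labels:
            yield ()
            return
        first, rest = labels[0], labels[1:]
        for i, partner in enumerate(rest):
            pair = frozenset((first, partner))
            remaining = rest[:i] + rest[i + 1 :]
            for sub in matchings(remaining):
                yield (pair,) + sub

    return tuple(frozenset(mt) for mt in matchings(tuple(range(m))))


def consistent_configurations(
    gamete, ploidy: "Ploidy | int"
) -> tuple[frozenset[frozenset[int]], ...]:
    """Pairing configurations a gamete can originate from.

    A gamete is consistent with a configuration when every bivalent
    contributes exactly one of its two homologs to the gamete.  Exactly
    k! of the configurations qualify for any gamete, so each carries
    posterior weight 1/k! given the gamete.
    """
    m = _as_m(ploidy)
    gset = set(gamete)
    out = []
    for cfg in enumerate_pairing_configurations(m):
        if all(len(pair & gset) == 1 for pair in cfg):
            out.append(cfg)
    return tuple(out)


@lru_cache(maxsize=None)
def consistency_matrix(ploidy: "Ploidy | int") -> np.ndarray:
    """Boolean matrix [n_configs x n_gametes]: configuration consistent with gamete."""
    m = _as_m(ploidy)
    cfgs = enumerate_pairing_configurations(m)
    gams = enumerate_gametes(m)
    out = np.zeros((len(cfgs), len(gams)), dtype=bool)
    for i, cfg in enumerate(cfgs):
        for j, g in enumerate(gams):
            gset = set(g)
            out[i, j] = all(len(pair & gset) == 1 for pair in cfg)
    return out


def haldane(r):
    """Haldane map function: recombination fraction -> distance in cM.

    d = -50 ln(1 - 2r); r >= 0.5 maps to infinity (unlinked).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("recombination fraction must be >= 0")
    with np.errstate(divide="ignore"):
        d = np.where(r < 0.5, -50.0 * np.log(1.0 - 2.0 * np.minimum(r, 0.5)), np.inf)
    return float(d) if d.ndim == 0 else d


def haldane_inv(d_cM):
    """Inverse Haldane map function: distance in cM -> recombination fraction."""
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0")
    r = 0.5 * (1.0 - np.exp(-d / 50.0))
    return float(r) if r.ndim == 0 else r


_ROMAN = {2: "II", 4: "IV", 6: "VI", 8: "VIII"}


def random_end_pairing_valencies(ploidy: "Ploidy | int") -> dict[str, float]:
    """Valency-class distribution under random end pairing.

    Each chromosome end independently forms a random perfect matching of
    the m homologs; the union multigraph of the two matchings decomposes
    into cycles, a cycle through 2c homologs corresponding to a
    2c-valent.  For m = 6 the class frequencies are proportional to
    1 (three bivalents) : 6 (quadrivalent + bivalent) : 8 (hexavalent).
    """
    m = _as_m(ploidy)
    cfgs = enumerate_pairing_configurations(m)
    counts: dict[str, int] = {}
    for left in cfgs:
        for right in cfgs:
            g = nx.MultiGraph()
            g.add_nodes_from(range(m))
            for pair in left:
                a, b = sorted(pair)
                g.add_edge(a, b)
            for pair in right:
                a, b = sorted(pair)
                g.add_edge(a, b)
            sizes = sorted(
                (len(c) for c in nx.connected_components(g)), reverse=True
            )
            label = "+".join(_ROMAN[s] for s in sizes)
            counts[label] = counts.get(label, 0) + 1
    total = sum(counts.values())
    return {k: v / total for k, v in sorted(counts.items(), key=lambda kv: -kv[1])}
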