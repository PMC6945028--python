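"""Crossover detection, valency classification and preferential pairing.

From the probabilistic homolog inheritance profiles this module calls
crossovers with a five-step heuristic (binarize at 0.8, drop segments
shorter than 10 cM, require 20% marker retention with one
re-estimation pass, read exchanges off probability transitions, mark
exchanges closer than 0.5 cM inconclusive), links the homologs
involved in each individual's crossovers into recombination chains
whose maximum size signals the minimum meiotic valency, and profiles
preferential pairing: the posterior over the 15 bivalent pairing
configurations (and the 15 homolog pairs) at every position, with a
chi-square test against the random-pairing expectation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import chi2

from polymap.core import (
    consistency_matrix,
    enumerate_pairing_configurations,
    homolog_letters,
)
from polymap.haplotypes import (
    GenotypePosterior,
    HaplotypeProfile,
    genotype_posteriors,
    homolog_probabilities,
)
from polymap.hmm import EmissionModel, PhasedMap

__all__ = [
    "detect_crossovers",
    "build_chains",
    "valency_summary",
    "PairingPosterior",
    "pairing_posterior",
    "preferential_pairing_test",
    "simplex_repulsion_screen",
]


def _run_removal_mask(
    B: np.ndarray, positions: np.ndarray, min_segment_cM: float
) -> np.ndarray:
    """Markers sitting in any homolog's short constant run (step 2)."""
    z, m = B.shape
    removed = np.zeros(z, dtype=bool)
    for h in range(m):
        col = B[:, h]
        start = 0
        for t in range(1, z + 1):
            if t == z or col[t] != col[start]:
                span = positions[t - 1] - positions[start]
                if span < min_segment_cM:
                    removed[start:t] = True
                start = t
    return removed


def _segment_support(
    col: np.ndarray,
    positions: np.ndarray,
    ret_idx: np.ndarray,
    t: int,
    min_segment_cM: float,
) -> bool:
    """True when the run of ``col`` (over retained markers) containing
    position index ``t`` spans at least ``min_segment_cM`` or reaches a
    chromosome end."""
    where = np.where(ret_idx == t)[0]
    if len(where) == 0:
        return False
    j = int(where[0])
    v = col[t]
    lo = j
    while lo > 0 and col[ret_idx[lo - 1]] == v:
        lo -= 1
    hi = j
    while hi < len(ret_idx) - 1 and col[ret_idx[hi + 1]] == v:
        hi += 1
    span = positions[ret_idx[hi]] - positions[ret_idx[lo]]
    touches_end = lo == 0 or hi == len(ret_idx) - 1
    return span >= min_segment_cM or touches_end


def _locally_distinguishable(
    phase: np.ndarray,
    positions: np.ndarray,
    h: int,
    others,
    x: float,
    direction: int,
    window_cM: float,
) -> bool:
    """True when homolog ``h``'s parental allele content differs from every
    homolog in ``others`` over a window on one side of position ``x``."""
    if direction > 0:
        sel = (positions >= x) & (positions <= x + window_cM)
    else:
        sel = (positions <= x) & (positions >= x - window_cM)
    if not sel.any():
        return False
    block = phase[sel]
    return all((block[:, h] != block[:, h2]).any() for h2 in others)


def _transitions(
    B: np.ndarray,
    positions: np.ndarray,
    retained: np.ndarray,
    k: int,
    min_segment_cM: float,
    phase: np.ndarray,
):
    """Exchange events between consecutive fully-called retained markers.

    The homolog sets are read at markers where exactly k homologs are
    confidently present.  An exchange is conclusive only when (a) it is
    a single swap, (b) both homologs involved show long (>= min
    segment) support on their respective sides of the breakpoint, and
    (c) the parental phase makes the attribution identifiable: the
    incoming homolog differs in allele content from every other absent
    homolog over the downstream window, and the outgoing one from
    every other present homolog upstream — otherwise the exchanged
    partners could be swapped at no cost in likelihood.  The call
    position interpolates the last/first confident observation of the
    outgoing/incoming homolog.
    """
    z = len(positions)
    ret_idx = np.array([t for t in range(z) if retained[t]], dtype=int)
    idx = [t for t in ret_idx if B[t].sum() == k]
    calls = []
    for a, b in zip(idx[:-1], idx[1:]):
        Sa = set(np.where(B[a])[0])
        Sb = set(np.where(B[b])[0])
        out = sorted(Sa - Sb)
        inn = sorted(Sb - Sa)
        if not out:
            continue
        unambiguous = len(out) == 1 and len(inn) == 1
        for h_out, h_in in zip(out, inn):
            between = ret_idx[(ret_idx >= a) & (ret_idx < b)]
            x1 = positions[a]
            for t in between:
                if B[t, h_out]:
                    x1 = positions[t]
            x2 = positions[b]
            for t in between[::-1]:
                if t > a and B[t, h_in]:
                    x2 = positions[t]
            supported = (
                _segment_support(B[:, h_out], positions, ret_idx, a, min_segment_cM)
                and _segment_support(B[:, h_out], positions, ret_idx, b, min_segment_cM)
                and _segment_support(B[:, h_in], positions, ret_idx, a, min_segment_cM)
                and _segment_support(B[:, h_in], positions, ret_idx, b, min_segment_cM)
            )
            absent_after = [
                h for h in range(phase.shape[1]) if h not in Sb and h != h_in
            ]
            present_before = [h for h in Sa if h != h_out]
            identifiable = _locally_distinguishable(
                phase, positions, h_in, absent_after, positions[b], +1, min_segment_cM
            ) and _locally_distinguishable(
                phase, positions, h_out, present_before, positions[a], -1, min_segment_cM
            )
            calls.append(
                {
                    "position_cM": float(0.5 * (x1 + x2)),
                    "homolog_out": int(h_out),
                    "homolog_in": int(h_in),
                    "conclusive": bool(unambiguous and supported and identifiable),
                }
            )
    return calls


def detect_crossovers(
    profile: HaplotypeProfile,
    pm: PhasedMap,
    data,
    emission: EmissionModel,
    prob_threshold: float = 0.8,
    min_segment_cM: float = 10.0,
    min_retained: float = 0.2,
    min_spacing_cM: float = 0.5,
    reestimate: bool = True,
):
    """Call crossovers from homolog inheritance profiles.

    Returns ``(calls, conclusive)``: a DataFrame of per-individual
    crossover calls (parent, position, homolog pair, conclusive flag)
    and an (n, 2) boolean array saying whether each individual's
    profile was conclusive for parents P and Q.
    """
    if profile.prob_P.size == 0:
        raise ValueError("empty haplotype profile")
    z, n, m = profile.prob_P.shape
    k = m // 2
    positions = profile.positions_cM

    probs = {"P": profile.prob_P, "Q": profile.prob_Q}
    removed = np.zeros((z, n), dtype=bool)
    conclusive = np.ones((n, 2), dtype=bool)
    for pi, parent in enumerate("PQ"):
        for i in range(n):
            B = probs[parent][:, i, :] > prob_threshold
            removed[:, i] |= _run_removal_mask(B, positions, min_segment_cM)
    retained_frac = 1.0 - removed.mean(axis=0)
    conclusive &= (retained_frac >= min_retained)[:, None]

    if reestimate and removed.any():
        # one re-estimation pass: mask cleaned markers and re-run the HMM
        masked = _masked_data(data, pm, removed)
        post2 = genotype_posteriors(pm, masked, emission)
        profile = homolog_probabilities(post2, pm)
        probs = {"P": profile.prob_P, "Q": profile.prob_Q}
        # the re-estimated profile gets the same short-segment cleaning
        # before transitions are read off it
        removed = np.zeros((z, n), dtype=bool)
        for parent in "PQ":
            for i in range(n):
                B = probs[parent][:, i, :] > prob_threshold
                removed[:, i] |= _run_removal_mask(B, positions, min_segment_cM)

    rows = []
    for pi, parent in enumerate("PQ"):
        letters = homolog_letters(m, parent)
        for i in range(n):
            if not conclusive[i, pi] or not profile.valid[i]:
                conclusive[i, pi] = False
                continue
            B = probs[parent][:, i, :] > prob_threshold
            keep = ~removed[:, i]
            phase = pm.phase_P if parent == "P" else pm.phase_Q
            calls = _transitions(B, positions, keep, k, min_segment_cM, phase)
            calls.sort(key=lambda c: c["position_cM"])
            for a, b in zip(calls[:-1], calls[1:]):
                gap = b["position_cM"] - a["position_cM"]
                if gap < min_spacing_cM:
                    a["conclusive"] = False
                    b["conclusive"] = False
                elif gap < min_segment_cM:
                    # a second exchange signal within the minimum-segment
                    # span contaminates the partner attribution of both
                    a["conclusive"] = False
                    b["conclusive"] = False
            for c in calls:
                rows.append(
                    {
                        "individual": i,
                        "parent": parent,
                        "position_cM": c["position_cM"],
                        "homolog_out": letters[c["homolog_out"]],
                        "homolog_in": letters[c["homolog_in"]],
                        "conclusive": c["conclusive"],
                    }
                )
    calls_df = pd.DataFrame(
        rows,
        columns=[
            "individual", "parent", "position_cM",
            "homolog_out", "homolog_in", "conclusive",
        ],
    )
    return calls_df, conclusive


def _masked_data(data, pm: PhasedMap, removed: np.ndarray):
    """Copy of the observations with cleaned (marker, individual) cells masked."""
    import copy

    masked = copy.copy(data)
    dosage = data.dosage.copy()
    post = None if data.posterior is None else data.posterior.copy()
    for t_map, t_data in enumerate(pm.markers):
        cells = removed[t_map]
        dosage[t_data, cells] = np.nan
        if post is not None:
            post[t_data, cells] = 1.0 / (data.m + 1)
    masked.dosage = dosage
    masked.posterior = post
    return masked


def build_chains(calls: pd.DataFrame, m: int) -> pd.DataFrame:
    """Recombination chains per (individual, parent) from conclusive calls.

    The chain graph links the homologs exchanged by each crossover; the
    largest connected component gives the minimum valency signature
    (1 = no recombination observed, 2 = bivalent, >= 3 = multivalent).
    """
    cols = ["individual", "parent", "max_chain"]
    if calls.empty:
        return pd.DataFrame(columns=cols)
    rows = []
    conclusive = calls[calls["conclusive"].astype(bool)]
    for (ind, parent), grp in conclusive.groupby(["individual", "parent"]):
        g = nx.Graph()
        letters = homolog_letters(m, parent)
        g.add_nodes_from(letters)
        for _, row in grp.iterrows():
            g.add_edge(row["homolog_out"], row["homolog_in"])
        comp_sizes = [
            len(c) for c in nx.connected_components(g) if len(c) > 1
        ]
        rows.append(
            {
                "individual": ind,
                "parent": parent,
                "max_chain": max(comp_sizes) if comp_sizes else 1,
            }
        )
    return pd.DataFrame(rows, columns=["individual", "parent", "max_chain"])


def valency_summary(
    chains: pd.DataFrame, conclusive: np.ndarray
) -> pd.DataFrame:
    """Percentage of meioses per chain-size class, per parent.

    Only conclusive meioses enter the denominator; percentages sum to
    100 within each parent.
    """
    n, _ = conclusive.shape
    rows = []
    for pi, parent in enumerate("PQ"):
        ok_inds = set(np.where(conclusive[:, pi])[0])
        sub = chains[(chains["parent"] == parent) & chains["individual"].isin(ok_inds)]
        seen = dict(sub.set_index("individual")["max_chain"])
        sizes = [seen.get(i, 1) for i in ok_inds]
        total = len(sizes)
        if total == 0:
            continue
        for cls in sorted(set(sizes)):
            rows.append(
                {
                    "parent": parent,
                    "chain_size": cls,
                    "percent": 100.0 * sizes.count(cls) / total,
                    "n_conclusive": total,
                }
            )
    return pd.DataFrame(rows, columns=["parent", "chain_size", "percent", "n_conclusive"])


@dataclass
class PairingPosterior:
    """Per-position pairing-configuration and homolog-pair posteriors."""

    config_profile: np.ndarray  # (z, n_configs), rows sum to 1
    pair_profile: np.ndarray  # (z, n_pairs)
    pair_labels: list[tuple[str, str]]
    config_chi2: np.ndarray  # (z,)
    config_p: np.ndarray
    pair_chi2: np.ndarray  # (z, n_pairs)
    pair_p: np.ndarray
    positions_cM: np.ndarray
    n: int


def pairing_posterior(
    posterior: GenotypePosterior, pm: PhasedMap, parent: str = "P"
) -> PairingPosterior:
    """Posterior pairing-configuration profile for one parent.

    At every position the population average of
    sum_j Pr(config | gamete_j) Pr(state_j | data) is taken, with
    Pr(config | gamete) = 1/k! over the k! configurations a gamete is
    consistent with; the homolog-pair profile sums the configurations
    containing each pair.  A uniform genotype posterior yields the
    uniform 1/15 configuration vector and 0.2 per pair (m = 6).
    """
    m = pm.m
    k = m // 2
    cfgs = enumerate_pairing_configurations(m)
    C = consistency_matrix(m).astype(float)  # (n_cfg, G)
    marg = posterior.post.sum(axis=3 if parent.upper() == "P" else 2)  # (z, n, G)
    marg = marg[:, posterior.valid, :]
    n = marg.shape[1]
    if n < 1:
        raise ValueError("no valid individuals")
    per_ind = marg @ C.T / math.factorial(k)  # (z, n, n_cfg)
    config_profile = per_ind.mean(axis=1)

    letters = homolog_letters(m, parent)
    pairs = list(itertools.combinations(range(m), 2))
    I = np.zeros((len(pairs), len(cfgs)))
    for pi, (a, b) in enumerate(pairs):
        key = frozenset((a, b))
        for ci, cfg in enumerate(cfgs):
            I[pi, ci] = 1.0 if key in cfg else 0.0
    pair_profile = config_profile @ I.T

    stats, ps, pstats, pps = preferential_pairing_test(
        config_profile, pair_profile, n, m
    )
    return PairingPosterior(
        config_profile=config_profile,
        pair_profile=pair_profile,
        pair_labels=[(letters[a], letters[b]) for a, b in pairs],
        config_chi2=stats,
        config_p=ps,
        pair_chi2=pstats,
        pair_p=pps,
        positions_cM=pm.positions_cM,
        n=n,
    )


def preferential_pairing_test(
    config_profile: np.ndarray,
    pair_profile: np.ndarray,
    n: int,
    m: int,
):
    """Chi-square tests of the pairing profiles against random pairing.

    Posterior-weighted soft counts (n times the profile) are compared
    with the uniform expectation: n/15 per configuration (df = 14) and
    n/(m-1) per homolog pair (df = 1).  Significance is declared at
    P < 1e-4 downstream.
    """
    if n < 2:
        raise ValueError("need at least two individuals for the pairing test")
    n_cfg = config_profile.shape[1]
    exp_cfg = n / n_cfg
    obs = n * config_profile
    stats = ((obs - exp_cfg) ** 2 / exp_cfg).sum(axis=1)
    ps = chi2.sf(stats, df=n_cfg - 1)

    p0 = 1.0 / (m - 1)  # random-pairing probability of a specific pair
    obs1 = n * pair_profile
    obs0 = n - obs1
    pstats = (obs1 - n * p0) ** 2 / (n * p0) + (obs0 - n * (1 - p0)) ** 2 / (
        n * (1 - p0)
    )
    pps = chi2.sf(pstats, df=1)
    return stats, ps, pstats, pps


def simplex_repulsion_screen(data, pm: PhasedMap, parent: str = "P") -> pd.DataFrame:
    """Single-dose-marker corroboration of preferential pairing (experimental).

    For pairs of simplex markers of one parent phased to distinct
    homologs (repulsion), the fraction of offspring carrying both
    alternative alleles is compared with the random-pairing expectation
    k(k-1)/(m(m-1)); a deficit indicates the two homologs tend to
    co-pair and separate at meiosis I.
    """
    m = pm.m
    k = m // 2
    phase = pm.phase_P if parent.upper() == "P" else pm.phase_Q
    dthis = data.dP if parent.upper() == "P" else data.dQ
    dother = data.dQ if parent.upper() == "P" else data.dP
    letters = homolog_letters(m, parent)
    simplex = [
        t
        for t in range(pm.n_markers)
        if dthis[pm.markers[t]] == 1 and dother[pm.markers[t]] == 0
    ]
    expected = k * (k - 1) / (m * (m - 1))
    rows = []
    for a, b in itertools.combinations(simplex, 2):
        ha = int(np.argmax(phase[a]))
        hb = int(np.argmax(phase[b]))
        if ha == hb:
            continue
        da = data.dosage[pm.markers[a]]
        db = data.dosage[pm.markers[b]]
        ok = ~(np.isnan(da) | np.isnan(db))
        if ok.sum() < 2:
            continue
        both = float(((da[ok] > 0) & (db[ok] > 0)).mean())
        rows.append(
            {
                "marker_a": int(pm.markers[a]),
                "marker_b": int(pm.markers[b]),
                "homolog_a": letters[ha],
                "homolog_b": letters[hb],
                "distance_cM": float(
                    abs(pm.positions_cM[b] - pm.positions_cM[a])
                ),
                "frac_both": both,
                "expected_random": expected,
                "n": int(ok.sum()),
            }
        )
    return pd.DataFrame(rows)
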