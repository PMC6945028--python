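"""Meiosis and full-sib population simulator.

Generates phased polyploid parents, simulates meioses under bivalent or
(optionally) multivalent pairing with Haldane (no-interference)
crossovers, and produces noisy dosage observations with caller-style
posterior vectors.  The simulator is the ground-truth substrate for the
mapping, haplotyping and diagnostics machinery: every meiosis records
the pairing structure, the crossover positions and the per-marker
source homolog of each transmitted chromatid.

The default parental dosage spectrum mirrors a typical high-density
polyploid SNP panel: roughly half simplex markers, a tenth
double-simplex and the rest multiplex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from polymap.core import (
    Ploidy,
    enumerate_pairing_configurations,
    _as_m,
)

__all__ = [
    "PhasedParent",
    "MeiosisRecord",
    "PopulationTruth",
    "ObservedData",
    "DEFAULT_DOSAGE_SPECTRUM",
    "simulate_parents",
    "simulate_meiosis",
    "simulate_population",
    "observe_dosages",
]

# simplex : double-simplex : multiplex mix of a dense polyploid panel
DEFAULT_DOSAGE_SPECTRUM = {"simplex": 0.494, "double_simplex": 0.113, "multiplex": 0.393}


@dataclass
class PhasedParent:
    """Phased parental haplotypes over one linkage group.

    ``allele_matrix[t, h]`` is 1 when homolog ``h`` carries the
    alternative allele at marker ``t``.
    """

    allele_matrix: np.ndarray  # (z, m) int8
    positions_cM: np.ndarray  # (z,) strictly increasing
    positions_bp: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.positions_cM) <= 0):
            raise ValueError("marker positions must be strictly increasing")

    @property
    def n_markers(self) -> int:
        return self.allele_matrix.shape[0]

    @property
    def m(self) -> int:
        return self.allele_matrix.shape[1]

    @property
    def dosages(self) -> np.ndarray:
        return self.allele_matrix.sum(axis=1)


@dataclass
class MeiosisRecord:
    """One gamete: pairing structure, crossovers and source homologs.

    ``sources[c, t]`` is the parental homolog transmitted by chromatid
    ``c`` at marker ``t``; exactly ``k`` chromatids per gamete.
    """

    pairing: list[tuple[int, int]]
    crossovers: list[tuple[float, tuple[int, int]]]
    sources: np.ndarray  # (k, z) int
    multivalent_groups: list[tuple[int, ...]] = field(default_factory=list)


@dataclass
class PopulationTruth:
    parents: tuple[PhasedParent, PhasedParent]
    meioses_P: list[MeiosisRecord]
    meioses_Q: list[MeiosisRecord]
    dosages: np.ndarray  # (z, n) true offspring dosage

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[1]


@dataclass
class ObservedData:
    """Noisy dosage observations for a full-sib population.

    ``dosage`` holds the called dosage per marker x individual with
    ``nan`` for missing; ``posterior`` the caller-style probability
    vector over dosage classes 0..m (rows sum to 1).
    """

    dosage: np.ndarray  # (z, n) float, nan = missing
    posterior: np.ndarray | None  # (z, n, m+1)
    dP: np.ndarray  # (z,) parental dosages
    dQ: np.ndarray
    positions_cM: np.ndarray
    m: int
    marker_ids: list[str] | None = None

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[1]


def _draw_marker_dosages(mode: str, m: int, rng: np.random.Generator) -> tuple[int, int]:
    if mode == "simplex":
        return (1, 0) if rng.random() < 0.5 else (0, 1)
    if mode == "double_simplex":
        return (1, 1)
    # multiplex: at least one parent with >1 copy, at least one parent
    # heterozygous so the marker is informative
    while True:
        dP = int(rng.integers(0, m + 1))
        dQ = int(rng.integers(0, m + 1))
        if max(dP, dQ) < 2:
            continue
        if not (0 < dP < m or 0 < dQ < m):
            continue
        return dP, dQ


def simulate_parents(
    ploidy: Ploidy | int,
    n_markers: int,
    map_length_cM: float,
    dosage_spectrum: dict[str, float] | None = None,
    seed: int | np.random.Generator = 0,
    spacing: str = "even",
) -> tuple[PhasedParent, PhasedParent]:
    """Draw two phased parents over one linkage group.

    Marker dosage classes (simplex / double-simplex / multiplex) are
    drawn from ``dosage_spectrum`` and the alternative alleles placed on
    uniformly chosen homolog subsets.
    """
    m = _as_m(ploidy)
    if n_markers < 2:
        raise ValueError("need at least 2 markers")
    if map_length_cM <= 0:
        raise ValueError("map length must be positive")
    spectrum = dict(
        DEFAULT_DOSAGE_SPECTRUM if dosage_spectrum is None else dosage_spectrum
    )
    if not spectrum or sum(spectrum.values()) <= 0:
        raise ValueError("empty dosage spectrum")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    modes = list(spectrum)
    probs = np.array([spectrum[x] for x in modes], dtype=float)
    probs /= probs.sum()

    if spacing == "even":
        pos = np.linspace(0.0, map_length_cM, n_markers)
    elif spacing == "uniform":
        pos = np.sort(rng.uniform(0.0, map_length_cM, n_markers))
        while np.any(np.diff(pos) <= 0):
            pos = np.sort(rng.uniform(0.0, map_length_cM, n_markers))
    else:
        raise ValueError(f"unknown spacing {spacing!r}")

    AP = np.zeros((n_markers, m), dtype=np.int8)
    AQ = np.zeros((n_markers, m), dtype=np.int8)
    for t in range(n_markers):
        mode = modes[rng.choice(len(modes), p=probs)]
        dP, dQ = _draw_marker_dosages(mode, m, rng)
        AP[t, rng.choice(m, size=dP, replace=False)] = 1
        AQ[t, rng.choice(m, size=dQ, replace=False)] = 1
    return (
        PhasedParent(AP, pos.copy()),
        PhasedParent(AQ, pos.copy()),
    )


def _random_matching(labels: list[int], rng: np.random.Generator) -> list[tuple[int, int]]:
    labels = list(labels)
    rng.shuffle(labels)
    return [tuple(sorted((labels[i], labels[i + 1]))) for i in range(0, len(labels), 2)]


def _draw_pairing(
    m: int, pairing_mode, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Sample a pairing configuration according to the pairing mode."""
    if pairing_mode is None or pairing_mode == "random_bivalent":
        return _random_matching(list(range(m)), rng)
    if isinstance(pairing_mode, dict) and pairing_mode.get("mode") == "preferential":
        pi = float(pairing_mode["pi"])
        h1, h2 = pairing_mode["pair"]
        if not (0.0 <= pi <= 1.0):
            raise ValueError(f"preferential pairing probability pi={pi} outside [0, 1]")
        if rng.random() < pi:
            rest = [h for h in range(m) if h not in (h1, h2)]
            return [tuple(sorted((h1, h2)))] + _random_matching(rest, rng)
        while True:
            cfg = _random_matching(list(range(m)), rng)
            if tuple(sorted((h1, h2))) not in cfg:
                return cfg
    raise ValueError(f"invalid pairing mode {pairing_mode!r}")


def _walk_bivalent(
    pair: tuple[int, int],
    length: float,
    positions: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[float, tuple[int, int]]]]:
    """One recombinant chromatid from a bivalent: Poisson crossovers."""
    n_co = rng.poisson(length / 100.0)
    xpos = np.sort(rng.uniform(0.0, length, n_co))
    cur = pair[rng.integers(2)]
    sources = np.empty(len(positions), dtype=np.int64)
    crossovers = []
    i = 0
    for t, p in enumerate(positions):
        while i < len(xpos) and xpos[i] <= p:
            other = pair[0] if cur == pair[1] else pair[1]
            crossovers.append((float(xpos[i]), (cur, other)))
            cur = other
            i += 1
        sources[t] = cur
    # crossovers beyond the last marker never affect transmission; drop them
    return sources, crossovers


def _walk_quadrivalent(
    pairA: tuple[int, int],
    pairB: tuple[int, int],
    length: float,
    positions: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[tuple[float, tuple[int, int]]]]:
    """Two chromatids from a quadrivalent with one partner-exchange point.

    Before the exchange point the four homologs pair as the two original
    bivalents; after it partners are exchanged crosswise.  Crossover
    events occur at the bivalent rate per pairing unit and switch the
    walk to its active partner.  Walks are resampled in the rare case
    the two transmitted chromatids would collide on the same source
    homolog at a marker (double reduction is modelled separately).
    """
    for _ in range(200):
        x = rng.uniform(0.0, length)
        if rng.random() < 0.5:
            after = {pairA[0]: pairB[0], pairB[0]: pairA[0], pairA[1]: pairB[1], pairB[1]: pairA[1]}
        else:
            after = {pairA[0]: pairB[1], pairB[1]: pairA[0], pairA[1]: pairB[0], pairB[0]: pairA[1]}
        before = {pairA[0]: pairA[1], pairA[1]: pairA[0], pairB[0]: pairB[1], pairB[1]: pairB[0]}
        n_co = rng.poisson(2.0 * length / 100.0)
        events = np.sort(rng.uniform(0.0, length, n_co))
        which = rng.integers(0, 2, n_co)

        curs = [pairA[rng.integers(2)], pairB[rng.integers(2)]]
        srcs = [np.empty(len(positions), dtype=np.int64) for _ in range(2)]
        crossovers: list[tuple[float, tuple[int, int]]] = []
        i = 0
        ok = True
        for t, p in enumerate(positions):
            while i < len(events) and events[i] <= p:
                w = which[i]
                partner_map = before if events[i] < x else after
                nxt = partner_map[curs[w]]
                if nxt == curs[1 - w]:
                    ok = False
                    break
                crossovers.append((float(events[i]), (curs[w], nxt)))
                curs[w] = nxt
                i += 1
            if not ok:
                break
            srcs[0][t] = curs[0]
            srcs[1][t] = curs[1]
            if curs[0] == curs[1]:
                ok = False
                break
        if ok:
            return srcs[0], srcs[1], crossovers
    raise RuntimeError("quadrivalent walk failed to produce a balanced gamete")


def simulate_meiosis(
    parent: PhasedParent,
    pairing_mode=None,
    p_multi: float = 0.0,
    p_dr: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> MeiosisRecord:
    """Simulate one meiosis of ``parent`` and return the gamete record.

    ``pairing_mode`` is ``"random_bivalent"`` (default) or
    ``{"mode": "preferential", "pair": (h, h'), "pi": p}``; with
    probability ``p_multi`` two bivalents are fused into a quadrivalent
    permitting partner exchange; with probability ``p_dr`` a double
    reduction overwrite is applied (off by default).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = parent.m
    k = m // 2
    positions = parent.positions_cM
    length = float(positions[-1] - positions[0])
    rel = positions - positions[0]

    pairing = _draw_pairing(m, pairing_mode, rng)
    sources = np.empty((k, len(positions)), dtype=np.int64)
    crossovers: list[tuple[float, tuple[int, int]]] = []
    multivalent_groups: list[tuple[int, ...]] = []

    pair_idx = list(range(k))
    fused: tuple[int, int] | None = None
    if p_multi > 0 and k >= 2 and rng.random() < p_multi:
        a, b = rng.choice(k, size=2, replace=False)
        fused = (int(a), int(b))

    slot = 0
    for i in pair_idx:
        if fused is not None and i == fused[0]:
            sA, sB, cos = _walk_quadrivalent(
                pairing[fused[0]], pairing[fused[1]], max(length, 1e-9), rel, rng
            )
            sources[slot] = sA
            sources[slot + 1] = sB
            slot += 2
            crossovers.extend(cos)
            multivalent_groups.append(tuple(sorted(pairing[fused[0]] + pairing[fused[1]])))
        elif fused is not None and i == fused[1]:
            continue
        else:
            s, cos = _walk_bivalent(pairing[i], max(length, 1e-9), rel, rng)
            sources[slot] = s
            slot += 1
            crossovers.extend(cos)

    if p_dr > 0 and rng.random() < p_dr and k >= 2:
        # double reduction stressor: duplicate the tail of one chromatid
        # onto another from a random breakpoint onward
        c1, c2 = rng.choice(k, size=2, replace=False)
        cut = rng.integers(0, len(positions))
        sources[c2, cut:] = sources[c1, cut:]

    crossovers = [(p + positions[0], hp) for p, hp in sorted(crossovers)]
    return MeiosisRecord(pairing, crossovers, sources, multivalent_groups)


def simulate_population(
    parents: tuple[PhasedParent, PhasedParent],
    n_ind: int,
    pairing_mode_P=None,
    pairing_mode_Q=None,
    p_multi: float = 0.0,
    p_dr: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> PopulationTruth:
    """Simulate a full-sib population; returns the complete truth set."""
    if n_ind < 1:
        raise ValueError("need at least one individual")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    parP, parQ = parents
    z = parP.n_markers
    meiP, meiQ = [], []
    dos = np.zeros((z, n_ind), dtype=np.int64)
    for i in range(n_ind):
        mp = simulate_meiosis(parP, pairing_mode_P, p_multi, p_dr, rng)
        mq = simulate_meiosis(parQ, pairing_mode_Q, p_multi, p_dr, rng)
        meiP.append(mp)
        meiQ.append(mq)
        t = np.arange(z)
        dos[:, i] = (
            parP.allele_matrix[t[:, None], mp.sources.T].sum(axis=1)
            + parQ.allele_matrix[t[:, None], mq.sources.T].sum(axis=1)
        )
    return PopulationTruth((parP, parQ), meiP, meiQ, dos)


def observe_dosages(
    truth: PopulationTruth,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    posterior_sharpness: float = 5.0,
    seed: int | np.random.Generator = 0,
    min_posterior: float = 0.8,
) -> ObservedData:
    """Corrupt true dosages into caller-style observations.

    With probability ``error_rate`` a call is perturbed to a neighboring
    dosage class.  Posterior vectors decay geometrically away from the
    call with rate ``exp(-posterior_sharpness)``; calls whose top
    posterior falls below ``min_posterior`` are set to missing, as are a
    further ``missing_rate`` fraction at random.
    """
    if not (0.0 <= error_rate < 1.0 and 0.0 <= missing_rate < 1.0):
        raise ValueError("error_rate and missing_rate must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    parP, parQ = truth.parents
    m = parP.m
    z, n = truth.dosages.shape

    called = truth.dosages.astype(float).copy()
    err = rng.random((z, n)) < error_rate
    step = np.where(rng.random((z, n)) < 0.5, -1, 1)
    perturbed = np.clip(truth.dosages + step, 0, m)
    # at the boundary the drawn step may be clipped back onto the truth;
    # push the other way so an error always changes the class
    same = perturbed == truth.dosages
    perturbed = np.where(same, np.clip(truth.dosages - step, 0, m), perturbed)
    called[err] = perturbed[err]

    classes = np.arange(m + 1)
    dist = np.abs(called[..., None] - classes[None, None, :])
    post = np.exp(-posterior_sharpness * dist)
    post /= post.sum(axis=2, keepdims=True)

    assay_missing = rng.random((z, n)) < missing_rate
    post[assay_missing] = 1.0 / (m + 1)  # failed assays carry no information
    missing = assay_missing | (post.max(axis=2) < min_posterior)
    dosage = called.copy()
    dosage[missing] = np.nan

    return ObservedData(
        dosage=dosage,
        posterior=post,
        dP=parP.dosages.astype(np.int64),
        dQ=parQ.dosages.astype(np.int64),
        positions_cM=parP.positions_cM.copy(),
        m=m,
        marker_ids=[f"M{t + 1}" for t in range(z)],
    )
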