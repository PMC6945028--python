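"""Multilocus map estimation by hidden Markov model.

The HMM runs over offspring genotype states — ordered pairs of one
maternal and one paternal gamete, C(m, k)^2 states in total (400 for a
hexaploid).  Transitions between adjacent markers factorize into one
gamete transition kernel per parent sharing a single interval
recombination fraction; emissions connect states to observed dosages
either through a global genotyping-error rate or through the caller's
posterior dosage distributions.  On top of the forward-backward
machinery this module provides sequential linkage-phase estimation,
EM re-estimation of interval recombination fractions, multipoint
comparison of candidate orders, the inflating-marker screen and
position-constrained marker insertion.

All likelihood computations exploit the factorized transition: the
forward state vector is held as an (n_gametes x n_gametes) matrix per
individual and propagated with two small matrix products instead of a
dense product over C(m,k)^2 states.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize_scalar

from polymap.core import (
    _as_m,
    _exchange_counts,
    enumerate_gametes,
    gamete_transition_matrix,
    haldane,
)
from polymap.twopoint import estimate_pair

__all__ = [
    "PhasedMap",
    "EmissionModel",
    "multipoint_loglik",
    "phase_markers",
    "reestimate_rfs",
    "compare_orders",
    "drop_inflating_markers",
    "insert_constrained_markers",
    "forward_backward",
]

_R_MIN, _R_MAX = 1e-6, 0.4999


@dataclass
class EmissionModel:
    """How observed dosages attach to hidden genotype states.

    ``dosage`` mode: P(obs d | state) = (1 - eps) if d equals the state
    dosage, eps / m otherwise (m wrong classes); missing observations
    emit uniformly.  ``posterior`` mode: the caller's probability
    vector over dosage classes is used directly (optionally mixed with
    a uniform floor when eps > 0).
    """

    mode: str = "dosage"
    eps: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("dosage", "posterior"):
            raise ValueError(f"unknown emission mode {self.mode!r}")
        if not (0.0 <= self.eps < 1.0):
            raise ValueError("eps must be in [0, 1)")


@dataclass
class PhasedMap:
    """Ordered, phased markers with inter-marker recombination fractions.

    ``markers`` holds the data-row index of each mapped marker;
    ``phase_P[t, h]`` is 1 when homolog ``h`` of parent P carries the
    alternative allele at the t-th mapped marker.
    """

    markers: np.ndarray  # (z,) data indices in map order
    phase_P: np.ndarray  # (z, m) int8
    phase_Q: np.ndarray  # (z, m) int8
    rf: np.ndarray  # (z-1,)
    loglik: float | None = None
    dropped: list[int] = field(default_factory=list)
    converged: bool = True

    @property
    def m(self) -> int:
        return self.phase_P.shape[1]

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def positions_cM(self) -> np.ndarray:
        return np.r_[0.0, np.cumsum(haldane(np.clip(self.rf, 0.0, 0.499999)))]

    @property
    def length_cM(self) -> float:
        return float(self.positions_cM[-1])

    def subset(self, idx) -> "PhasedMap":
        idx = np.asarray(idx)
        pos = self.positions_cM[idx]
        rf = 0.5 * (1.0 - np.exp(-np.diff(pos) / 50.0))
        return PhasedMap(
            markers=self.markers[idx],
            phase_P=self.phase_P[idx],
            phase_Q=self.phase_Q[idx],
            rf=np.clip(rf, _R_MIN, _R_MAX),
        )


# ---------------------------------------------------------------------------
# emissions


def _member_idx(m: int) -> np.ndarray:
    return np.array(enumerate_gametes(m), dtype=np.int64)


def _state_doses(phase_row_P: np.ndarray, phase_row_Q: np.ndarray) -> np.ndarray:
    m = len(phase_row_P)
    mem = _member_idx(m)
    dP = phase_row_P[mem].sum(axis=1)
    dQ = phase_row_Q[mem].sum(axis=1)
    return dP[:, None] + dQ[None, :]


def _emission_table(data, emission: EmissionModel) -> np.ndarray:
    """Per (marker, individual) emission over dosage classes 0..m."""
    m = data.m
    z, n = data.dosage.shape
    if emission.mode == "posterior":
        if data.posterior is None:
            raise ValueError("posterior emission mode requires posterior vectors")
        E = np.asarray(data.posterior, dtype=float).copy()
        if emission.eps > 0:
            E = (1.0 - emission.eps) * E + emission.eps / (m + 1)
        bad = ~np.isfinite(E).all(axis=2)
        E[bad] = 1.0
        return E
    eps = emission.eps
    E = np.full((z, n, m + 1), eps / m if eps > 0 else 0.0)
    obs = data.dosage
    seen = ~np.isnan(obs)
    t_idx, i_idx = np.where(seen)
    E[t_idx, i_idx, obs[seen].astype(np.int64)] = 1.0 - eps
    E[~seen] = 1.0
    return E


def _marker_emissions(
    pm: PhasedMap, data, emission: EmissionModel
) -> list[np.ndarray]:
    """Emission matrices (n, G, G) per mapped marker."""
    table = _emission_table(data, emission)
    out = []
    for t in range(pm.n_markers):
        dose = _state_doses(pm.phase_P[t], pm.phase_Q[t])
        out.append(table[pm.markers[t]][:, dose])
    return out


# ---------------------------------------------------------------------------
# forward-backward


def _transition(m: int, r: float) -> np.ndarray:
    return gamete_transition_matrix(m, float(np.clip(r, 0.0, 0.5)))


def forward_backward(pm: PhasedMap, data, emission: EmissionModel):
    """Scaled forward-backward pass over all individuals.

    Returns ``(alpha, beta, scale, loglik_per_ind, valid)`` where
    ``alpha``/``beta`` are lists of (n, G, G) arrays per marker and
    individuals whose observation sequence has probability zero are
    flagged invalid (and skipped from the likelihood) with a warning.
    """
    m = pm.m
    z = pm.n_markers
    n = data.n_individuals
    G = len(enumerate_gametes(m))
    E = _marker_emissions(pm, data, emission)
    Ts = [_transition(m, r) for r in pm.rf]

    alpha: list[np.ndarray] = [None] * z
    scale = np.zeros((z, n))
    valid = np.ones(n, dtype=bool)

    a = np.broadcast_to(1.0 / G ** 2, (n, G, G)) * E[0]
    c = a.sum(axis=(1, 2))
    dead = c <= 0.0
    valid &= ~dead
    c = np.where(dead, 1.0, c)
    a = np.where(dead[:, None, None], 1.0 / G ** 2, a / c[:, None, None])
    alpha[0] = a
    scale[0] = c
    for t in range(1, z):
        T = Ts[t - 1]
        pred = T.T @ alpha[t - 1] @ T
        a = pred * E[t]
        c = a.sum(axis=(1, 2))
        dead = c <= 0.0
        valid &= ~dead
        c = np.where(dead, 1.0, c)
        a = np.where(dead[:, None, None], 1.0 / G ** 2, a / c[:, None, None])
        alpha[t] = a
        scale[t] = c

    beta: list[np.ndarray] = [None] * z
    b = np.ones((n, G, G))
    beta[z - 1] = b
    for t in range(z - 2, -1, -1):
        T = Ts[t]
        nxt = beta[t + 1] * E[t + 1]
        b = T @ nxt @ T.T
        norm = np.maximum(b.sum(axis=(1, 2)), 1e-300)
        b = b / norm[:, None, None] * G ** 2
        beta[t] = b

    if not valid.all():
        warnings.warn(
            f"{(~valid).sum()} individual(s) have zero-probability "
            "observation sequences and were skipped",
            stacklevel=2,
        )
    ll = np.log(scale).sum(axis=0)
    ll[~valid] = 0.0
    return alpha, beta, scale, ll, valid


def multipoint_loglik(pm: PhasedMap, data, emission: EmissionModel) -> float:
    """Total log-likelihood of the data under the phased map (forward pass)."""
    m = pm.m
    z = pm.n_markers
    n = data.n_individuals
    G = len(enumerate_gametes(m))
    E = _marker_emissions(pm, data, emission)

    a = np.broadcast_to(1.0 / G ** 2, (n, G, G)) * E[0]
    c = a.sum(axis=(1, 2))
    valid = c > 0.0
    c = np.where(valid, c, 1.0)
    a = a / c[:, None, None]
    ll = np.log(c)
    for t in range(1, z):
        T = _transition(m, pm.rf[t - 1])
        a = (T.T @ a @ T) * E[t]
        c = a.sum(axis=(1, 2))
        dead = c <= 0.0
        valid &= ~dead
        c = np.where(dead, 1.0, c)
        a = np.where(dead[:, None, None], 1.0 / G ** 2, a / c[:, None, None])
        ll += np.log(c)
    return float(ll[valid].sum())


# ---------------------------------------------------------------------------
# EM re-estimation of recombination fractions


def reestimate_rfs(
    pm: PhasedMap,
    data,
    emission: EmissionModel,
    tol: float = 1e-4,
    max_iter: int = 50,
) -> PhasedMap:
    """Baum-Welch updates of every interval recombination fraction.

    Each EM iteration computes, per interval, the posterior expected
    number of homolog exchanges in both parental meioses and divides by
    the 2k transmission slots; the likelihood is non-decreasing across
    iterations and iteration stops when its change falls below ``tol``.
    """
    m = pm.m
    k = m // 2
    L = _exchange_counts(m).astype(float)
    rf = np.clip(pm.rf.astype(float).copy(), _R_MIN, _R_MAX)
    E = _marker_emissions(pm, data, emission)
    z = pm.n_markers
    prev_ll = -np.inf
    converged = False

    for _ in range(max_iter):
        cur = replace(pm, rf=rf)
        alpha, beta, scale, ll_i, valid = forward_backward(cur, data, emission)
        ll = float(ll_i[valid].sum())
        n_valid = int(valid.sum())
        if n_valid == 0:
            warnings.warn("no individuals usable for EM re-estimation")
            break
        new_rf = rf.copy()
        for t in range(z - 1):
            T = _transition(m, rf[t])
            TL = T * L
            Btil = beta[t + 1] * E[t + 1]
            a = alpha[t]
            # inner_P[n, aP, bP] = sum_{aQ,bQ} a[n,aP,aQ] T[aQ,bQ] Btil[n,bP,bQ]
            innP = np.einsum("nij,jl,nkl->nik", a, T, Btil, optimize=True)
            innQ = np.einsum("nij,ik,nkl->njl", a, T, Btil, optimize=True)
            Z = np.einsum("ik,nik->n", T, innP)
            Z = np.where(Z > 0, Z, 1.0)
            elP = np.einsum("ik,nik->n", TL, innP) / Z
            elQ = np.einsum("jl,njl->n", TL, innQ) / Z
            num = (elP + elQ)[valid].sum()
            new_rf[t] = np.clip(num / (2.0 * k * n_valid), _R_MIN, _R_MAX)
        rf = new_rf
        if abs(ll - prev_ll) < tol:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll

    out = replace(pm, rf=rf, loglik=prev_ll, converged=converged)
    if not converged:
        warnings.warn("EM re-estimation did not converge; returning best iterate")
    return out


# ---------------------------------------------------------------------------
# sequential phasing


def _phase_rows(m: int, d: int) -> list[np.ndarray]:
    rows = []
    for combo in itertools.combinations(range(m), d):
        row = np.zeros(m, dtype=np.int8)
        row[list(combo)] = 1
        rows.append(row)
    return rows


def _tp(cache: dict, data, i: int, j: int):
    key = (min(i, j), max(i, j))
    if key not in cache:
        cache[key] = estimate_pair(
            data.m,
            int(data.dP[key[0]]), int(data.dP[key[1]]),
            int(data.dQ[key[0]]), int(data.dQ[key[1]]),
            data.dosage[key[0]], data.dosage[key[1]],
        )
    return cache[key]


def _candidate_phases(
    data,
    cache: dict,
    new_idx: int,
    placed_idx: np.ndarray,
    phase_P: list[np.ndarray],
    phase_Q: list[np.ndarray],
    lod_threshold: float,
    cap: int,
):
    """Candidate (rowP, rowQ) assignments for a marker being inserted.

    Confident two-point results (phase LOD >= threshold) against placed
    markers act as hard constraints; the survivors are ranked by their
    summed two-point log-likelihood at the implied phase class.
    """
    m = data.m
    dP = int(data.dP[new_idx])
    dQ = int(data.dQ[new_idx])
    cands = [
        (rp, rq) for rp in _phase_rows(m, dP) for rq in _phase_rows(m, dQ)
    ]
    scores = np.zeros(len(cands))
    lod_nats = lod_threshold * np.log(10.0)
    for pi, p_idx in enumerate(placed_idx):
        tp = _tp(cache, data, p_idx, new_idx)
        if tp.degenerate or tp.all_phases is None:
            continue
        rowP, rowQ = phase_P[pi], phase_Q[pi]
        implied = [
            (int(rp @ rowP), int(rq @ rowQ)) for rp, rq in cands
        ]
        lls = np.array(
            [tp.all_phases.get(s, (np.nan, -1e9))[1] for s in implied]
        )
        # hard-eliminate candidates whose implied phase class is decisively
        # worse than this pair's best class
        keep = np.where(lls >= lls.max() - lod_nats)[0]
        if 0 < len(keep) < len(cands):
            cands = [cands[ci] for ci in keep]
            scores = scores[keep]
            lls = lls[keep]
        scores = scores + lls
    order = np.argsort(-scores, kind="stable")
    return [cands[i] for i in order[:cap]]


class _Messages:
    """Forward/backward messages of a phased map for fast what-if scoring.

    ``pred[t]`` is the forward state distribution just before the
    emission at marker t and ``bnoe[t]`` the backward message excluding
    the emission at t; both are per-individual (n, G, G) arrays with
    arbitrary per-individual normalization.  The exact full-map
    log-likelihood change of replacing marker t's emission (a phase
    swap) or of permuting all downstream states (a homolog relabeling
    of the block after an interval) is then a single contraction.
    """

    def __init__(self, pm: PhasedMap, data, emission: EmissionModel):
        m = pm.m
        z = pm.n_markers
        n = data.n_individuals
        G = len(enumerate_gametes(m))
        self.table = _emission_table(data, emission)
        self.E = [
            self.table[pm.markers[t]][:, _state_doses(pm.phase_P[t], pm.phase_Q[t])]
            for t in range(z)
        ]
        Ts = [_transition(m, r) for r in pm.rf]
        self.pred: list[np.ndarray] = [None] * z
        self.bnoe: list[np.ndarray] = [None] * z
        valid = np.ones(n, dtype=bool)
        ll = np.zeros(n)
        a = np.broadcast_to(1.0 / G ** 2, (n, G, G)).copy()
        for t in range(z):
            self.pred[t] = a
            aE = a * self.E[t]
            c = aE.sum(axis=(1, 2))
            dead = c <= 0
            valid &= ~dead
            c = np.where(dead, 1.0, c)
            a = np.where(dead[:, None, None], 1.0 / G ** 2, aE / c[:, None, None])
            ll += np.log(c)
            if t < z - 1:
                T = Ts[t]
                a = T.T @ a @ T
        b = np.ones((n, G, G))
        self.bnoe[z - 1] = b
        for t in range(z - 2, -1, -1):
            T = Ts[t]
            eb = self.E[t + 1] * self.bnoe[t + 1]
            b = T @ eb @ T.T
            norm = np.maximum(b.sum(axis=(1, 2)), 1e-300)
            b = b / norm[:, None, None] * G ** 2
            self.bnoe[t] = b
        self.valid = valid
        self.loglik = float(ll[valid].sum())
        self.pm = pm
        self.data = data
        self.m = m

    def swap_delta(self, t: int, rowP: np.ndarray, rowQ: np.ndarray) -> float:
        """Exact delta log-likelihood of re-phasing marker t to (rowP, rowQ)."""
        Ec = self.table[self.pm.markers[t]][:, _state_doses(rowP, rowQ)]
        num = (self.pred[t] * Ec * self.bnoe[t]).sum(axis=(1, 2))
        den = (self.pred[t] * self.E[t] * self.bnoe[t]).sum(axis=(1, 2))
        ok = self.valid & (den > 0) & (num > 0)
        bad = self.valid & ((num <= 0) | (den <= 0))
        if bad.any():
            return -np.inf
        return float(np.log(num[ok] / den[ok]).sum())

    def block_perm_delta(
        self, t: int, parent: str, perm, r_new: float | None = None
    ) -> float:
        """Delta log-likelihood of relabeling one parent's homologs in the
        block after interval t (markers t+1..end), optionally with a new
        boundary rf."""
        m = self.m
        gams = enumerate_gametes(m)
        lut = {g: i for i, g in enumerate(gams)}
        gperm = np.array(
            [lut[tuple(sorted(perm[h] for h in g))] for g in gams]
        )
        eb = self.E[t + 1] * self.bnoe[t + 1]
        ebp = eb[:, gperm, :] if parent == "P" else eb[:, :, gperm]
        T0 = _transition(m, self.pm.rf[t])
        Tn = T0 if r_new is None else _transition(m, r_new)
        # forward message after emission at t
        aE = self.pred[t] * self.E[t]
        num = (aE * (Tn @ ebp @ Tn.T)).sum(axis=(1, 2))
        den = (aE * (T0 @ eb @ T0.T)).sum(axis=(1, 2))
        ok = self.valid & (den > 0) & (num > 0)
        if (self.valid & ((num <= 0) | (den <= 0))).any():
            return -np.inf
        return float(np.log(num[ok] / den[ok]).sum())


def _refine_phases(
    pm: PhasedMap,
    data,
    twopoint_cache: dict,
    emission: EmissionModel,
    lod_threshold: float,
    max_passes: int = 2,
    min_gain: float = 0.5,
) -> PhasedMap:
    """Coordinate sweeps re-phasing each marker against the whole map.

    Serial insertion can commit to a wrong assignment while few markers
    are placed.  With the complete map available, every admissible
    homolog assignment of each marker is compared by the exact
    full-map multipoint likelihood at the current interval rfs (kept
    fixed so a wrong phase cannot buy back likelihood through inflated
    local recombination) using cached forward/backward messages; the
    rfs are re-fit by a short EM between sweeps.
    """
    pm = replace(pm)
    m = pm.m
    z = pm.n_markers
    for _ in range(max_passes):
        pm = reestimate_rfs(pm, data, emission, tol=1e-2, max_iter=15)
        msgs = _Messages(pm, data, emission)
        changed = 0
        for t in range(z):
            dP = int(data.dP[pm.markers[t]])
            dQ = int(data.dQ[pm.markers[t]])
            best = (min_gain, None)
            for rp in _phase_rows(m, dP):
                for rq in _phase_rows(m, dQ):
                    if np.array_equal(rp, pm.phase_P[t]) and np.array_equal(
                        rq, pm.phase_Q[t]
                    ):
                        continue
                    delta = msgs.swap_delta(t, rp, rq)
                    if delta > best[0]:
                        best = (delta, (rp, rq))
            if best[1] is not None:
                pm.phase_P[t] = best[1][0]
                pm.phase_Q[t] = best[1][1]
                changed += 1
                msgs = _Messages(pm, data, emission)
        if changed == 0:
            break
    return pm


def _heal_gauge_breaks(
    pm: PhasedMap,
    data,
    emission: EmissionModel,
    rf_threshold: float | None = None,
    max_rounds: int = 6,
    max_suspects: int = 8,
) -> PhasedMap:
    """Repair homolog-relabeling breaks that inflate interval rfs.

    Serial phasing can switch to a different (equally valid) homolog
    permutation partway along the map; the two internally consistent
    blocks then stitch through a spuriously inflated recombination
    fraction.  Relabeling a whole downstream block leaves its internal
    likelihood unchanged, so each suspect interval is tested by
    applying every within-parent homolog permutation to the downstream
    block and scoring the exact full-map likelihood change through
    cached messages (boundary rf profiled); improvements are accepted
    and the rfs re-fit.
    """
    m = pm.m
    perms = list(itertools.permutations(range(m)))
    identity = tuple(range(m))
    pm = replace(pm)
    pm = reestimate_rfs(pm, data, emission, tol=1e-2, max_iter=15)
    tried: set[tuple[int, str]] = set()
    for _ in range(max_rounds):
        # an interval is suspect when its rf stands out against the map's
        # typical interval (absolute floor guards dense clean maps)
        cut = rf_threshold
        if cut is None:
            cut = max(0.03, 2.5 * float(np.median(pm.rf)))
        sus = [
            t for t in np.argsort(-pm.rf)[:max_suspects]
            if pm.rf[t] > cut and t < pm.n_markers - 1
        ]
        sus = [t for t in sus if (t, "P") not in tried or (t, "Q") not in tried]
        if not sus:
            break
        t = int(sus[0])
        msgs = _Messages(pm, data, emission)
        improved = False
        for which in ("P", "Q"):
            tried.add((t, which))
            quick = np.array(
                [
                    msgs.block_perm_delta(t, which, p, r_new=0.05)
                    for p in perms
                ]
            )
            best = (1.0, None, None)  # require > 1 nat gain
            for pi in np.argsort(-quick)[:5]:
                p = perms[pi]
                if p == identity:
                    continue
                res = minimize_scalar(
                    lambda r: -msgs.block_perm_delta(t, which, p, r_new=r),
                    bounds=(_R_MIN, _R_MAX), method="bounded",
                    options={"xatol": 1e-3},
                )
                if -res.fun > best[0]:
                    best = (-res.fun, p, float(res.x))
            if best[1] is not None:
                phase = pm.phase_P if which == "P" else pm.phase_Q
                phase[t + 1 :] = phase[t + 1 :][:, list(best[1])]
                pm.rf[t] = best[2]
                improved = True
                msgs = _Messages(pm, data, emission)
        if improved:
            pm = reestimate_rfs(pm, data, emission, tol=1e-2, max_iter=15)
    return pm


def phase_markers(
    order,
    data,
    twopoint_cache: dict | None = None,
    emission: EmissionModel | None = None,
    lod_threshold: float = 10.0,
    candidate_cap: int = 50,
    window: int = 8,
    refine_passes: int = 2,
) -> PhasedMap:
    """Estimate parental linkage phases by serial marker insertion.

    Markers are added in map order; for each insertion the admissible
    homolog assignments are pruned with confident two-point phase
    estimates against the placed markers (phase LOD >= threshold) and
    surviving candidates are compared by multipoint likelihood over a
    trailing window.  Markers with contradictory data (no candidate
    with finite likelihood) are dropped and reported.  The first
    marker's assignment fixes the within-parent homolog gauge.
    """
    order = np.asarray(order, dtype=np.int64)
    if twopoint_cache is None:
        twopoint_cache = {}
    if emission is None:
        emission = EmissionModel("dosage", 0.01)
    m = data.m

    def first_row(d: int) -> np.ndarray:
        row = np.zeros(m, dtype=np.int8)
        row[:d] = 1
        return row

    placed: list[int] = [int(order[0])]
    phase_P = [first_row(int(data.dP[order[0]]))]
    phase_Q = [first_row(int(data.dQ[order[0]]))]
    rfs: list[float] = []
    dropped: list[int] = []

    for new_idx in order[1:]:
        new_idx = int(new_idx)
        cands = _candidate_phases(
            data, twopoint_cache, new_idx, np.array(placed),
            phase_P, phase_Q, lod_threshold, candidate_cap,
        )
        tp_adj = _tp(twopoint_cache, data, placed[-1], new_idx)
        r_init = tp_adj.rf if np.isfinite(tp_adj.rf) else 0.25
        r_init = float(np.clip(r_init, _R_MIN, _R_MAX))

        w0 = max(0, len(placed) - window)
        sub_markers = placed[w0:]
        sub_P = phase_P[w0:]
        sub_Q = phase_Q[w0:]
        sub_rf = list(rfs[w0:]) if len(rfs) >= 1 else []

        def window_ll(rp, rq, r_last):
            pm = PhasedMap(
                markers=np.array(sub_markers + [new_idx]),
                phase_P=np.array(sub_P + [rp]),
                phase_Q=np.array(sub_Q + [rq]),
                rf=np.array(sub_rf + [r_last]),
            )
            return multipoint_loglik(pm, data, emission)

        if len(cands) > 1:
            # coarse ranking at the two-point rf, then rf-profiled
            # likelihood for the leaders
            quick = [window_ll(rp, rq, r_init) for rp, rq in cands]
            top = np.argsort(-np.asarray(quick), kind="stable")[:10]
            best = None
            for ci in top:
                rp, rq = cands[ci]
                res = minimize_scalar(
                    lambda r: -window_ll(rp, rq, r),
                    bounds=(_R_MIN, _R_MAX),
                    method="bounded",
                    options={"xatol": 1e-3},
                )
                key = (-res.fun, tuple(-rp), tuple(-rq))  # lex-smallest rows win ties
                if best is None or key > best[0]:
                    best = (key, rp, rq, float(res.x))
            cands = [(best[1], best[2])]
            r_new = best[3]
        else:
            res = minimize_scalar(
                lambda r: -window_ll(cands[0][0], cands[0][1], r),
                bounds=(_R_MIN, _R_MAX),
                method="bounded",
                options={"xatol": 1e-3},
            )
            r_new = float(res.x)

        if not cands or not np.isfinite(window_ll(cands[0][0], cands[0][1], r_new)):
            dropped.append(new_idx)
            continue

        rp, rq = cands[0]
        placed.append(new_idx)
        phase_P.append(rp)
        phase_Q.append(rq)
        rfs.append(r_new)

    pm = PhasedMap(
        markers=np.array(placed),
        phase_P=np.array(phase_P),
        phase_Q=np.array(phase_Q),
        rf=np.array(rfs),
        dropped=dropped,
    )
    if refine_passes > 0 and pm.n_markers >= 3:
        pm = _heal_gauge_breaks(pm, data, emission)
        pm = _refine_phases(
            pm, data, twopoint_cache, emission, lod_threshold,
            max_passes=refine_passes,
        )
        pm = _heal_gauge_breaks(pm, data, emission)
    pm.dropped = dropped
    return pm


# ---------------------------------------------------------------------------
# order comparison, pruning, constrained insertion


def compare_orders(
    candidate_orders,
    data,
    emission: EmissionModel,
    twopoint_cache: dict | None = None,
    em_tol: float = 1e-3,
    em_max_iter: int = 30,
):
    """Phase and re-estimate each candidate order; return the ML one.

    Every candidate is processed under identical settings; ties keep
    the earliest candidate.  Returns ``(best_index, best_map, logliks)``.
    """
    if len(candidate_orders) < 2:
        raise ValueError("need at least two candidate orders")
    if twopoint_cache is None:
        twopoint_cache = {}
    logliks = []
    maps = []
    for order in candidate_orders:
        pm = phase_markers(order, data, twopoint_cache, emission=emission)
        pm = reestimate_rfs(pm, data, emission, tol=em_tol, max_iter=em_max_iter)
        logliks.append(pm.loglik)
        maps.append(pm)
    best = 0
    for i, ll in enumerate(logliks):
        if ll > logliks[best] + 1e-9:  # ties keep the earliest candidate
            best = i
    return best, maps[best], logliks


def _window_fit_length(
    pm: PhasedMap, data, emission: EmissionModel, idx: np.ndarray
) -> float:
    sub = pm.subset(idx)
    sub = reestimate_rfs(sub, data, emission, tol=1e-3, max_iter=15)
    return sub.length_cM


def drop_inflating_markers(
    pm: PhasedMap,
    data,
    emission: EmissionModel,
    max_expansion_cM: float = 2.0,
    window: int = 5,
    min_markers: int = 4,
):
    """Remove markers whose inclusion inflates the local map length.

    For each marker a +/- ``window`` flanking region is re-fit with and
    without it; the worst marker exceeding ``max_expansion_cM`` of
    expansion is removed and the screen repeats to a fixed point.  A
    minimum-marker floor guards against degenerate over-pruning.
    Returns ``(pruned_map, removal_log)``.
    """
    pm = replace(pm)
    removed: list[tuple[int, float]] = []
    while pm.n_markers > min_markers:
        z = pm.n_markers
        worst = None
        for t in range(z):
            lo, hi = max(0, t - window), min(z, t + window + 1)
            idx_with = np.arange(lo, hi)
            idx_without = idx_with[idx_with != t]
            if len(idx_without) < 2:
                continue
            len_with = _window_fit_length(pm, data, emission, idx_with)
            len_without = _window_fit_length(pm, data, emission, idx_without)
            delta = len_with - len_without
            if delta > max_expansion_cM and (worst is None or delta > worst[1]):
                worst = (t, delta)
        if worst is None:
            break
        t, delta = worst
        removed.append((int(pm.markers[t]), float(delta)))
        keep = np.arange(pm.n_markers) != t
        pm = pm.subset(np.where(keep)[0])
        pm.dropped = list(pm.dropped)
    pm = reestimate_rfs(pm, data, emission, tol=1e-4, max_iter=30)
    return pm, removed


def insert_constrained_markers(
    pm: PhasedMap,
    private_markers,
    data,
    emission: EmissionModel,
    twopoint_cache: dict | None = None,
    window: int = 5,
):
    """Place anchored markers at their ML position within an interval.

    ``private_markers`` is a list of ``(data_index, (lo, hi))`` where
    the marker may be inserted at any slot between mapped positions
    ``lo`` and ``hi`` (inclusive slot range in current map order).
    Each marker is phased as in :func:`phase_markers`, evaluated at
    every admissible slot over a local window, and inserted at the
    best-likelihood slot; markers with an empty interval are skipped.
    Returns ``(map, skipped)``.
    """
    if twopoint_cache is None:
        twopoint_cache = {}
    skipped: list[int] = []
    for data_idx, (lo, hi) in private_markers:
        data_idx = int(data_idx)
        lo = max(0, int(lo))
        hi = min(pm.n_markers, int(hi))
        if hi <= lo:
            skipped.append(data_idx)
            continue
        best = None
        # one shared evaluation window spanning the whole anchor interval,
        # so slot likelihoods are comparable
        wlo, whi = max(0, lo - window), min(pm.n_markers, hi + window)
        idx = np.arange(wlo, whi)
        sub = pm.subset(idx)
        cands = _candidate_phases(
            data, twopoint_cache, data_idx, sub.markers,
            list(sub.phase_P), list(sub.phase_Q), 10.0, 20,
        )
        for slot in range(lo, hi + 1):
            local_slot = slot - wlo
            for rp, rq in cands[:5]:
                mk = np.insert(sub.markers, local_slot, data_idx)
                pP = np.insert(sub.phase_P, local_slot, rp, axis=0)
                pQ = np.insert(sub.phase_Q, local_slot, rq, axis=0)
                rf = np.insert(
                    sub.rf, min(local_slot, len(sub.rf)), 0.05
                ) if len(sub.rf) else np.array([0.05])
                cand_pm = PhasedMap(mk, pP, pQ, rf)
                cand_pm = reestimate_rfs(cand_pm, data, emission, tol=1e-2, max_iter=8)
                if best is None or cand_pm.loglik > best[0]:
                    best = (cand_pm.loglik, slot, rp, rq)
        if best is None:
            skipped.append(data_idx)
            continue
        _, slot, rp, rq = best
        mk = np.insert(pm.markers, slot, data_idx)
        pP = np.insert(pm.phase_P, slot, rp, axis=0)
        pQ = np.insert(pm.phase_Q, slot, rq, axis=0)
        rf = np.insert(pm.rf, min(slot, len(pm.rf)), 0.05) if len(pm.rf) else np.array([0.05])
        pm = PhasedMap(mk, pP, pQ, rf, dropped=pm.dropped)
        pm = reestimate_rfs(pm, data, emission, tol=1e-3, max_iter=15)
    return pm, skipped
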