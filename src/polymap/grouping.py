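"""Linkage-group assignment and initial marker ordering.

Markers are partitioned into linkage groups by UPGMA hierarchical
clustering of the pairwise recombination-fraction matrix, and each
group receives an initial linear order from weighted multidimensional
scaling (stress weighted by squared LOD scores) followed by a
principal-curve projection to one dimension — the standard "de novo"
stage of map construction when no reference genome is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from polymap.core import haldane

__all__ = ["upgma_groups", "mds_order", "MDSResult"]

_RF_CAP = 0.49  # unlinked-pair distances are capped before MDS


def upgma_groups(rf: np.ndarray, n_groups: int) -> np.ndarray:
    """Cut the UPGMA dendrogram of the rf matrix into ``n_groups`` clusters.

    Returns an integer label per marker, with labels 0.. ordered by
    decreasing cluster size (ties broken by first member index).
    Missing rf entries are treated as unlinked (0.5).
    """
    z = rf.shape[0]
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if n_groups > z:
        raise ValueError(f"cannot form {n_groups} groups from {z} markers")
    d = rf.copy()
    d[np.isnan(d)] = 0.5
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    Z = linkage(squareform(d, checks=False), method="average")
    raw = fcluster(Z, t=n_groups, criterion="maxclust")
    # order labels by size, then by first appearance
    labels = np.unique(raw)
    key = sorted(labels, key=lambda c: (-(raw == c).sum(), int(np.argmax(raw == c))))
    remap = {c: i for i, c in enumerate(key)}
    return np.array([remap[c] for c in raw], dtype=np.int64)


@dataclass
class MDSResult:
    order: np.ndarray  # marker indices in estimated linear order
    positions: np.ndarray  # 1-D arc-length coordinate per marker (input index order)
    stress: float
    stress_per_marker: np.ndarray  # contribution of each marker to the stress
    converged: bool


def _classical_mds(D: np.ndarray, ndim: int) -> np.ndarray:
    z = D.shape[0]
    J = np.eye(z) - np.ones((z, z)) / z
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    idx = np.argsort(vals)[::-1][:ndim]
    vals = np.clip(vals[idx], 0.0, None)
    return vecs[:, idx] * np.sqrt(vals)


def _smacof(D: np.ndarray, W: np.ndarray, X0: np.ndarray, n_iter: int, tol: float):
    z = D.shape[0]
    V = np.diag(W.sum(axis=1)) - W
    Vp = np.linalg.pinv(V + np.ones((z, z)) / z) - np.ones((z, z)) / z
    X = X0.copy()

    def dist(X):
        d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
        return d

    def stress(X):
        d = dist(X)
        return 0.5 * float((W * (D - d) ** 2).sum())

    prev = stress(X)
    for _ in range(n_iter):
        d = dist(X)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 1e-12, D / np.where(d > 1e-12, d, 1.0), 0.0)
        Bm = -W * ratio
        np.fill_diagonal(Bm, 0.0)
        np.fill_diagonal(Bm, -Bm.sum(axis=1))
        X = Vp @ Bm @ X
        cur = stress(X)
        if prev - cur < tol * max(prev, 1.0):
            return X, cur, True
        prev = cur
    return X, prev, False


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window < 3:
        return y.copy()
    kernel = np.ones(window) / window
    pad = window // 2
    yp = np.r_[np.full(pad, y[0]), y, np.full(pad, y[-1])]
    return np.convolve(yp, kernel, mode="valid")[: len(y)]


def _project_to_polyline(X: np.ndarray, curve: np.ndarray) -> np.ndarray:
    """Arc-length parameter of the closest point on the polyline for each row of X."""
    seg_start = curve[:-1]
    seg_vec = curve[1:] - curve[:-1]
    seg_len = np.linalg.norm(seg_vec, axis=1)
    cum = np.r_[0.0, np.cumsum(seg_len)]
    lam = np.empty(len(X))
    for i, p in enumerate(X):
        diff = p - seg_start
        denom = np.where(seg_len > 1e-12, seg_len ** 2, 1.0)
        t = np.clip((diff * seg_vec).sum(axis=1) / denom, 0.0, 1.0)
        proj = seg_start + t[:, None] * seg_vec
        d2 = ((p - proj) ** 2).sum(axis=1)
        j = int(np.argmin(d2))
        lam[i] = cum[j] + t[j] * seg_len[j]
    return lam


def _principal_curve_param(X: np.ndarray, n_iter: int = 8) -> np.ndarray:
    z = len(X)
    Xc = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    lam = Xc @ vt[0]
    window = max(3, z // 8) | 1
    for _ in range(n_iter):
        idx = np.argsort(lam, kind="stable")
        curve = np.column_stack(
            [_smooth(X[idx, c], window) for c in range(X.shape[1])]
        )
        lam_new = np.empty(z)
        lam_new[idx] = _project_to_polyline(X[idx], curve)
        if np.allclose(lam_new, lam, atol=1e-10):
            lam = lam_new
            break
        lam = lam_new
    return lam


def mds_order(
    rf: np.ndarray,
    lod: np.ndarray,
    n_iter: int = 300,
    tol: float = 1e-9,
) -> MDSResult:
    """Order markers within one linkage group by weighted MDS.

    Recombination fractions are converted to Haldane distances (capped
    at r = 0.49), a 2-D configuration is fit by SMACOF minimizing the
    stress weighted by squared LOD scores, and markers are projected
    onto a principal curve; the arc-length parameter gives the linear
    order (reported up to global reversal).  Falls back to 1-D
    classical scaling if the curve fit degenerates.
    """
    z = rf.shape[0]
    if z < 3:
        raise ValueError("MDS ordering needs at least 3 markers")
    W = lod.astype(float) ** 2
    W[np.isnan(rf)] = 0.0
    np.fill_diagonal(W, 0.0)

    g = nx.Graph()
    g.add_nodes_from(range(z))
    g.add_edges_from(zip(*np.where(W > 0)))
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        raise ValueError(
            f"rf submatrix is disconnected; components: "
            f"{[sorted(c) for c in comps]}"
        )

    D = haldane(np.clip(np.nan_to_num(rf, nan=_RF_CAP), 0.0, _RF_CAP))
    np.fill_diagonal(D, 0.0)

    X0 = _classical_mds(D, 2)
    X, stress, converged = _smacof(D, W, X0, n_iter, tol)
    try:
        lam = _principal_curve_param(X)
        if np.unique(lam).size < max(2, z // 2):
            raise FloatingPointError("degenerate principal curve")
    except FloatingPointError:
        lam = _classical_mds(D, 1)[:, 0]

    order = np.argsort(lam, kind="stable")
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    contrib = 0.5 * (W * (D - d) ** 2).sum(axis=1)
    return MDSResult(
        order=order,
        positions=lam - lam.min(),
        stress=float(stress),
        stress_per_marker=contrib,
        converged=converged,
    )
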