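"""Vertex-wise local functional homogeneity (2dReHo).

For every cortex vertex, 2dReHo is Kendall's coefficient of concordance
(W) computed over the rfMRI time series of the vertex and its 1-ring mesh
neighbors.  W is a rank statistic in [0, 1]: 1 means the K series rank the
timepoints identically, values near 1/K arise under independence.  Tie
correction is applied so that W stays exactly <= 1 on quantized data.

The map-level routine is vectorized: per-vertex ranks are computed once
and neighborhood rank sums are accumulated through the sparse mesh
adjacency, which reproduces the per-vertex definition exactly (a contract
covered by tests against the naive per-vertex computation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.stats import rankdata

from .mesh import SurfaceMesh

__all__ = ["RehoMap", "kendalls_w", "reho_map", "global_mean"]


@dataclass
class RehoMap:
    """Per-vertex W values for one subject; NaN marks masked vertices."""

    values: np.ndarray
    subject_id: str
    neighborhood_size: np.ndarray  # K per vertex, 0 where masked


def _tie_term(ranks: np.ndarray) -> np.ndarray:
    """Tie correction sum_j (t_j^3 - t_j) per series, from midranks.

    ``ranks`` is (K, n) with average ranks for ties; the multiset of
    midrank multiplicities recovers the tie-group sizes.
    """
    K, n = ranks.shape
    T = np.zeros(K)
    for i in range(K):
        _, counts = np.unique(ranks[i], return_counts=True)
        t = counts.astype(np.float64)
        T[i] = np.sum(t**3 - t)
    return T


def kendalls_w(series_matrix: np.ndarray) -> float:
    """Kendall's coefficient of concordance of K time series of length n.

    Ranks each series over time (midranks for ties) and returns

        W = 12 S / (K^2 (n^3 - n) - K T)

    with S the sum of squared deviations of per-timepoint rank sums from
    their mean and T the tie-correction term.
    """
    X = np.asarray(series_matrix, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("series_matrix must be 2-D (K x n)")
    K, n = X.shape
    if K < 2:
        raise ValueError("need at least 2 series")
    if n < 2:
        raise ValueError("need at least 2 timepoints")
    if not np.isfinite(X).all():
        raise ValueError("non-finite input")
    if np.any(np.ptp(X, axis=1) == 0):
        raise ValueError("constant series")
    R = rankdata(X, axis=1)
    col_sums = R.sum(axis=0)
    S = float(np.sum((col_sums - col_sums.mean()) ** 2))
    T = float(_tie_term(R).sum())
    denom = K**2 * (n**3 - n) - K * T
    if denom <= 0:
        raise ValueError("degenerate denominator (all series fully tied)")
    return min(1.0, 12.0 * S / denom)


def reho_map(vertex_time_matrix: np.ndarray, mesh: SurfaceMesh) -> RehoMap:
    """2dReHo at every cortex vertex of ``mesh``.

    The neighborhood of a vertex is itself plus its unmasked 1-ring
    neighbors; constant-series vertices are treated as masked (projection
    artifacts are expected near the medial wall) and vertices whose usable
    patch has K < 3 are masked rather than errored.
    """
    X = np.asarray(vertex_time_matrix, dtype=np.float64)
    V, n = X.shape
    if V != mesh.n_vertices:
        raise ValueError("matrix rows must match mesh vertices")
    usable = mesh.cortex_mask.copy()
    if not usable.any():
        raise ValueError("all vertices masked")
    with np.errstate(invalid="ignore"):
        usable &= np.ptp(np.nan_to_num(X, nan=0.0), axis=1) > 0
        usable &= np.isfinite(X).all(axis=1)

    R = np.zeros((V, n))
    if usable.any():
        R[usable] = rankdata(X[usable], axis=1)
    # tie term per usable series
    T = np.zeros(V)
    idx = np.flatnonzero(usable)
    if idx.size:
        T[idx] = _tie_term(R[idx])

    u = usable.astype(np.float64)
    A_closed = mesh.adjacency.astype(np.float64) + sp.eye(V, format="csr")
    Du = sp.diags(u)
    # restrict both membership and contributions to usable vertices
    M = Du @ A_closed @ Du
    K = np.asarray(M.sum(axis=1)).ravel()  # patch size per vertex
    rank_sums = M @ R  # (V, n) per-timepoint rank sums over the patch
    T_sums = M @ T

    mean_sum = K[:, None] * (n + 1) / 2.0
    S = np.sum((rank_sums - mean_sum) ** 2, axis=1)
    denom = K**2 * (n**3 - n) - K * T_sums
    values = np.full(V, np.nan)
    ok = usable & (K >= 3) & (denom > 0)
    values[ok] = np.minimum(1.0, 12.0 * S[ok] / denom[ok])
    Kout = np.where(ok, K, 0).astype(int)
    return RehoMap(values=values, subject_id="", neighborhood_size=Kout)


def global_mean(
    values: np.ndarray,
    mesh: SurfaceMesh,
    area_weighted: bool = False,
    include_all: bool = False,
) -> float:
    """Mean of a vertex map over unmasked, finite vertices.

    ``include_all`` averages over every finite vertex regardless of the
    cortex mask; ``area_weighted`` weights by per-vertex area.
    """
    values = np.asarray(values, dtype=np.float64)
    sel = np.isfinite(values)
    if not include_all:
        sel &= mesh.cortex_mask
    if not sel.any():
        raise ValueError("no unmasked vertices")
    if area_weighted:
        w = mesh.vertex_areas[sel]
        return float(np.sum(values[sel] * w) / w.sum())
    return float(values[sel].mean())
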