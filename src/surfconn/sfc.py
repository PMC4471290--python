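"""Cluster-seeded remote functional connectivity (SFC).

A seed region's mean time series (extracted from 6-mm-smoothed data) is
correlated with every cortex vertex of the same smoothed data; the
correlation map is Fisher z-transformed (variance stabilizing) and then
smoothed at 10 mm.  Seed vertices remain in the map but are flagged,
since self-correlation inflates them; group statistics may exclude them
by configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import SurfaceMesh
from .reho import global_mean
from .smooth import SmoothingSpec, smooth_map

__all__ = ["FCMap", "seed_timeseries", "sfc_map", "fisher_z", "inverse_fisher_z",
           "global_mean_sfc"]

_R_CLAMP = 1.0 - 1e-7


@dataclass
class FCMap:
    """Per-vertex Fisher z connectivity with one seed; NaN = masked."""

    values: np.ndarray
    subject_id: str
    seed_vertices: np.ndarray


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z = atanh(r); requires |r| < 1."""
    r_arr = np.asarray(r, dtype=np.float64)
    if np.any(np.abs(r_arr) >= 1):
        raise ValueError("|r| must be < 1")
    out = np.arctanh(r_arr)
    return float(out) if np.isscalar(r) else out


def inverse_fisher_z(z: np.ndarray | float) -> np.ndarray | float:
    out = np.tanh(np.asarray(z, dtype=np.float64))
    return float(out) if np.isscalar(z) else out


def seed_timeseries(vertex_time_matrix: np.ndarray, cluster_vertices: np.ndarray,
                    mesh: SurfaceMesh | None = None) -> np.ndarray:
    """Unweighted mean time series over the cluster's (unmasked) vertices."""
    idx = np.asarray(cluster_vertices, dtype=int)
    if mesh is not None:
        idx = idx[mesh.cortex_mask[idx]]
    if idx.size == 0:
        raise ValueError("cluster fully masked")
    return np.asarray(vertex_time_matrix, dtype=np.float64)[idx].mean(axis=0)


def sfc_map(
    vertex_time_matrix: np.ndarray,
    seed_series: np.ndarray,
    mesh: SurfaceMesh,
    seed_vertices: np.ndarray,
    map_smoothing: SmoothingSpec | None = None,
    subject_id: str = "",
) -> FCMap:
    """Pearson r of every cortex vertex with the seed series, as Fisher z.

    r is clamped to +/-(1 - 1e-7) before atanh; the z map is then smoothed
    with ``map_smoothing`` (pass None to skip).  Constant-series vertices
    come out NaN (masked).
    """
    X = np.asarray(vertex_time_matrix, dtype=np.float64)
    s = np.asarray(seed_series, dtype=np.float64)
    if X.shape[1] != s.size:
        raise ValueError("series length mismatch")
    if np.ptp(s) == 0:
        raise ValueError("constant seed series")
    sc = s - s.mean()
    sn = np.sqrt(np.sum(sc**2))
    Xc = X - X.mean(axis=1, keepdims=True)
    xn = np.sqrt(np.sum(Xc**2, axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ sc) / (xn * sn)
    r[xn == 0] = np.nan
    r[~mesh.cortex_mask] = np.nan
    r = np.clip(r, -_R_CLAMP, _R_CLAMP)
    z = np.arctanh(r)
    if map_smoothing is not None and map_smoothing.n_iterations > 0:
        finite = np.isfinite(z)
        if not finite[mesh.cortex_mask].all():
            sub = SurfaceMesh(mesh.vertex_coords, mesh.triangles,
                              mesh.cortex_mask & finite)
            z = smooth_map(z, sub, map_smoothing)
        else:
            z = smooth_map(z, mesh, map_smoothing)
    return FCMap(values=z, subject_id=subject_id,
                 seed_vertices=np.asarray(seed_vertices, dtype=int))


def global_mean_sfc(
    fc_map: FCMap, mesh: SurfaceMesh, include_seed: bool = True
) -> float:
    """Mean Fisher z over cortex vertices (seed included by default)."""
    vals = fc_map.values
    if not include_seed:
        vals = vals.copy()
        vals[fc_map.seed_vertices] = np.nan
    return global_mean(vals, mesh)
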