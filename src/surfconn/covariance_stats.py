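"""Local-remote functional covariance and symptom correlations.

For each cluster, the across-subject Pearson correlation between its mean
local homogeneity (2dReHo) and its mean remote connectivity (Fisher z)
quantifies how tightly local and long-range connectivity covary within a
group; group differences in that covariance are compared with the
independent-samples Fisher z-test.  Symptom correlations relate cluster
metrics to PANSS subscale scores; every configured pair is reported
(uncorrected, labelled exploratory) to avoid selective reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CovarianceResult",
    "cluster_mean_metric",
    "local_remote_covariance",
    "compare_correlations",
    "symptom_correlation",
]


@dataclass
class CovarianceResult:
    group: str
    n: int
    r: float
    p: float
    comparison_z: float | None = None
    comparison_p: float | None = None


def cluster_mean_metric(maps: np.ndarray, cluster_vertices: np.ndarray) -> np.ndarray:
    """Per-subject unweighted mean of a map stack over cluster vertices."""
    idx = np.asarray(cluster_vertices, dtype=int)
    if idx.size == 0:
        raise ValueError("empty cluster")
    M = np.asarray(maps, dtype=np.float64)
    if M.ndim == 1:
        M = M[None, :]
    return M[:, idx].mean(axis=1)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def local_remote_covariance(
    reho_means: np.ndarray,
    z_means: np.ndarray,
    group_labels: np.ndarray,
) -> dict[str, CovarianceResult]:
    """Per-group Pearson r between local and remote cluster means.

    Requires >= 4 subjects per group; when exactly two groups are present
    the Fisher z-test comparison is filled in on both results (signed from
    the perspective of each group against the other).
    """
    groups = list(dict.fromkeys(np.asarray(group_labels)))
    out: dict[str, CovarianceResult] = {}
    for g in groups:
        sel = np.asarray(group_labels) == g
        n = int(sel.sum())
        if n < 4:
            raise ValueError(f"group {g!r} has fewer than 4 subjects")
        r, p = _pearson(np.asarray(reho_means)[sel], np.asarray(z_means)[sel])
        out[str(g)] = CovarianceResult(group=str(g), n=n, r=r, p=p)
    if len(groups) == 2:
        a, b = (out[str(g)] for g in groups)
        clamp = 1.0 - 1e-7  # degenerate |r| = 1 (noise-free input) stays testable
        z, p = compare_correlations(
            float(np.clip(a.r, -clamp, clamp)), a.n,
            float(np.clip(b.r, -clamp, clamp)), b.n,
        )
        a.comparison_z, a.comparison_p = z, p
        b.comparison_z, b.comparison_p = -z, p
    return out


def compare_correlations(
    r1: float, n1: int, r2: float, n2: int
) -> tuple[float, float]:
    """Independent-samples Fisher z-test for the difference of two correlations.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), two-tailed p
    from the standard normal.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("both groups need n > 3")
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("|r| must be < 1")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def symptom_correlation(
    cluster_metric: np.ndarray, scores: np.ndarray
) -> tuple[float, float]:
    """Pearson r and two-tailed p between a cluster metric and symptom scores."""
    x = np.asarray(cluster_metric, dtype=np.float64)
    y = np.asarray(scores, dtype=np.float64)
    if x.size != y.size or x.size < 4:
        raise ValueError("need >= 4 paired observations")
    return _pearson(x, y)
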