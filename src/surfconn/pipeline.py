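"""End-to-end local-to-remote connectivity analysis.

Stages, in order: QC exclusions -> per-subject 2dReHo (10-mm smoothed) ->
global-mean tests -> group-level nuisance residualization -> vertex GLM
(diagnosis main effect and diagnosis-age interaction) -> cluster
inference -> each surviving cluster seeds the remote stage (seed FC on
6-mm-smoothed series, z maps smoothed 10 mm, three-nuisance
residualization, GLM, cluster inference at alpha/N) -> local-remote
covariance and symptom correlations -> optional leave-one-out
reproducibility.

The local nuisance set is meanFD, mcBBR, the mean surface Jacobian and
the subject's global mean 2dReHo; the remote set drops the Jacobian and
swaps in the global mean SFC.  N in the alpha/N seed correction counts
the clusters actually carried into the remote stage of the current run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import covariance_stats as cov
from .cluster_inference import (
    Cluster,
    InferenceConfig,
    correct_across_seeds,
    estimate_smoothness,
    form_clusters,
    permutation_cluster_p,
    rft_cluster_p,
)
from .glm import DesignMatrix, fit_vertex_glm, make_design, residualize
from .mesh import SurfaceMesh
from .qc import apply_exclusions
from .reho import global_mean, reho_map
from .sfc import global_mean_sfc, sfc_map, seed_timeseries
from .smooth import SmoothingSpec, fwhm_to_iterations, smooth_timeseries
from .synthetic_cohort import SubjectData

__all__ = [
    "PipelineConfig",
    "LocalStageResult",
    "RemoteStageResult",
    "run_qc_stage",
    "run_local_stage",
    "run_remote_stage",
    "run_covariance_stage",
    "leave_one_out_reproducibility",
    "run_full",
]


@dataclass
class PipelineConfig:
    map_fwhm_mm: float = 10.0
    timeseries_fwhm_mm: float = 6.0
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    run_interaction: bool = True
    include_seed_in_global: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "map_fwhm_mm": self.map_fwhm_mm,
            "timeseries_fwhm_mm": self.timeseries_fwhm_mm,
            "inference": {
                "cluster_defining_p": self.inference.cluster_defining_p,
                "cluster_alpha": self.inference.cluster_alpha,
                "method": self.inference.method,
                "n_permutations": self.inference.n_permutations,
                "seed": self.inference.seed,
            },
            "run_interaction": self.run_interaction,
            "include_seed_in_global": self.include_seed_in_global,
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _phenotype_frame(subjects: list[SubjectData]):
    import pandas as pd

    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "group": [s.group for s in subjects],
            "age": [s.age for s in subjects],
            "sex": [s.sex for s in subjects],
        }
    )


def _analysis_mesh(mesh: SurfaceMesh, stack: np.ndarray) -> SurfaceMesh:
    """Mesh with its mask narrowed to vertices finite in every subject."""
    finite = np.isfinite(stack).all(axis=0)
    mask = mesh.cortex_mask & finite
    if mask.sum() == mesh.cortex_mask.sum():
        return mesh
    return SurfaceMesh(mesh.vertex_coords, mesh.triangles, mask)


def _smooth_stack(stack: np.ndarray, mesh: SurfaceMesh, spec: SmoothingSpec) -> np.ndarray:
    # per-map smoothing shares one operator; time axis trick reuses
    # smooth_timeseries with maps as "timepoints"
    return smooth_timeseries(stack.T, mesh, spec).T


def _infer(
    stack: np.ndarray,
    design: DesignMatrix,
    contrast: str,
    mesh: SurfaceMesh,
    config: InferenceConfig,
) -> tuple[object, list[Cluster]]:
    """Fit + cluster inference with the configured engine."""
    result = fit_vertex_glm(stack, design, contrast)
    if config.method == "permutation":
        clusters, _ = permutation_cluster_p(stack, design, contrast, mesh, config)
    else:
        clusters = form_clusters(result, mesh, config)
        if clusters:
            sm = estimate_smoothness(result.residuals, mesh)
            for cl in clusters:
                cl.corrected_p = rft_cluster_p(cl, sm, config, df=result.df)
    return result, clusters


@dataclass
class LocalStageResult:
    reho_stack: np.ndarray  # smoothed maps, (n_subjects, V)
    resid_reho_stack: np.ndarray  # nuisance-residualized maps
    global_reho: np.ndarray
    global_tests: dict
    glm_results: dict
    clusters: dict  # contrast -> list[Cluster]
    seeds: list  # (contrast, Cluster) pairs surviving correction
    analysis_mesh: SurfaceMesh


def run_qc_stage(subjects: list[SubjectData]) -> tuple[list[SubjectData], list[dict]]:
    kept_qc, dropped_qc = apply_exclusions([s.qc for s in subjects])
    kept_ids = {q.subject_id for q in kept_qc}
    kept = [s for s in subjects if s.qc.subject_id in kept_ids]
    dropped = [
        {"subject_id": q.subject_id, "reasons": reasons} for q, reasons in dropped_qc
    ]
    return kept, dropped


def run_local_stage(
    subjects: list[SubjectData], mesh: SurfaceMesh, config: PipelineConfig
) -> LocalStageResult:
    if len({s.group for s in subjects}) < 2:
        raise ValueError("need two groups after QC")
    raw = np.stack(
        [reho_map(s.vertex_time_matrix, mesh).values for s in subjects]
    )
    amesh = _analysis_mesh(mesh, raw)
    spec = SmoothingSpec(config.map_fwhm_mm,
                         fwhm_to_iterations(config.map_fwhm_mm, amesh))
    filled = np.where(np.isfinite(raw), raw, 0.0)
    stack = _smooth_stack(filled, amesh, spec)
    stack[:, ~amesh.cortex_mask] = np.nan

    g = np.array([global_mean(stack[i], amesh) for i in range(stack.shape[0])])
    pheno = _phenotype_frame(subjects)
    design = make_design(pheno)
    design_int = make_design(pheno, interaction=True)

    global_tests = {}
    gres = fit_vertex_glm(g[:, None], design, "diagnosis")
    global_tests["diagnosis"] = {"t": float(gres.t[0]), "p": float(gres.p[0])}
    if config.run_interaction:
        gres_i = fit_vertex_glm(g[:, None], design_int, "age_x_diagnosis")
        global_tests["age_x_diagnosis"] = {
            "t": float(gres_i.t[0]), "p": float(gres_i.p[0]),
        }

    nuis = np.column_stack(
        [
            np.ones(len(subjects)),
            [s.qc.meanFD for s in subjects],
            [s.qc.mcBBR for s in subjects],
            [s.qc.jacobian_mean for s in subjects],
            g,
        ]
    )
    resid_stack = residualize(stack, nuis)

    glm_results, clusters, seeds = {}, {}, []
    contrasts = [("diagnosis", design)]
    if config.run_interaction:
        contrasts.append(("age_x_diagnosis", design_int))
    for name, dm in contrasts:
        res, cls = _infer(resid_stack, dm, name, amesh, config.inference)
        glm_results[name] = res
        clusters[name] = cls
        for cl in cls:
            if cl.corrected_p is not None and cl.corrected_p < config.inference.cluster_alpha:
                seeds.append((name, cl))
    return LocalStageResult(
        reho_stack=stack,
        resid_reho_stack=resid_stack,
        global_reho=g,
        global_tests=global_tests,
        glm_results=glm_results,
        clusters=clusters,
        seeds=seeds,
        analysis_mesh=amesh,
    )


@dataclass
class RemoteStageResult:
    n_seeds: int
    per_seed_alpha: float
    seed_results: list  # dicts: contrast, seed cluster, z stack, clusters, tests


def run_remote_stage(
    seeds: list,
    subjects: list[SubjectData],
    mesh: SurfaceMesh,
    config: PipelineConfig,
) -> RemoteStageResult:
    if not seeds:
        return RemoteStageResult(n_seeds=0, per_seed_alpha=float("nan"), seed_results=[])
    N = len(seeds)
    alpha_n = correct_across_seeds(config.inference.cluster_alpha, N)
    ts_spec = SmoothingSpec(
        config.timeseries_fwhm_mm, fwhm_to_iterations(config.timeseries_fwhm_mm, mesh)
    )
    smoothed = [
        smooth_timeseries(s.vertex_time_matrix, mesh, ts_spec) for s in subjects
    ]
    pheno = _phenotype_frame(subjects)
    design = make_design(pheno)
    design_int = make_design(pheno, interaction=True)
    map_spec_cache: dict[int, SmoothingSpec] = {}

    results = []
    for contrast_name, seed_cluster in seeds:
        zmaps = []
        for X, s in zip(smoothed, subjects):
            series = seed_timeseries(X, seed_cluster.vertices, mesh)
            if mesh.n_vertices not in map_spec_cache:
                map_spec_cache[mesh.n_vertices] = SmoothingSpec(
                    config.map_fwhm_mm, fwhm_to_iterations(config.map_fwhm_mm, mesh)
                )
            fc = sfc_map(
                X, series, mesh, seed_cluster.vertices,
                map_smoothing=map_spec_cache[mesh.n_vertices],
                subject_id=s.subject_id,
            )
            zmaps.append(fc)
        stack = np.stack([f.values for f in zmaps])
        amesh = _analysis_mesh(mesh, stack)
        g_sfc = np.array(
            [global_mean_sfc(f, amesh, include_seed=config.include_seed_in_global)
             for f in zmaps]
        )
        gres = fit_vertex_glm(g_sfc[:, None], design, "diagnosis")
        nuis = np.column_stack(
            [
                np.ones(len(subjects)),
                [s.qc.meanFD for s in subjects],
                [s.qc.mcBBR for s in subjects],
                g_sfc,
            ]
        )
        resid_stack = residualize(stack, nuis)
        icfg = InferenceConfig(
            cluster_defining_p=config.inference.cluster_defining_p,
            cluster_alpha=alpha_n,
            n_seeds_for_bonferroni=N,
            method=config.inference.method,
            n_permutations=config.inference.n_permutations,
            seed=config.inference.seed,
        )
        res, cls = _infer(resid_stack, design, "diagnosis", amesh, icfg)
        entry = {
            "seed_contrast": contrast_name,
            "seed_cluster": seed_cluster,
            "z_stack": stack,
            "resid_z_stack": resid_stack,
            "global_sfc": g_sfc,
            "global_test": {"t": float(gres.t[0]), "p": float(gres.p[0])},
            "glm_result": res,
            "clusters": cls,
            "significant": [
                c for c in cls if c.corrected_p is not None and c.corrected_p < alpha_n
            ],
        }
        if config.run_interaction:
            res_i, cls_i = _infer(resid_stack, design_int, "age_x_diagnosis", amesh, icfg)
            entry["interaction_clusters"] = cls_i
            entry["interaction_significant"] = [
                c for c in cls_i
                if c.corrected_p is not None and c.corrected_p < alpha_n
            ]
        results.append(entry)
    return RemoteStageResult(n_seeds=N, per_seed_alpha=alpha_n, seed_results=results)


def run_covariance_stage(
    local: LocalStageResult,
    remote: RemoteStageResult,
    subjects: list[SubjectData],
) -> list[dict]:
    """Local-remote covariance for every (seed, significant remote cluster) pair.

    The local metric is the mean 2dReHo within the seed cluster; the
    remote metric is the mean Fisher z of that seed's FC map within the
    remote cluster; Pearson r per group plus the Fisher z-test of the
    group difference.  Both metrics are taken from the
    nuisance-residualized stacks: the motion component is shared between
    every subject's local and remote maps, so raw cluster means would
    covary through head motion alone in every group.
    """
    labels = np.array([s.group for s in subjects])
    out = []
    for entry in remote.seed_results:
        seed_cl = entry["seed_cluster"]
        reho_means = cov.cluster_mean_metric(local.resid_reho_stack, seed_cl.vertices)
        for rc in entry["significant"]:
            z_means = cov.cluster_mean_metric(entry["resid_z_stack"], rc.vertices)
            res = cov.local_remote_covariance(reho_means, z_means, labels)
            out.append(
                {
                    "seed_contrast": entry["seed_contrast"],
                    "seed_peak_vertex": seed_cl.peak_vertex,
                    "remote_peak_vertex": rc.peak_vertex,
                    "by_group": {
                        g: {
                            "n": r.n, "r": r.r, "p": r.p,
                            "comparison_z": r.comparison_z,
                            "comparison_p": r.comparison_p,
                        }
                        for g, r in res.items()
                    },
                }
            )
    return out


def run_symptom_stage(
    local: LocalStageResult,
    remote: RemoteStageResult,
    subjects: list[SubjectData],
) -> list[dict]:
    """Exploratory PANSS correlations in patients for every cluster metric.

    All configured (metric, subscale) pairs are reported, uncorrected.
    """
    pat = [s for s in subjects if s.group == "patient"]
    if len(pat) < 4:
        return []
    pat_idx = np.array([i for i, s in enumerate(subjects) if s.group == "patient"])
    subscales = {
        "positive": [s.phenotype.panss_positive for s in pat],
        "negative": [s.phenotype.panss_negative for s in pat],
        "general": [s.phenotype.panss_general for s in pat],
        "supplementary": [s.phenotype.panss_supplementary for s in pat],
        "total": [s.phenotype.panss_total for s in pat],
    }
    out = []
    for entry in remote.seed_results:
        seed_cl = entry["seed_cluster"]
        metrics = {
            "reho": cov.cluster_mean_metric(local.reho_stack, seed_cl.vertices)[pat_idx],
            "sfc_global": entry["global_sfc"][pat_idx],
        }
        for mname, mvals in metrics.items():
            for sname, svals in subscales.items():
                svals = np.asarray(svals, dtype=float)
                if np.ptp(svals) == 0 or np.ptp(mvals) == 0:
                    continue
                r, p = cov.symptom_correlation(mvals, svals)
                out.append(
                    {
                        "seed_peak_vertex": seed_cl.peak_vertex,
                        "metric": mname,
                        "panss_subscale": sname,
                        "r": r,
                        "p": p,
                        "note": "exploratory, uncorrected",
                    }
                )
    return out


def leave_one_out_reproducibility(
    subjects: list[SubjectData],
    mesh: SurfaceMesh,
    config: PipelineConfig,
    contrast: str = "diagnosis",
) -> dict:
    """Detection-frequency map across leave-one-out repetitions of the local stage."""
    for g in ("control", "patient"):
        if sum(s.group == g for s in subjects) < 6:
            raise ValueError("need >= 6 subjects per group for leave-one-out")
    V = mesh.n_vertices
    counts = np.zeros(V)
    n_rep = len(subjects)
    cfg = PipelineConfig(
        map_fwhm_mm=config.map_fwhm_mm,
        timeseries_fwhm_mm=config.timeseries_fwhm_mm,
        inference=config.inference,
        run_interaction=(contrast == "age_x_diagnosis"),
        seed=config.seed,
    )
    for i in range(n_rep):
        sub = subjects[:i] + subjects[i + 1 :]
        local = run_local_stage(sub, mesh, cfg)
        for cl in local.clusters.get(contrast, []):
            if cl.corrected_p is not None and cl.corrected_p < cfg.inference.cluster_alpha:
                counts[cl.vertices] += 1
    freq = counts / n_rep
    full = run_local_stage(subjects, mesh, cfg)
    summaries = []
    for cl in full.clusters.get(contrast, []):
        if cl.corrected_p is not None and cl.corrected_p < cfg.inference.cluster_alpha:
            f = freq[cl.vertices]
            summaries.append(
                {
                    "peak_vertex": cl.peak_vertex,
                    "min_fraction": float(f.min()),
                    "median_fraction": float(np.median(f)),
                }
            )
    return {"frequency_map": freq, "cluster_summaries": summaries}


def run_full(
    subjects: list[SubjectData],
    mesh: SurfaceMesh,
    config: PipelineConfig,
    run_loo: bool = False,
) -> dict:
    """QC -> local -> remote -> covariance/symptoms [-> leave-one-out]; JSON-able report."""
    kept, dropped = run_qc_stage(subjects)
    report: dict = {
        "provenance": {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "n_subjects_input": len(subjects),
        },
        "qc": {"n_kept": len(kept), "dropped": dropped},
    }
    local = run_local_stage(kept, mesh, config)
    report["local"] = {
        "global_mean_reho": [float(x) for x in local.global_reho],
        "global_tests": local.global_tests,
        "clusters": {
            name: [c.to_dict() for c in cls] for name, cls in local.clusters.items()
        },
        "n_seeds": len(local.seeds),
    }
    remote = run_remote_stage(local.seeds, kept, mesh, config)
    report["remote"] = {
        "n_seeds": remote.n_seeds,
        "per_seed_alpha": None if remote.n_seeds == 0 else remote.per_seed_alpha,
        "seeds": [
            {
                "seed_contrast": e["seed_contrast"],
                "seed_peak_vertex": e["seed_cluster"].peak_vertex,
                "global_test": e["global_test"],
                "clusters": [c.to_dict() for c in e["clusters"]],
            }
            for e in remote.seed_results
        ],
    }
    report["covariance"] = run_covariance_stage(local, remote, kept)
    report["symptom_correlations"] = run_symptom_stage(local, remote, kept)
    if run_loo:
        loo = leave_one_out_reproducibility(kept, mesh, config)
        report["leave_one_out"] = {"cluster_summaries": loo["cluster_summaries"]}
    return report
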