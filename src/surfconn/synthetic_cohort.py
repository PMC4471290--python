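"""Synthetic surface rfMRI cohorts with planted, recoverable effects.

The generator emulates *post-preprocessing* surface time series on a
shared mesh: per-vertex temporally band-limited Gaussian noise, plus
latent signals mixed by variance fractions.

* A :class:`PlantedPatch` injects a patch-wide latent at fraction
  ``lambda`` of each member vertex's variance, so neighboring patch
  vertices correlate at ~lambda and the patch's true local homogeneity
  (2dReHo) is monotone in lambda.
* A :class:`PlantedCoupling` makes two patches' latents share a common
  signal at fraction ``phi`` of the latent variance, so remote
  patch-to-patch connectivity is monotone in phi.
* Group, age-slope and subject-jitter terms move lambda and phi per
  subject, planting diagnosis effects, diagnosis-age interactions, and
  (via a per-subject latent shared between local and remote jitters) a
  local-remote covariance structure in chosen groups.
* A global motion component scaled by the subject's drawn meanFD
  contaminates every vertex, creating the nuisance structure that group
  analyses must regress out.

All signals are variance-normalized before mixing, so planted "true
ReHo" and "true FC" are analytically monotone in the mixing fractions —
the property the recovery tests rely on.  Everything is deterministic
given the design seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .mesh import SurfaceMesh
from .qc import SubjectQC

__all__ = [
    "PlantedPatch",
    "PlantedCoupling",
    "Phenotype",
    "SubjectData",
    "SyntheticDesign",
    "TruthRecord",
    "generate_cohort",
    "generate_null_cohort",
    "ring_patch",
    "antipodal_vertex",
    "write_cohort",
    "load_cohort",
]

GROUPS = ("control", "patient")
MAX_FRACTION = 0.95


@dataclass
class PlantedPatch:
    """A contiguous vertex set sharing a latent signal (true ReHo effect)."""

    vertex_set: np.ndarray
    local_coupling_base: float
    group_effect: float = 0.0  # additive change in patients
    age_slope_by_group: dict = field(default_factory=dict)  # per-year change
    subject_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        self.vertex_set = np.asarray(self.vertex_set, dtype=int)


@dataclass
class PlantedCoupling:
    """A shared latent between two patches (true remote-FC effect)."""

    patch_a: int
    patch_b: int
    shared_signal_fraction_by_group: dict
    age_slope_by_group: dict = field(default_factory=dict)
    subject_jitter_sd: float = 0.0


@dataclass
class Phenotype:
    panss_positive: int
    panss_negative: int
    panss_general: int
    panss_supplementary: int
    panss_total: int
    diagnosis_code: int  # 0 control, 1 patient

    def __post_init__(self) -> None:
        for s in (self.panss_positive, self.panss_negative, self.panss_general,
                  self.panss_supplementary):
            if self.panss_total < s:
                raise ValueError("total PANSS below a subscale score")


@dataclass
class SubjectData:
    subject_id: str
    group: str
    age: float
    sex: int  # 0 female, 1 male
    vertex_time_matrix: np.ndarray
    qc: SubjectQC
    phenotype: Phenotype

    def __post_init__(self) -> None:
        self.vertex_time_matrix = np.asarray(self.vertex_time_matrix, dtype=np.float64)
        if not np.isfinite(self.vertex_time_matrix).all():
            raise ValueError("non-finite entries in time series")


@dataclass
class SyntheticDesign:
    mesh: SurfaceMesh
    n_per_group: int = 20
    n_timepoints: int = 120
    tr_seconds: float = 2.0
    patches: list = field(default_factory=list)
    couplings: list = field(default_factory=list)
    age_range_by_group: dict = field(
        default_factory=lambda: {"control": (14.0, 30.0), "patient": (14.0, 30.0)}
    )
    sex_ratio: float = 0.5
    nuisance_model: dict = field(
        default_factory=lambda: {
            "motion_scale": 1.0,
            "global_signal_base": 0.08,
            "global_signal_sd": 0.05,
        }
    )
    noise_sigma: float = 1.0
    seed: int = 0
    # correlation between local and remote subject jitters, per group;
    # drives the local-remote covariance structure when set to ~1 in a group
    local_remote_link_by_group: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_per_group < 4:
            raise ValueError("n_per_group must be >= 4")
        if self.n_timepoints < 30:
            raise ValueError("n_timepoints must be >= 30")
        seen: set[int] = set()
        for p in self.patches:
            vs = set(int(v) for v in p.vertex_set)
            if vs & seen:
                raise ValueError("patches must be disjoint")
            if not self.mesh.cortex_mask[list(vs)].all():
                raise ValueError("patch extends outside cortex mask")
            seen |= vs


@dataclass
class TruthRecord:
    """Ground truth: patch/coupling definitions plus realized per-subject fractions."""

    patches: list
    couplings: list
    subject_ids: list
    groups: list
    lambda_by_subject: np.ndarray  # (n_subjects, n_patches)
    phi_by_subject: np.ndarray  # (n_subjects, n_couplings)

    def to_json(self) -> str:
        return json.dumps(
            {
                "patches": [
                    {
                        "vertices": [int(v) for v in p.vertex_set],
                        "local_coupling_base": p.local_coupling_base,
                        "group_effect": p.group_effect,
                        "age_slope_by_group": p.age_slope_by_group,
                    }
                    for p in self.patches
                ],
                "couplings": [
                    {
                        "patch_a": c.patch_a,
                        "patch_b": c.patch_b,
                        "shared_signal_fraction_by_group": c.shared_signal_fraction_by_group,
                        "age_slope_by_group": c.age_slope_by_group,
                    }
                    for c in self.couplings
                ],
                "subject_ids": self.subject_ids,
                "groups": self.groups,
                "lambda_by_subject": self.lambda_by_subject.tolist(),
                "phi_by_subject": self.phi_by_subject.tolist(),
            },
            indent=1,
        )


# ---------------------------------------------------------------------------
# helpers

def ring_patch(mesh: SurfaceMesh, center: int, n_rings: int) -> np.ndarray:
    """Vertices within ``n_rings`` edge steps of ``center`` (BFS ball)."""
    current = {int(center)}
    seen = set(current)
    for _ in range(n_rings):
        nxt = set()
        for v in current:
            nxt.update(int(u) for u in mesh.neighbor_lists[v])
        current = nxt - seen
        seen |= nxt
    out = np.array(sorted(seen), dtype=int)
    return out[mesh.cortex_mask[out]]


def antipodal_vertex(mesh: SurfaceMesh, vertex: int) -> int:
    """Vertex closest to the point mirror-opposite ``vertex`` (homotopic stand-in)."""
    target = -mesh.vertex_coords[vertex]
    d = np.linalg.norm(mesh.vertex_coords - target, axis=1)
    d[~mesh.cortex_mask] = np.inf
    return int(np.argmin(d))


def _band_limited(rng: np.random.Generator, shape: tuple, window: int) -> np.ndarray:
    """Unit-variance Gaussian series, temporally smoothed by a moving average."""
    x = rng.standard_normal(shape)
    if window > 1:
        x = uniform_filter1d(x, size=window, axis=-1, mode="nearest")
    x = x - x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _age_center(design: SyntheticDesign, group: str) -> float:
    lo, hi = design.age_range_by_group[group]
    return 0.5 * (lo + hi)


def _draw_qc(rng: np.random.Generator, subject_id: str) -> SubjectQC:
    # meanFD centered near 0.15 mm with sd ~0.09 (typical adolescent cohorts)
    meanFD = float(np.clip(rng.normal(0.15, 0.09), 0.02, 1.0))
    return SubjectQC(
        meanFD=meanFD,
        maxTran=float(np.clip(rng.normal(0.8, 0.5), 0.05, 5.0)),
        maxRot=float(np.clip(rng.normal(0.8, 0.5), 0.05, 5.0)),
        mcBBR=float(np.clip(rng.normal(0.55, 0.05), 0.3, 0.9)),
        jacobian_mean=float(np.clip(rng.normal(1.0, 0.05), 0.7, 1.3)),
        subject_id=subject_id,
    )


def _draw_phenotype(rng: np.random.Generator, group: str) -> Phenotype:
    if group == "patient":
        pos = int(rng.integers(10, 31))
        neg = int(rng.integers(10, 31))
        gen = int(rng.integers(24, 61))
        supp = int(rng.integers(4, 16))
    else:
        pos, neg, gen, supp = 7, 7, 16, 3
    return Phenotype(pos, neg, gen, supp, pos + neg + gen, int(group == "patient"))


# ---------------------------------------------------------------------------
# generation

def generate_cohort(design: SyntheticDesign) -> tuple[list[SubjectData], TruthRecord]:
    """Simulate one two-group cohort; deterministic given ``design.seed``."""
    rng = np.random.default_rng(design.seed)
    mesh = design.mesh
    V, T = mesh.n_vertices, design.n_timepoints
    window = max(1, int(round(1.0 / (2.0 * 0.1 * design.tr_seconds))))
    n_patches = len(design.patches)
    n_coup = len(design.couplings)

    patch_of_coupling: dict[int, int] = {}
    for ci, c in enumerate(design.couplings):
        for pi in (c.patch_a, c.patch_b):
            if pi in patch_of_coupling:
                raise ValueError("a patch may participate in at most one coupling")
            patch_of_coupling[pi] = ci

    subjects: list[SubjectData] = []
    lam_all = np.zeros((2 * design.n_per_group, n_patches))
    phi_all = np.zeros((2 * design.n_per_group, n_coup))
    ids: list[str] = []
    groups: list[str] = []

    s_index = 0
    for group in GROUPS:
        for k in range(design.n_per_group):
            sid = f"{group[:3]}{k:03d}"
            lo, hi = design.age_range_by_group[group]
            age = float(rng.uniform(lo, hi))
            sex = int(rng.random() < design.sex_ratio)
            qc = _draw_qc(rng, sid)
            pheno = _draw_phenotype(rng, group)
            is_pat = float(group == "patient")
            age_c = age - _age_center(design, group)

            # shared subject latent linking local and remote jitters;
            # jitters are truncated at 2.5 sd so bounded bases keep
            # fractions inside [0, MAX_FRACTION]
            link = float(design.local_remote_link_by_group.get(group, 0.0))
            u = rng.standard_normal()

            lam = np.zeros(n_patches)
            for pi, patch in enumerate(design.patches):
                base = (
                    patch.local_coupling_base
                    + patch.group_effect * is_pat
                    + patch.age_slope_by_group.get(group, 0.0) * age_c
                )
                if patch.subject_jitter_sd > 0:
                    jit = link * u + np.sqrt(max(0.0, 1 - link**2)) * rng.standard_normal()
                    base += patch.subject_jitter_sd * np.clip(jit, -2.5, 2.5)
                if not 0.0 <= base <= MAX_FRACTION:
                    raise ValueError(
                        f"subject {sid}: patch {pi} coupling fraction {base:.3f} "
                        f"outside [0, {MAX_FRACTION}]"
                    )
                lam[pi] = base

            phi = np.zeros(n_coup)
            for ci, c in enumerate(design.couplings):
                base = (
                    c.shared_signal_fraction_by_group[group]
                    + c.age_slope_by_group.get(group, 0.0) * age_c
                )
                if c.subject_jitter_sd > 0:
                    jit = link * u + np.sqrt(max(0.0, 1 - link**2)) * rng.standard_normal()
                    base += c.subject_jitter_sd * np.clip(jit, -2.5, 2.5)
                if not 0.0 <= base <= MAX_FRACTION:
                    raise ValueError(
                        f"subject {sid}: coupling {ci} fraction {base:.3f} "
                        f"outside [0, {MAX_FRACTION}]"
                    )
                phi[ci] = base

            # motion contamination fraction, monotone in drawn meanFD, plus
            # a subject-varying global-signal fraction independent of motion
            # (emulating ubiquitous whole-cortex BOLD fluctuations; without
            # it the global-mean nuisance covariate would be a pure motion
            # proxy and its non-motion variance degenerate)
            motion_scale = float(design.nuisance_model.get("motion_scale", 1.0))
            mu = float(np.clip(motion_scale * qc.meanFD, 0.0, 0.5))
            g_base = float(design.nuisance_model.get("global_signal_base", 0.08))
            g_sd = float(design.nuisance_model.get("global_signal_sd", 0.05))
            gamma = float(np.clip(g_base + g_sd * rng.standard_normal(), 0.0, 0.3))

            noise = _band_limited(rng, (V, T), window)
            shared = _band_limited(rng, (max(n_coup, 1), T), window)
            patch_noise = _band_limited(rng, (max(n_patches, 1), T), window)
            motion = _band_limited(rng, (T,), window)
            global_sig = _band_limited(rng, (T,), window)

            avail = 1.0 - mu - gamma
            X = np.sqrt(avail) * noise
            for pi, patch in enumerate(design.patches):
                ci = patch_of_coupling.get(pi)
                if ci is None:
                    latent = patch_noise[pi]
                else:
                    f = phi[ci]
                    latent = np.sqrt(f) * shared[ci] + np.sqrt(1 - f) * patch_noise[pi]
                lv = lam[pi]
                rows = patch.vertex_set
                X[rows] = np.sqrt(avail) * (
                    np.sqrt(1 - lv) * noise[rows] + np.sqrt(lv) * latent
                )
            X += np.sqrt(mu) * motion + np.sqrt(gamma) * global_sig
            X *= design.noise_sigma

            subjects.append(
                SubjectData(sid, group, age, sex, X, qc, pheno)
            )
            lam_all[s_index] = lam
            phi_all[s_index] = phi
            ids.append(sid)
            groups.append(group)
            s_index += 1

    truth = TruthRecord(
        patches=list(design.patches),
        couplings=list(design.couplings),
        subject_ids=ids,
        groups=groups,
        lambda_by_subject=lam_all,
        phi_by_subject=phi_all,
    )
    return subjects, truth


def generate_null_cohort(
    mesh: SurfaceMesh, n_subjects: int, n_timepoints: int, seed: int
) -> list[SubjectData]:
    """Pure-noise cohort (no planted effects); groups assigned alternately."""
    rng = np.random.default_rng(seed)
    window = max(1, int(round(1.0 / (2.0 * 0.1 * 2.0))))
    subjects = []
    for k in range(n_subjects):
        group = GROUPS[k % 2]  # control, patient, control, ...
        sid = f"null{k:03d}"
        X = _band_limited(rng, (mesh.n_vertices, n_timepoints), window)
        qc = _draw_qc(rng, sid)
        subjects.append(
            SubjectData(
                sid, group, float(rng.uniform(14, 30)), int(rng.random() < 0.5),
                X, qc, _draw_phenotype(rng, group),
            )
        )
    return subjects


# ---------------------------------------------------------------------------
# I/O: one functional GIFTI per subject + phenotype/QC CSV + truth JSON

def write_cohort(
    subjects: list[SubjectData],
    out_dir: str,
    truth: TruthRecord | None = None,
) -> None:
    import nibabel as nib
    from nibabel.gifti import GiftiDataArray, GiftiImage

    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for s in subjects:
        da = GiftiDataArray(
            s.vertex_time_matrix.astype(np.float32), intent="NIFTI_INTENT_TIME_SERIES"
        )
        nib.save(GiftiImage(darrays=[da]), os.path.join(out_dir, f"{s.subject_id}.func.gii"))
        rows.append(
            {
                "subject_id": s.subject_id, "group": s.group, "age": s.age,
                "sex": s.sex, "meanFD": s.qc.meanFD, "maxTran": s.qc.maxTran,
                "maxRot": s.qc.maxRot, "mcBBR": s.qc.mcBBR,
                "jacobian_mean": s.qc.jacobian_mean,
                "panss_positive": s.phenotype.panss_positive,
                "panss_negative": s.phenotype.panss_negative,
                "panss_general": s.phenotype.panss_general,
                "panss_supplementary": s.phenotype.panss_supplementary,
                "panss_total": s.phenotype.panss_total,
            }
        )
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "phenotype.csv"), index=False)
    if truth is not None:
        with open(os.path.join(out_dir, "truth.json"), "w") as fh:
            fh.write(truth.to_json())


def load_cohort(cohort_dir: str) -> list[SubjectData]:
    import nibabel as nib

    pheno = pd.read_csv(os.path.join(cohort_dir, "phenotype.csv"))
    subjects = []
    for _, row in pheno.iterrows():
        img = nib.load(os.path.join(cohort_dir, f"{row.subject_id}.func.gii"))
        X = np.asarray(img.darrays[0].data, dtype=np.float64)
        qc = SubjectQC(
            meanFD=row.meanFD, maxTran=row.maxTran, maxRot=row.maxRot,
            mcBBR=row.mcBBR, jacobian_mean=row.jacobian_mean,
            subject_id=str(row.subject_id),
        )
        pheno_obj = Phenotype(
            int(row.panss_positive), int(row.panss_negative),
            int(row.panss_general), int(row.panss_supplementary),
            int(row.panss_total), int(row.group == "patient"),
        )
        subjects.append(
            SubjectData(str(row.subject_id), str(row.group), float(row.age),
                        int(row.sex), X, qc, pheno_obj)
        )
    return subjects
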