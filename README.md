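# surfconn

Threshold-free, surface-based analysis of **local-to-remote functional
connectivity** in resting-state fMRI.

Graph-theoretic connectome analyses depend heavily on an arbitrary edge
threshold. `surfconn` implements the alternative: characterize *local*
connectivity vertex-by-vertex on the cortical surface, let the resulting
clusters seed *remote* (long-range) connectivity maps, and relate the two
with an across-subject covariance statistic. The pipeline targets group
studies (e.g. patients vs. controls with an age-by-diagnosis interaction)
on a shared mesh such as FreeSurfer's fsaverage5, and ships a synthetic
cohort generator with planted, recoverable effects so every stage is
testable end to end.

## The metrics

**2dReHo (local short-range connectivity).** For vertex *v* with time
series of its closed 1-ring neighborhood (K series, n timepoints), the
metric is Kendall's coefficient of concordance

    W = 12 S / (K² (n³ − n) − K T)

where S is the sum of squared deviations of per-timepoint rank sums and T
the tie-correction term. W ∈ [0, 1]; higher W means the vertex and its
~5–7 mesh neighbors fluctuate coherently. Maps are smoothed with a 10-mm
FWHM surface kernel (iterative 1-ring averaging, empirically calibrated
in mm).

**SFC (remote connectivity).** Each cluster that survives cluster-wise
correction in the local stage becomes a seed: its mean time series (from
6-mm-smoothed data) is correlated with every vertex, r is Fisher
z-transformed (z = atanh r), and the z map is smoothed at 10 mm.

**Group model.** Vertex-wise OLS with age, sex and diagnosis (optionally
age×diagnosis, age mean-centered), after group-level residualization of
the nuisance covariates meanFD, mcBBR, surface-Jacobian mean and the
modality's global mean. Significance is reported as signed log10 p and
corrected cluster-wise (cluster-defining P = 0.01, cluster-level
α = 0.05) by a Freedman–Lane max-cluster-extent permutation test, with a
2-D random-field-theory alternative cross-checked against it. Remote
stages with N seeds use α/N.

**Local–remote covariance.** Per group, Pearson r between a cluster's
mean 2dReHo and the mean Fisher z of its remote (e.g. homotopic)
counterpart, compared between groups with the Fisher z-test
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)).

**QC.** Power-style frame-wise displacement; scans are excluded iff
maxTran > 3 mm, maxRot > 3°, or meanFD > 0.35 mm (strict inequalities).

## Worked example

```python
import numpy as np
from surfconn.mesh import make_icosphere
from surfconn.synthetic_cohort import (SyntheticDesign, PlantedPatch,
    PlantedCoupling, ring_patch, antipodal_vertex, generate_cohort)
from surfconn.pipeline import PipelineConfig, run_full
from surfconn.cluster_inference import InferenceConfig

mesh = make_icosphere(3, 42.0)              # 642-vertex spherical cortex
pA = ring_patch(mesh, 0, 2)                 # 16-vertex planted patch
pB = ring_patch(mesh, antipodal_vertex(mesh, 0), 2)   # its mirror patch
design = SyntheticDesign(
    mesh=mesh, n_per_group=15, n_timepoints=120,
    patches=[PlantedPatch(pA, 0.3, group_effect=0.3), PlantedPatch(pB, 0.45)],
    couplings=[PlantedCoupling(0, 1, {"control": 0.6, "patient": 0.2})],
    seed=21)
subjects, truth = generate_cohort(design)
cfg = PipelineConfig(inference=InferenceConfig(n_permutations=199, seed=5))
report = run_full(subjects, mesh, cfg)
loc = report["local"]["clusters"]["diagnosis"][0]
print(loc["extent_vertices"], loc["corrected_p"])
print(report["remote"]["n_seeds"], report["remote"]["per_seed_alpha"])
```

prints

```
26 0.01
1 0.05
```

The patients' elevated local coupling at patch A is recovered as a
26-vertex positive cluster with permutation-corrected p = 0.01; that one
cluster seeds the remote stage (N = 1, so the per-seed level stays at
α = 0.05/1), where the reduced patient coupling shows up as a negative
cluster over patch B in `report["remote"]["seeds"][0]["clusters"]`.

A YAML-driven CLI wraps the same stages:

```bash
surfconn example-config --out cfg.yaml
surfconn simulate --config cfg.yaml
surfconn run --config cfg.yaml        # also: qc / local / remote / covariance / loo
```

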