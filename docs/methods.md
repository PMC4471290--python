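# Methods

This note documents the models, numerical choices and limitations behind
`surfconn`, in the order the pipeline runs them.

## Surface representation

All subjects share one triangulated mesh. "Nearest neighbors" of a
vertex are its 1-ring (edge-adjacent) vertices — the established choice
for surface ReHo on fsaverage-style grids, where the closed neighborhood
spans roughly 8 mm. Cluster connectivity likewise uses edge adjacency.
Vertex indices are 0-based; file readers (GIFTI, FreeSurfer binary
geometry, GIFTI/FreeSurfer labels) convert as needed. Vertices flagged
false in the cortex mask, vertices belonging to no triangle, and
vertices with constant or non-finite time series are excluded from every
statistic. Per-vertex areas are one-third of incident-triangle areas, a
standard barycentric approximation to Voronoi areas that is positive and
sums exactly to the mesh area.

Test meshes are subdivided icosahedra projected to a sphere
(10·4^L + 2 vertices at level L; level 5 matches the 10,242 vertices of
one fsaverage5 hemisphere). The default study mesh is level 3 at radius
42 mm: 642 vertices with ~6.3 mm mean edge length, chosen so that the
10-mm smoothing kernel spans a realistic one-to-two rings, as it does on
fsaverage5, while keeping simulation ensembles cheap.

## 2dReHo

Kendall's W over the closed 1-ring, with tie correction (W ≤ 1 holds
exactly on quantized data) and per-vertex K bookkeeping (5 at the 12
icosahedral pentagons, 7 typically). Whether the original surface-ReHo
implementations used tie correction is not documentable; it is recorded
here as this package's default, not an inference about other code.
Constant-series vertices are masked rather than errored at map level
(medial-wall projection artifacts are expected); usable neighborhoods
smaller than K = 3 are masked. The vectorized map (ranks computed once,
rank sums accumulated through the sparse adjacency) is tested to equal
the per-vertex definition exactly. Global means are unweighted over
unmasked vertices by default; area weighting and including-all-vertices
variants are flags, since published descriptions of "averaged across all
vertices" do not resolve the medial-wall question.

## Smoothing

Iterative equal-weight closed-1-ring averaging (FreeSurfer-style),
mask-aware, linear, and bounded by the max principle; exact mean
conservation is not promised on irregular meshes. The mm-FWHM contract
is empirical: a requested FWHM is converted to an iteration count by a
diffusion-scaling starting guess refined against the measured impulse
response (second moment of the response vs. Euclidean distance,
E[d²] = 2σ², FWHM = √(8 ln 2) σ). The naive guess
FWHM²/(4 ln 2 · h²) underestimates substantially — the discrete operator
spreads only ~0.72 h² per pass — which is why the calibration is
measured, not assumed; the realized FWHM is tested to land within 15% of
the request on a level-4 icosphere. On very coarse meshes the iteration
granularity limits how closely a target can be met (on the 642-vertex
mesh a 10-mm request realizes ~11.4 mm); the acceptance script reports
the realized value.

## Synthetic cohorts

The generator emulates *post-preprocessing* surface rfMRI, not raw EPI:
no hemodynamics, drift, or acquisition differences. Per subject:

- **Baseline noise**: i.i.d. Gaussian per vertex, moving-average
  filtered along time (window ≈ 1/(2·0.1 Hz·TR) samples, i.e. the upper
  edge of the 0.01–0.1 Hz band at TR = 2 s) and variance-normalized.
  Moving-average filtering stands in for explicit Fourier filtering;
  adequate for a rank-based statistic.
- **Planted patches**: disjoint vertex sets whose members mix a shared
  patch latent at variance fraction λ = base + group effect (patients)
  + per-year age slope + subject jitter (jitters truncated at ±2.5 sd so
  bounded bases keep fractions in [0, 0.95]). Within-patch pairwise
  correlation ≈ λ, so true 2dReHo is monotone in λ — recovery tests need
  no closed-form inversion.
- **Planted couplings**: two patches' latents share a common signal at
  fraction φ (each patch participates in at most one coupling), making
  patch-to-patch connectivity monotone in φ. Homotopic pairs use the
  antipodal vertex as the mirror center.
- **Nuisance structure**: a global motion component mixed at fraction
  μ = meanFD (clipped at 0.5), with meanFD drawn near 0.15 ± 0.09 mm as
  in typical adolescent cohorts, plus a subject-varying global-signal
  fraction (0.08 ± 0.05, independent of motion) emulating whole-cortex
  BOLD fluctuations. The latter matters: without it the global-mean
  covariate is a pure motion proxy whose residual variance after meanFD
  regression is dominated by the planted patches themselves, and
  nuisance regression then removes planted signal — a degenerate world
  no real dataset resembles.
- **Covariance links**: an optional per-group correlation between the
  local (λ) and remote (φ) subject jitters; setting it to 1 in controls
  and 0 in patients plants the "covariance present in controls, absent
  in patients" structure.
- **Phenotypes/QC**: ages uniform per group, PANSS subscales within
  instrument ranges (total = positive + negative + general), mcBBR and
  Jacobian summaries drawn in realistic bands. Cosmetic, not fit to any
  dataset.

Everything is deterministic given the design seed; cohorts round-trip
through per-subject GIFTI time-series files plus a phenotype/QC CSV and
a truth JSON.

What passing recovery tests therefore shows: the pipeline detects
variance-fraction effects of the planted kind under motion and global
confounds at realistic sample sizes. What they do not show: robustness
to spatially structured artifacts, inter-subject misalignment, or
non-Gaussian physiology, none of which the generator produces.

## Group GLM

Two-stage estimation follows the described order of operations: scalar
nuisances (meanFD, mcBBR, Jacobian mean, global mean of the modeled
metric — global SFC replaces the Jacobian in the remote stage) are
regressed out of the maps at the group level; the interest model
(intercept, age, sex 0/1, diagnosis 0 = control / 1 = patient, optional
age×diagnosis with age mean-centered before the product) is then fit per
vertex by OLS. Two-stage and joint fits coincide only when interest and
nuisance columns are orthogonal; this equivalence and its failure are
tested rather than assumed. The exact parameterization of the original
model is not recoverable, so coding and centering choices are flagged
defaults. Two-tailed t tests throughout; signed log10 p carries the sign
of t.

A known cost of the global-mean covariate, reproduced faithfully here:
a focal positive effect depresses the residualized background
everywhere, so diffuse opposite-signed background clusters can reach
significance far from a strong planted effect. Recovery tests therefore
score sign correctness at clusters overlapping the planted patch.

## Cluster inference

Clusters form from vertices with two-tailed p strictly below the
cluster-defining threshold (default 0.01), separately per sign, via
edge-connected components. Two engines share that formation step:

- **Permutation (default)**: Freedman–Lane — residualize under the
  reduced model, permute residual rows, refit the full model, take the
  max supra-threshold cluster area over both signs; corrected
  p = (1 + #{null ≥ observed})/(1 + B). Valid by construction under
  exchangeability, hence the default; its family-wise error is verified
  on 200 null cohorts.
- **RFT**: residual smoothness from along-edge correlations of
  per-vertex-standardized residuals (2(1 − ρ) ≈ h²/(2σ²), FWHM =
  √(8 ln 2) σ, resels = masked area/FWHM²), the t threshold Gaussianized
  via its p-value, expected cluster count from the 2-D EC density
  ρ₂(u) = (4 ln 2)(2π)^{-3/2} u e^{-u²/2}, exponential cluster-extent
  law, and a factor 2 for the two signs. Gaussianization and this resel
  estimator are documented defaults, since the original RFT details are
  unspecified. The smoothness estimator runs ~10–20% high on
  iteratively smoothed fields; RFT p-values are tested to agree with
  permutation within a factor of 2 for clusters in the p ∈ [0.01, 0.2]
  band, and discrepancies beyond that band are expected at the extremes.

Multi-seed remote analyses Bonferroni-correct the cluster alpha to
α/N, N = the number of seed clusters actually carried into the remote
stage of the current run.

## Remote stage and covariance

Seed mean series come from 6-mm-smoothed data and are correlated against
the same smoothed data (the literal reading of the source description);
r is clamped to ±(1 − 1e-7) before atanh; z maps are smoothed at 10 mm.
Seed vertices stay in the maps but are flagged, and the global mean SFC
includes them by default (flag to exclude — the published choice is
unstated).

The local–remote covariance uses *nuisance-residualized* cluster means.
This is a deliberate design choice: the motion and global-signal
components are shared between a subject's ReHo and SFC maps, so raw
cluster means correlate strongly in every group through head motion
alone (empirically r ≈ 0.97 on motion-only cohorts), which would mask
any group difference in the biological coupling. Symptom correlations
(every configured cluster-metric × PANSS-subscale pair, patients only)
are reported uncorrected and labelled exploratory; no pair is omitted.

## Leave-one-out reproducibility

The local stage is repeated dropping one subject at a time; each
vertex's detection frequency is the fraction of repetitions in which it
belongs to a significant cluster, summarized per full-sample cluster by
its minimum and median frequency.

## Problem sizes and determinism

Standard desk-scale conditions, chosen once: level-3 icosphere (642
vertices), 20–50 subjects, 100–240 timepoints (240 for the covariance
designs — an 8-minute scan at TR = 2 s, reflecting that across-subject
correlation estimates are the noise-limited quantity), 199 permutations
for recovery ensembles and 499 where p-resolution in [0.01, 0.2]
matters. Every stage is deterministic given (config, seed); the same
seed reproduces cohorts bit-identically.

## Known limitations

- The spherical test mesh has no real cortical geometry, curvature
  inhomogeneity or medial wall; mask-aware paths are tested with
  synthetic masks instead.
- On meshes where planted patches are a non-trivial fraction of the
  surface, the global-mean covariate partially absorbs strong focal
  effects (and induces the opposite-signed background bias noted above);
  with fsaverage5-scale vertex counts the absorption is negligible, but
  the bias mechanism is inherent to global-mean regression.
- RFT here assumes stationary smoothness; nonstationary cluster
  correction and TFCE are out of scope.
- The Fisher z-test for comparing correlations assumes bivariate
  normality within groups; with the generator's Gaussian latents this
  holds by construction.
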