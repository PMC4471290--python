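"""Cluster formation, smoothness estimation, RFT and permutation inference."""

import numpy as np
import pytest

from surfconn.cluster_inference import (
    Cluster,
    InferenceConfig,
    SmoothnessEstimate,
    correct_across_seeds,
    estimate_smoothness,
    form_clusters,
    permutation_cluster_p,
    rft_cluster_p,
)
from surfconn.glm import GlmResult, make_design
from surfconn.mesh import average_edge_length, make_icosphere
from surfconn.smooth import SmoothingSpec, smooth_map
from surfconn.synthetic_cohort import ring_patch


def _fake_result(mesh, t_map, p_map):
    t_map = np.asarray(t_map, float)
    p_map = np.asarray(p_map, float)
    with np.errstate(divide="ignore"):
        slp = np.sign(t_map) * (-np.log10(np.clip(p_map, 1e-300, 1.0)))
    return GlmResult(
        contrast="diagnosis", beta=t_map.copy(), t=t_map, p=p_map,
        signed_log10_p=slp, residuals=np.zeros((4, mesh.n_vertices)),
        df=10, mask=np.ones(mesh.n_vertices, bool),
    )


class TestFormClusters:
    def test_no_suprathreshold_vertices(self, ico2):
        res = _fake_result(ico2, np.ones(ico2.n_vertices), np.full(ico2.n_vertices, 0.5))
        assert form_clusters(res, ico2, InferenceConfig()) == []

    def test_two_patches_opposite_signs(self, ico3):
        pA = ring_patch(ico3, 0, 1)
        pB = ring_patch(ico3, 300, 1)
        t = np.zeros(ico3.n_vertices)
        p = np.full(ico3.n_vertices, 0.9)
        t[pA], p[pA] = 4.0, 0.001
        t[pB], p[pB] = -4.0, 0.001
        clusters = form_clusters(_fake_result(ico3, t, p), ico3, InferenceConfig())
        assert len(clusters) == 2
        by_sign = {c.sign: set(c.vertices.tolist()) for c in clusters}
        assert by_sign[+1] == set(pA.tolist())
        assert by_sign[-1] == set(pB.tolist())

    def test_boundary_p_excluded_strictly(self, ico2):
        t = np.ones(ico2.n_vertices)
        p = np.full(ico2.n_vertices, 0.5)
        patch = ring_patch(ico2, 0, 1)
        p[patch] = 0.01  # exactly the threshold: must not cluster
        cfg = InferenceConfig(cluster_defining_p=0.01)
        assert form_clusters(_fake_result(ico2, t, p), ico2, cfg) == []

    def test_extent_area_matches_vertex_areas(self, ico3):
        patch = ring_patch(ico3, 5, 1)
        t = np.zeros(ico3.n_vertices)
        p = np.ones(ico3.n_vertices)
        t[patch], p[patch] = 3.0, 1e-4
        (cl,) = form_clusters(_fake_result(ico3, t, p), ico3, InferenceConfig())
        assert cl.extent_area_mm2 == pytest.approx(ico3.vertex_areas[patch].sum())
        assert cl.extent_vertices == patch.size


class TestSmoothness:
    def test_white_noise_estimates_edge_scale(self, ico3, rng):
        R = rng.normal(size=(20, ico3.n_vertices))
        est = estimate_smoothness(R, ico3)
        h = average_edge_length(ico3)
        assert 0.7 * h < est.fwhm_mm < 1.5 * h
        assert est.resels > 0

    def test_presmoothed_field_recovered(self):
        mesh = make_icosphere(4, 42.0)
        rng = np.random.default_rng(3)
        from surfconn.smooth import fwhm_to_iterations

        spec = SmoothingSpec(10.0, fwhm_to_iterations(10.0, mesh))
        R = np.stack([
            smooth_map(rng.normal(size=mesh.n_vertices), mesh, spec) for _ in range(12)
        ])
        est = estimate_smoothness(R, mesh)
        assert 7.0 <= est.fwhm_mm <= 13.0

    def test_scale_invariance(self, ico3, rng):
        R = rng.normal(size=(10, ico3.n_vertices))
        a = estimate_smoothness(R, ico3)
        b = estimate_smoothness(42.0 * R, ico3)
        assert a.fwhm_mm == pytest.approx(b.fwhm_mm, rel=1e-12)

    def test_zero_variance_rejected(self, ico2):
        with pytest.raises(ValueError):
            estimate_smoothness(np.zeros((5, ico2.n_vertices)), ico2)


class TestRftClusterP:
    def _cluster(self, area):
        return Cluster(
            vertices=np.arange(3), sign=1, extent_vertices=3,
            extent_area_mm2=area, peak_vertex=0, peak_signed_log10_p=3.0,
        )

    def test_monotone_in_extent(self):
        sm = SmoothnessEstimate(fwhm_mm=10.0, resels=200.0)
        cfg = InferenceConfig()
        ps = [rft_cluster_p(self._cluster(a), sm, cfg) for a in (1, 50, 200, 800)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_zero_extent_limit_is_any_cluster_probability(self):
        sm = SmoothnessEstimate(fwhm_mm=10.0, resels=200.0)
        cfg = InferenceConfig()
        p0 = rft_cluster_p(self._cluster(0.0), sm, cfg)
        assert 0 < p0 <= 1.0
        # limit equals P(at least one cluster anywhere)
        assert rft_cluster_p(self._cluster(1e-9), sm, cfg) == pytest.approx(p0, rel=1e-6)

    def test_probability_range_fuzz(self, rng):
        cfg = InferenceConfig()
        for _ in range(100):
            sm = SmoothnessEstimate(
                fwhm_mm=float(rng.uniform(2, 20)), resels=float(rng.uniform(10, 2000))
            )
            p = rft_cluster_p(self._cluster(float(rng.uniform(0, 500))), sm, cfg)
            assert 0 < p <= 1.0


class TestPermutation:
    def _planted_stack(self, mesh, seed, effect=1.0):
        rng = np.random.default_rng(seed)
        import pandas as pd

        n = 24
        pheno = pd.DataFrame(
            {
                "group": ["control"] * 12 + ["patient"] * 12,
                "age": rng.uniform(14, 30, n),
                "sex": rng.integers(0, 2, n),
            }
        )
        design = make_design(pheno)
        patch = ring_patch(mesh, 0, 2)
        dx = (pheno["group"] == "patient").to_numpy(float)
        Y = rng.normal(size=(n, mesh.n_vertices))
        Y[:, patch] += effect * dx[:, None]
        return Y, design, patch

    def test_determinism_same_seed(self, ico2):
        Y, design, _ = self._planted_stack(ico2, 7)
        cfg = InferenceConfig(n_permutations=120, seed=9)
        _, null_a = permutation_cluster_p(Y, design, "diagnosis", ico2, cfg)
        _, null_b = permutation_cluster_p(Y, design, "diagnosis", ico2, cfg)
        assert np.array_equal(null_a, null_b)

    def test_strong_effect_attains_p_floor(self, ico2):
        Y, design, patch = self._planted_stack(ico2, 3, effect=3.0)
        cfg = InferenceConfig(n_permutations=120, seed=1)
        clusters, _ = permutation_cluster_p(Y, design, "diagnosis", ico2, cfg)
        best = min(c.corrected_p for c in clusters)
        assert best == pytest.approx(1.0 / 121.0)
        top = max(clusters, key=lambda c: c.extent_vertices)
        assert set(patch.tolist()) <= set(top.vertices.tolist())

    def test_memberships_shared_with_rft_route(self, ico2):
        # both engines cluster through form_clusters: identical extents
        from surfconn.glm import fit_vertex_glm

        Y, design, _ = self._planted_stack(ico2, 11, effect=1.5)
        cfg = InferenceConfig(n_permutations=120, seed=2)
        perm_clusters, _ = permutation_cluster_p(Y, design, "diagnosis", ico2, cfg)
        res = fit_vertex_glm(Y, design, "diagnosis")
        direct = form_clusters(res, ico2, cfg)
        assert [c.extent_vertices for c in perm_clusters] == [
            c.extent_vertices for c in direct
        ]
        for a, b in zip(perm_clusters, direct):
            assert np.array_equal(a.vertices, b.vertices)

    def test_too_few_subjects_rejected(self, ico2, rng):
        import pandas as pd

        pheno = pd.DataFrame(
            {"group": ["control", "patient"] * 3, "age": rng.uniform(14, 30, 6),
             "sex": [0, 0, 1, 0, 1, 1]}
        )
        design = make_design(pheno)
        with pytest.raises(ValueError):
            permutation_cluster_p(
                rng.normal(size=(6, ico2.n_vertices)), design, "diagnosis",
                ico2, InferenceConfig(n_permutations=100),
            )


class TestSeedCorrection:
    @pytest.mark.parametrize("N,expected", [(1, 0.05), (2, 0.025), (5, 0.01)])
    def test_alpha_over_n(self, N, expected):
        assert correct_across_seeds(0.05, N) == pytest.approx(expected)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            correct_across_seeds(0.05, 0)


class TestConfigValidation:
    def test_bad_values_rejected(self):
        with pytest.raises(ValueError):
            InferenceConfig(cluster_defining_p=0.0)
        with pytest.raises(ValueError):
            InferenceConfig(method="bayes")
        with pytest.raises(ValueError):
            InferenceConfig(n_permutations=50)
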