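"""Group-level GLM: residualization, vertex-wise fits, interactions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from surfconn.glm import (
    DesignMatrix,
    fit_vertex_glm,
    group_slope,
    interaction_glm,
    make_design,
    residualize,
)


def _pheno(n_per_group, rng, age_lo=14, age_hi=30):
    n = 2 * n_per_group
    return pd.DataFrame(
        {
            "group": ["control"] * n_per_group + ["patient"] * n_per_group,
            "age": rng.uniform(age_lo, age_hi, n),
            "sex": rng.integers(0, 2, n),
        }
    )


class TestResidualize:
    def test_linear_combination_gives_zero(self, rng):
        Z = np.column_stack([np.ones(20), rng.normal(size=(20, 2))])
        y = Z @ np.array([1.0, -2.0, 0.5])
        assert np.allclose(residualize(y, Z), 0.0, atol=1e-10)

    def test_orthogonal_values_unchanged_up_to_intercept(self, rng):
        Z = np.column_stack([np.ones(16), rng.normal(size=16)])
        y = rng.normal(size=16)
        y_orth = residualize(y, Z)  # now orthogonal to Z
        again = residualize(y_orth, Z)
        assert np.allclose(again, y_orth, atol=1e-10)

    def test_residuals_orthogonal_to_nuisance(self, rng):
        Z = np.column_stack([np.ones(30), rng.normal(size=(30, 3))])
        Y = rng.normal(size=(30, 5))
        R = residualize(Y, Z)
        assert np.abs(Z.T @ R).max() < 1e-8

    def test_missing_intercept_rejected(self, rng):
        with pytest.raises(ValueError, match="intercept"):
            residualize(rng.normal(size=10), rng.normal(size=(10, 2)))

    def test_rank_deficiency_rejected(self, rng):
        x = rng.normal(size=12)
        Z = np.column_stack([np.ones(12), x, 2 * x])
        with pytest.raises(ValueError, match="rank"):
            residualize(rng.normal(size=12), Z)


class TestFitVertexGlm:
    def test_matches_statsmodels(self, rng):
        # statsmodels OLS as the independent oracle
        import statsmodels.api as sm

        pheno = _pheno(12, rng)
        design = make_design(pheno)
        Y = rng.normal(size=(24, 6))
        res = fit_vertex_glm(Y, design, "diagnosis")
        c = design.column_index("diagnosis")
        for v in range(6):
            fit = sm.OLS(Y[:, v], design.X).fit()
            assert res.beta[v] == pytest.approx(fit.params[c], abs=1e-10)
            assert res.t[v] == pytest.approx(fit.tvalues[c], abs=1e-8)
            assert res.p[v] == pytest.approx(fit.pvalues[c], abs=1e-10)

    def test_location_invariance_of_diagnosis_t(self, rng):
        pheno = _pheno(10, rng)
        design = make_design(pheno)
        Y = rng.normal(size=(20, 4))
        t0 = fit_vertex_glm(Y, design, "diagnosis").t
        t1 = fit_vertex_glm(Y + 7.3, design, "diagnosis").t
        assert np.allclose(t0, t1, atol=1e-10)

    def test_planted_effect_beta_recovery(self):
        # group effect +delta at half the vertices; mean recovered beta
        # within 15% of delta across instances
        delta = 0.5
        betas = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pheno = _pheno(20, rng)
            design = make_design(pheno)
            dx = (pheno["group"] == "patient").to_numpy(float)
            Y = rng.normal(size=(40, 10), scale=0.5)
            Y[:, :5] += np.outer(dx, np.full(5, delta))
            res = fit_vertex_glm(Y, design, "diagnosis")
            betas.append(res.beta[:5].mean())
        assert abs(np.mean(betas) - delta) / delta < 0.15

    def test_signed_log10_p_consistent(self, rng):
        pheno = _pheno(10, rng)
        design = make_design(pheno)
        res = fit_vertex_glm(rng.normal(size=(20, 8)), design, "diagnosis")
        back = 10.0 ** (-np.abs(res.signed_log10_p))
        assert np.allclose(back, res.p, atol=1e-10)
        assert np.all(np.sign(res.signed_log10_p) == np.sign(res.t))

    def test_df_and_masking(self, rng):
        pheno = _pheno(8, rng)
        design = make_design(pheno)
        Y = rng.normal(size=(16, 3))
        Y[2, 1] = np.nan
        res = fit_vertex_glm(Y, design, "diagnosis")
        assert res.df == 16 - 4
        assert not res.mask[1] and np.isnan(res.t[1])
        assert res.mask[0] and res.mask[2]

    def test_too_few_subjects_rejected(self, rng):
        pheno = _pheno(2, rng)
        design = make_design(pheno)
        with pytest.raises(ValueError):
            fit_vertex_glm(rng.normal(size=(4, 2)), design, "diagnosis")


class TestInteraction:
    def test_centering_changes_main_effect_not_interaction_t(self, rng):
        pheno = _pheno(15, rng)
        Y = rng.normal(size=(30, 5))
        d_cent = make_design(pheno, interaction=True, center_age=True)
        d_raw = make_design(pheno, interaction=True, center_age=False)
        t_cent = interaction_glm(Y, d_cent).t
        t_raw = interaction_glm(Y, d_raw).t
        assert np.allclose(t_cent, t_raw, atol=1e-8)
        # shifting the age column reparameterizes the intercept
        b_cent = fit_vertex_glm(Y, d_cent, "intercept").beta
        b_raw = fit_vertex_glm(Y, d_raw, "intercept").beta
        assert not np.allclose(b_cent, b_raw)

    def test_null_interaction_t_follows_student(self):
        # equal age slopes in both groups: interaction t ~ t(df)
        tvals = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            pheno = _pheno(15, rng)
            age = pheno["age"].to_numpy()
            Y = 0.02 * age[:, None] + rng.normal(size=(30, 20), scale=0.3)
            design = make_design(pheno, interaction=True)
            tvals.append(interaction_glm(Y, design).t)
        tvals = np.concatenate(tvals)
        df = 30 - 5
        ks = stats.kstest(tvals, stats.t(df).cdf)
        assert ks.pvalue > 0.01

    def test_planted_patient_decline_detected(self):
        # patients decline with age, controls flat -> negative interaction t
        hits = 0
        n_rep = 25
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            pheno = _pheno(25, rng)
            age_c = pheno["age"].to_numpy() - pheno["age"].mean()
            dx = (pheno["group"] == "patient").to_numpy(float)
            Y = (-0.03 * age_c * dx)[:, None] + rng.normal(size=(50, 1), scale=0.2)
            design = make_design(pheno, interaction=True)
            hits += interaction_glm(Y, design).t[0] < 0
        assert hits >= 0.9 * n_rep


class TestGroupSlope:
    def test_perfect_line(self):
        ages = np.array([10.0, 12, 14, 16, 18])
        slope, p = group_slope(2.0 * ages + 1.0, ages)
        assert slope == pytest.approx(2.0)
        assert p < 1e-6

    def test_closed_form_slope(self, rng):
        x = rng.uniform(10, 30, 15)
        y = rng.normal(size=15)
        slope, _ = group_slope(y, x)
        assert slope == pytest.approx(np.cov(x, y, bias=True)[0, 1] / np.var(x))

    def test_permutation_invariance(self, rng):
        x = rng.uniform(10, 30, 12)
        y = rng.normal(size=12)
        perm = rng.permutation(12)
        s0, p0 = group_slope(y, x)
        s1, p1 = group_slope(y[perm], x[perm])
        assert s0 == pytest.approx(s1, abs=1e-12) and p0 == pytest.approx(p1, abs=1e-12)

    def test_constant_ages_rejected(self):
        with pytest.raises(ValueError):
            group_slope(np.arange(5.0), np.full(5, 20.0))


class TestDesignMatrix:
    def test_rank_deficient_rejected(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(ValueError):
            DesignMatrix(X, ["a", "b"])

    def test_sex_string_coding(self, rng):
        pheno = _pheno(5, rng)
        pheno["sex"] = ["M", "F"] * 5
        d = make_design(pheno)
        assert set(d.X[:, d.column_index("sex")]) == {0.0, 1.0}
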