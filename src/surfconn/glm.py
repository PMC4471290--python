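"""Group-level vertex-wise general linear models.

The group analysis follows a two-stage scheme: scalar nuisance covariates
(head motion, registration cost, surface Jacobian, global mean of the
modeled metric) are first regressed out of the per-subject maps at the
group level, and the residualized maps are then tested with an OLS model
whose covariates of interest are age, sex and diagnosis, optionally with
an age x diagnosis interaction (age mean-centered before the product is
formed).  The two-stage result coincides with a joint fit when interest
and nuisance columns are orthogonal; the general discrepancy is a tested,
documented property rather than a hidden assumption.

Vertex-wise significance is summarized as signed log10-transformed
p-values, sign(t) * (-log10 p).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DesignMatrix",
    "GlmResult",
    "make_design",
    "residualize",
    "fit_vertex_glm",
    "interaction_glm",
    "group_slope",
]


@dataclass
class DesignMatrix:
    """Named-column subject x covariate matrix (full column rank required)."""

    X: np.ndarray
    columns: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise ValueError("X shape does not match column names")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    def column_index(self, name: str) -> int:
        return self.columns.index(name)


@dataclass
class GlmResult:
    """Per-vertex OLS results for one contrast column."""

    contrast: str
    beta: np.ndarray
    t: np.ndarray
    p: np.ndarray
    signed_log10_p: np.ndarray
    residuals: np.ndarray  # (n_subjects, V), NaN at masked vertices
    df: int
    mask: np.ndarray  # True where the vertex was analyzed


def make_design(
    phenotype: pd.DataFrame,
    interaction: bool = False,
    center_age: bool = True,
    patient_label: str = "patient",
) -> DesignMatrix:
    """Build the interest design: intercept, age, sex, diagnosis [, age x dx].

    ``phenotype`` needs columns ``age`` (years), ``sex`` (coded or
    'M'/'F'), ``group``.  Diagnosis is coded 0 = control, 1 = patient; sex
    is coded 0/1; age is mean-centered when requested (always centered
    before forming the interaction product).
    """
    age = phenotype["age"].to_numpy(dtype=np.float64)
    age_c = age - age.mean() if center_age else age
    sex_raw = phenotype["sex"]
    if sex_raw.dtype == object:
        sex = (sex_raw.astype(str).str.upper().str.startswith("M")).astype(float)
    else:
        sex = sex_raw.to_numpy(dtype=np.float64)
    dx = (phenotype["group"].astype(str) == patient_label).astype(float).to_numpy()
    cols = [np.ones_like(age), age_c, sex, dx]
    names = ["intercept", "age", "sex", "diagnosis"]
    if interaction:
        age_for_product = age - age.mean()  # centered regardless
        cols.append(age_for_product * dx)
        names.append("age_x_diagnosis")
    return DesignMatrix(np.column_stack(cols), names)


def residualize(values: np.ndarray, nuisance: np.ndarray) -> np.ndarray:
    """OLS residuals of ``values`` on a nuisance matrix (intercept required).

    ``values`` may be a vector (n,) or a stack (n, V); NaN columns pass
    through as NaN.
    """
    Z = np.asarray(nuisance, dtype=np.float64)
    if Z.ndim != 2:
        raise ValueError("nuisance must be 2-D")
    if not np.any(np.all(Z == Z[0:1], axis=0) & (Z[0] != 0)):
        # no constant column found
        raise ValueError("nuisance matrix must include an intercept column")
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("nuisance matrix is rank deficient")
    y = np.asarray(values, dtype=np.float64)
    squeeze = y.ndim == 1
    Y = y[:, None] if squeeze else y.copy()
    good = np.isfinite(Y).all(axis=0)
    R = np.full_like(Y, np.nan)
    if good.any():
        coef, *_ = np.linalg.lstsq(Z, Y[:, good], rcond=None)
        R[:, good] = Y[:, good] - Z @ coef
    return R[:, 0] if squeeze else R


def fit_vertex_glm(
    maps: np.ndarray, design: DesignMatrix, contrast: str
) -> GlmResult:
    """Vertex-wise OLS fit and t-test for one named design column.

    ``maps`` is (n_subjects, V); vertices that are NaN for any subject are
    masked in the output.  t = beta / SE(beta) with error df
    n_subjects - n_columns; two-tailed p from Student's t.
    """
    Y = np.asarray(maps, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = design.X
    n, p_cols = X.shape
    if Y.shape[0] != n:
        raise ValueError("maps rows must match design rows")
    df = n - p_cols
    if df < 2:
        raise ValueError("fewer than 2 error degrees of freedom")
    c = design.column_index(contrast)
    good = np.isfinite(Y).all(axis=0)
    V = Y.shape[1]
    beta = np.full(V, np.nan)
    t = np.full(V, np.nan)
    p = np.full(V, np.nan)
    resid = np.full((n, V), np.nan)
    if good.any():
        XtX_inv = np.linalg.inv(X.T @ X)
        pinv = XtX_inv @ X.T
        B = pinv @ Y[:, good]  # (p_cols, Vg)
        R = Y[:, good] - X @ B
        sigma2 = np.sum(R**2, axis=0) / df
        se = np.sqrt(np.maximum(sigma2 * XtX_inv[c, c], 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tg = np.where(se > 0, B[c] / se, 0.0)
        beta[good] = B[c]
        t[good] = tg
        p[good] = 2.0 * stats.t.sf(np.abs(tg), df)
        resid[:, good] = R
    p_clipped = np.clip(p, np.finfo(float).tiny, 1.0)
    with np.errstate(invalid="ignore"):
        slp = np.sign(t) * (-np.log10(p_clipped))
    return GlmResult(
        contrast=contrast,
        beta=beta,
        t=t,
        p=p,
        signed_log10_p=slp,
        residuals=resid,
        df=df,
        mask=good,
    )


def interaction_glm(maps: np.ndarray, design: DesignMatrix) -> GlmResult:
    """Fit with the age x diagnosis product column as the contrast."""
    if "age_x_diagnosis" not in design.columns:
        raise ValueError("design has no age_x_diagnosis column")
    return fit_vertex_glm(maps, design, "age_x_diagnosis")


def group_slope(values: np.ndarray, ages: np.ndarray) -> tuple[float, float]:
    """Within-group simple regression of a cluster-mean metric on age.

    Returns (slope per year, two-tailed p).
    """
    values = np.asarray(values, dtype=np.float64)
    ages = np.asarray(ages, dtype=np.float64)
    if values.size != ages.size or values.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(ages) == 0:
        raise ValueError("constant ages")
    res = stats.linregress(ages, values)
    return float(res.slope), float(res.pvalue)
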