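"""Beta-regression differential abundance of deconvoluted proportions.

Each cell type's proportion is regressed on case status adjusted for
gestational age, fetal sex, and study source under a Beta likelihood with a
logit mean link and constant precision. The exponentiated case coefficient
is reported as a prevalence odds ratio (POR) with a Wald 95% CI and a
two-tailed Wald p-value at a nominal 0.05 threshold (no multiplicity
correction across cell types). Proportions of exactly 0 are transformed to
(1/2)/n before fitting, and proportions of exactly 1 symmetrically to
1 - (1/2)/n; cell types at zero abundance in every sample are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.othermod.betareg import BetaModel

from .containers import validate_sample_meta
from .deconv import ProportionEstimates


def transform_zeros(p: np.ndarray | pd.Series, n: int) -> np.ndarray | pd.Series:
    """Map boundary proportions into (0, 1): 0 -> (1/2)/n, 1 -> 1 - (1/2)/n."""
    if n <= 0:
        raise ValueError("n must be a positive sample count")
    arr = np.asarray(p, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("proportions must lie in [0, 1]")
    eps = 0.5 / n
    out = np.where(arr == 0.0, eps, np.where(arr == 1.0, 1.0 - eps, arr))
    if isinstance(p, pd.Series):
        return pd.Series(out, index=p.index, name=p.name)
    return out


@dataclass
class BetaRegressionFit:
    params: pd.Series  # mean-model coefficients (logit link)
    bse: pd.Series
    llf: float
    converged: bool
    precision: float  # fitted constant precision phi


def fit_beta_regression(y: np.ndarray | pd.Series, X: pd.DataFrame) -> BetaRegressionFit:
    """Maximum likelihood Beta regression with logit mean link.

    y ~ Beta(mu * phi, (1 - mu) * phi) with logit(mu) = X beta and constant
    log-precision. Raises on boundary y values, rank-deficient designs, or
    non-convergence.
    """
    y = np.asarray(y, dtype=float)
    if ((y <= 0) | (y >= 1)).any():
        raise ValueError("y must lie strictly in (0, 1); apply transform_zeros first")
    Xv = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise ValueError("design matrix is rank deficient")
    model = BetaModel(y, Xv)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", False):
            res = model.fit(method="bfgs", disp=0, maxiter=500)
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError(f"beta regression failed to converge: {res.mle_retvals}")
    names = list(X.columns) if hasattr(X, "columns") else [f"x{i}" for i in range(Xv.shape[1])]
    k = len(names)
    return BetaRegressionFit(
        params=pd.Series(res.params[:k], index=names),
        bse=pd.Series(res.bse[:k], index=names),
        llf=float(res.llf),
        converged=True,
        precision=float(np.exp(res.params[k])),
    )


def build_design(meta: pd.DataFrame) -> pd.DataFrame:
    """Design: intercept + case + gestational_age + fetal_sex + study dummies."""
    validate_sample_meta(meta)
    X = pd.DataFrame(index=meta.index)
    X["intercept"] = 1.0
    X["case"] = meta["case"].astype(float)
    X["gestational_age"] = meta["gestational_age"].astype(float)
    X["fetal_sex_male"] = (meta["fetal_sex"] == "male").astype(float)
    studies = sorted(meta["study"].unique())
    for s in studies[1:]:  # first level is the reference
        X[f"study_{s}"] = (meta["study"] == s).astype(float)
    return X


def differential_abundance_all(
    props: ProportionEstimates | pd.DataFrame, meta: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Fit one beta regression per cell type and report PORs.

    Cell types at zero abundance across all samples are excluded (counted in
    the report); the remaining types are zero-transformed with n = number of
    samples and fit with case + gestational_age + fetal_sex + study.
    """
    p = props.proportions if isinstance(props, ProportionEstimates) else props
    if not p.index.equals(meta.index):
        if set(p.index) != set(meta.index):
            raise ValueError("samples differ between proportions and metadata")
        meta = meta.loc[p.index]
    X = build_design(meta)
    n = len(p)

    all_zero = (p == 0).all(axis=0)
    dropped = p.columns[all_zero].tolist()
    rows = []
    for ct in p.columns[~all_zero]:
        y = transform_zeros(p[ct], n)
        n_transformed = int((p[ct] == 0).sum() + (p[ct] == 1).sum())
        fit = fit_beta_regression(y, X)
        beta = fit.params["case"]
        se = fit.bse["case"]
        z = beta / se
        rows.append(
            {
                "cell_type": ct,
                "por": float(np.exp(beta)),
                "ci_lo": float(np.exp(beta - 1.96 * se)),
                "ci_hi": float(np.exp(beta + 1.96 * se)),
                "wald_p": float(2.0 * stats.norm.sf(abs(z))),
                "converged": fit.converged,
                "zero_transform_n": n_transformed,
            }
        )
    results = pd.DataFrame(rows).set_index("cell_type")
    report = {"n_dropped_types": len(dropped), "dropped_types": dropped, "n_samples": n}
    return results, report
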