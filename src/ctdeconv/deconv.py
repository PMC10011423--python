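"""Constrained-regression deconvolution of bulk mixtures against a signature.

Two solvers are provided: non-negative least squares on the linear scale
with unit-norm column scaling, and nu-support-vector regression with a
linear kernel on z-scored data (z-scored mixture, globally standardized
signature - the CIBERSORT convention), sweeping nu over {0.25, 0.5, 0.75}
and keeping the fit with the lowest reconstruction RMSE. Either way
the weights are clipped at zero and normalized to proportions summing to 1.
Per-sample goodness of fit is the Pearson correlation and RMSE between the
reconstructed and observed mixture over the shared signature genes, with an
add-one-smoothed permutation p-value from shuffling the mixture's gene
labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.svm import NuSVR

from ._stats import fisher_ci
from .containers import BulkExpression
from .preprocess import lognormalize, make_pseudobulk, split_balanced
from .signature import SignatureMatrix, build_signature, one_vs_rest_markers, type_profiles

NU_GRID = (0.25, 0.5, 0.75)


@dataclass
class ProportionEstimates:
    """Per-sample cell-type fractions with per-sample fit statistics."""

    proportions: pd.DataFrame  # samples x types, rows sum to 1
    fit_stats: pd.DataFrame  # pearson_r, rmse, perm_p per sample
    method: str
    n_permutations: int = 50

    def __post_init__(self) -> None:
        p = self.proportions.to_numpy()
        if (p < -1e-12).any():
            raise ValueError("proportions must be non-negative")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("proportion rows must sum to 1 within 1e-8")


@dataclass
class ValidationReport:
    """Recovery summary: stacked predicted vs actual proportions."""

    pearson_r: float
    ci95: tuple[float, float]
    rmse: float
    pairs: pd.DataFrame  # columns: predicted, actual (one row per sample x type)
    scenario: str | None = None
    n_cells: int | None = None


def _solve_nnls(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """NNLS on the linear scale with unit-norm column scaling."""
    norms = np.linalg.norm(a, axis=0)
    norms[norms == 0] = 1.0
    w_scaled, _ = optimize.nnls(a / norms, b)
    w = w_scaled / norms
    recon = a @ w
    return w, recon, b


def _solve_nusvr(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linear-kernel nu-SVR on z-scored data.

    The mixture is z-scored over the shared genes; the signature is
    standardized by its global mean and sd (not per column), which keeps
    the relative column scales and hence the weight interpretation intact -
    per-column scaling would fold each type's sd into its weight.
    """
    b_sd = b.std()
    if b_sd == 0:
        raise ValueError("mixture has zero variance over the signature genes")
    bz = (b - b.mean()) / b_sd
    az = (a - a.mean()) / a.std()
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for nu in NU_GRID:
        model = NuSVR(nu=nu, C=1.0, kernel="linear")
        model.fit(az, bz)
        w = model.coef_.ravel().copy()
        recon = az @ np.clip(w, 0.0, None)
        rmse = float(np.sqrt(np.mean((recon - bz) ** 2)))
        if best is None or rmse < best[0]:
            best = (rmse, w, recon)
    _, w, recon = best
    return np.clip(w, 0.0, None), recon, bz


_SOLVERS = {"nnls": _solve_nnls, "nusvr": _solve_nusvr}


def deconvolve(
    bulk: BulkExpression,
    sig: SignatureMatrix | pd.DataFrame,
    method: str = "nnls",
    n_permutations: int = 50,
    seed: int = 0,
) -> ProportionEstimates:
    """Estimate cell-type proportions for every bulk sample.

    Requires at least 50% of the signature genes to be present in the bulk
    platform; absent genes are dropped (intersection), never imputed. Bulk
    values flagged log2 are de-logged to the linear scale first.
    """
    if method not in _SOLVERS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_SOLVERS)}")
    sig_mat = sig.matrix if isinstance(sig, SignatureMatrix) else sig
    linear = bulk.to_linear()
    shared = sig_mat.index.intersection(linear.index)
    frac_missing = 1.0 - len(shared) / len(sig_mat.index)
    if frac_missing > 0.5:
        raise ValueError(
            f"{frac_missing:.1%} of signature genes missing from the bulk data "
            "(more than 50%)"
        )
    a = sig_mat.loc[shared].to_numpy(dtype=float)
    solver = _SOLVERS[method]
    rng = np.random.default_rng(seed)

    rows, fit_rows = [], []
    for sample in linear.columns:
        b = linear.loc[shared, sample].to_numpy(dtype=float)
        if not b.any():
            raise ValueError(f"sample {sample!r} is all zero over the signature genes")
        w, recon, b_fit = solver(a, b)
        if w.sum() <= 0:
            raise ValueError(f"solver returned all-zero weights for sample {sample!r}")
        props = w / w.sum()
        r_obs = stats.pearsonr(recon, b_fit).statistic
        rmse = float(np.sqrt(np.mean((recon - b_fit) ** 2)))
        n_ge = 0
        for _ in range(n_permutations):
            b_perm = rng.permutation(b)
            try:
                w_p, recon_p, b_fit_p = solver(a, b_perm)
            except ValueError:
                continue
            if w_p.sum() <= 0:
                continue
            r_p = stats.pearsonr(recon_p, b_fit_p).statistic
            if r_p >= r_obs:
                n_ge += 1
        perm_p = (1.0 + n_ge) / (1.0 + n_permutations)
        rows.append(props)
        fit_rows.append((r_obs, rmse, perm_p))

    proportions = pd.DataFrame(rows, index=linear.columns, columns=sig_mat.columns)
    fit_stats = pd.DataFrame(
        fit_rows, index=linear.columns, columns=["pearson_r", "rmse", "perm_p"]
    )
    return ProportionEstimates(proportions, fit_stats, method, n_permutations)


def evaluate_recovery(
    estimates: ProportionEstimates | pd.DataFrame,
    truth: pd.DataFrame,
    scenario: str | None = None,
    n_cells: int | None = None,
) -> ValidationReport:
    """Pearson r (with Fisher-z 95% CI) and RMSE over stacked pairs."""
    est = estimates.proportions if isinstance(estimates, ProportionEstimates) else estimates
    if est.shape != truth.shape:
        raise ValueError(f"shape mismatch: estimates {est.shape} vs truth {truth.shape}")
    truth = truth.loc[est.index, est.columns]
    pred = est.to_numpy(dtype=float).ravel()
    act = truth.to_numpy(dtype=float).ravel()
    if pred.std() == 0:
        raise ValueError("predictions have zero variance; correlation undefined")
    r = stats.pearsonr(pred, act).statistic
    rmse = float(np.sqrt(np.mean((pred - act) ** 2)))
    pairs = pd.DataFrame(
        {
            "sample": np.repeat(est.index, est.shape[1]),
            "cell_type": np.tile(est.columns, est.shape[0]),
            "predicted": pred,
            "actual": act,
        }
    )
    return ValidationReport(
        pearson_r=float(r),
        ci95=fisher_ci(r, pred.size),
        rmse=rmse,
        pairs=pairs,
        scenario=scenario,
        n_cells=n_cells,
    )


def run_insilico_validation(
    counts,
    meta: pd.DataFrame,
    scenario: str = "all",
    seed: int = 0,
    *,
    method: str = "nnls",
    g_floor: int = 300,
    g_ceiling: int = 500,
    de_q_cutoff: float = 0.01,
    n_permutations: int = 50,
) -> ValidationReport:
    """Split/train/test pseudo-bulk validation of the deconvolution reference.

    Splits the labeled cells 50/50 with balanced type proportions, builds a
    signature from the training half, constructs a scenario pseudo-bulk from
    the test half, deconvolutes it, and scores recovery against the known
    composition.
    """
    train_ids, test_ids = split_balanced(meta, fraction=0.5, seed=seed)
    train_counts = counts.subset_cells(train_ids)
    train_norm = lognormalize(train_counts)
    labels = meta.loc[train_ids, "cell_type"]
    markers = one_vs_rest_markers(train_norm, labels)
    profiles = type_profiles(train_norm, labels)
    sig = build_signature(
        profiles, markers, g_floor=g_floor, g_ceiling=g_ceiling, de_q_cutoff=de_q_cutoff
    )

    test_counts = counts.subset_cells(test_ids)
    bulk_col, true_props = make_pseudobulk(test_counts, meta.loc[test_ids], scenario, seed=seed)
    bulk = BulkExpression(bulk_col.to_frame("mixture"), scale="linear")
    est = deconvolve(bulk, sig, method=method, n_permutations=n_permutations, seed=seed)
    truth = true_props.reindex(est.proportions.columns).fillna(0.0).to_frame("mixture").T
    truth.index = est.proportions.index
    report = evaluate_recovery(est, truth, scenario=scenario)
    report.n_cells = _selected_cell_count(meta.loc[test_ids], scenario)
    return report


def _selected_cell_count(meta: pd.DataFrame, scenario: str) -> int:
    """Number of test cells the scenario mixes into the pseudo-bulk."""
    if scenario == "all":
        return len(meta)
    if scenario == "fetal_only":
        return int((meta["origin"] == "fetal").sum())
    if scenario == "maternal_only":
        return int((meta["origin"] == "maternal").sum())
    fetal = meta[meta["origin"] == "fetal"]
    n_ff = int((fetal["sex"] == "female").sum())
    n_fetal = len(fetal)
    n_mat = int((meta["origin"] == "maternal").sum())
    keep = n_ff if scenario == "female_fetal" else min(n_ff, int((fetal["sex"] == "male").sum()))
    if n_fetal == 0:
        return keep
    return keep + min(n_mat, int(round(n_mat * keep / n_fetal)))
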