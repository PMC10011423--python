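"""G-formula causal mediation with randomized-interventional analogs.

Estimates how much of the case-control difference in one gene's expression
is transmitted through cellular composition (the five proportion PCs),
treating gestational age as a confounder of the mediator-outcome relation
that is itself affected by the exposure. Because such exposure-induced
confounding blocks identification of classical natural effects, the
estimands are their randomized-interventional analogs: each subject's
counterfactual mediator value is replaced by a random draw from the
exposure-specific mediator distribution given baseline covariates, obtained
by simulation from fitted linear-Gaussian component models (g-formula with
direct counterfactual imputation).

Component models:
  L-model: confounder ~ exposure + baseline covariates
  M-models: each mediator ~ exposure + baseline + confounder
  Y-model: outcome ~ exposure + mediators + confounder + baseline
           (+ exposure x mediator terms when interaction is requested)

Effects (G(a) denotes a randomized-interventional mediator draw under
exposure a):
  r_te  = E[Y(1, G(1))] - E[Y(0, G(0))]
  r_nde = E[Y(1, G(0))] - E[Y(0, G(0))]
  r_nie = E[Y(1, G(1))] - E[Y(1, G(0))]
  pm    = r_nie / r_te  (reported only when r_te is non-negligible and
          r_nie shares its sign; the raw ratio is always retained)

The residual draws are shared across the counterfactual arms (common random
numbers). Because the fitted outcome model is linear in the mediators and
the confounder, the shared draws cancel exactly in every effect difference:
the estimates carry no Monte-Carlo noise and the additivity
r_te = r_nde + r_nie is exact, not merely within tolerance.

With the interaction flag, a four-way decomposition is computed with the
controlled direct effect evaluated at the mean of G(0); the proportion
attributable to interaction is (INT_ref + INT_med) / r_te. Confidence
intervals are percentile bootstrap over subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass
class MediationSpec:
    exposure: str
    outcome: str
    mediators: tuple[str, ...]
    baseline_covariates: tuple[str, ...] = ()
    post_exposure_confounder: str = "gestational_age"
    interaction: bool = False
    n_mc_draws: int = 200
    n_boot: int = 1000
    ci_level: float = 0.95
    seed: int = 0
    te_tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.n_mc_draws < 1:
            raise ValueError("n_mc_draws must be >= 1")


@dataclass
class LinearFit:
    columns: list[str]
    coef: np.ndarray
    resid_sd: float


@dataclass
class ComponentModels:
    l_model: LinearFit
    m_models: list[LinearFit]
    y_model: LinearFit
    baseline_columns: list[str]


@dataclass
class MediationEstimate:
    r_te: float
    r_nde: float
    r_nie: float
    pm: float  # nan when undefined
    pm_raw: float  # raw ratio r_nie / r_te regardless of sign agreement
    pm_defined: bool
    pai: float  # 0 when interaction off
    cde: float
    int_ref: float
    int_med: float
    pie: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    converged: bool = True
    n_boot: int = 0


@dataclass
class _Arrays:
    """Numeric view of a mediation dataset (complete cases only)."""

    a: np.ndarray  # exposure, (n,)
    ell: np.ndarray  # post-exposure confounder, (n,)
    m: np.ndarray  # mediators, (n, K)
    y: np.ndarray  # outcome, (n,)
    bmat: np.ndarray  # baseline covariates after dummy expansion, (n, B)
    baseline_columns: list[str]


def _numeric_baseline(data: pd.DataFrame, covariates: tuple[str, ...]) -> pd.DataFrame:
    """Expand baseline covariates to a numeric frame (dummies for strings)."""
    if not covariates:
        return pd.DataFrame(index=data.index)
    cols = []
    for c in covariates:
        s = data[c]
        if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
            d = pd.get_dummies(s.astype(str), prefix=c, drop_first=True, dtype=float)
            cols.append(d)
        else:
            cols.append(s.astype(float).to_frame(c))
    return pd.concat(cols, axis=1)


def _extract_arrays(
    data: pd.DataFrame, spec: MediationSpec, baseline_columns: list[str] | None = None
) -> _Arrays:
    needed = [spec.exposure, spec.outcome, spec.post_exposure_confounder,
              *spec.mediators, *spec.baseline_covariates]
    data = data.dropna(subset=needed)
    base = _numeric_baseline(data, spec.baseline_covariates)
    if baseline_columns is not None:
        # align dummy columns with fit time (a resample may drop a level)
        for c in baseline_columns:
            if c not in base.columns:
                base[c] = 0.0
        base = base[baseline_columns]
    return _Arrays(
        a=data[spec.exposure].astype(float).to_numpy(),
        ell=data[spec.post_exposure_confounder].astype(float).to_numpy(),
        m=data[list(spec.mediators)].astype(float).to_numpy(),
        y=data[spec.outcome].astype(float).to_numpy(),
        bmat=base.to_numpy(dtype=float),
        baseline_columns=list(base.columns),
    )


def _ols(y: np.ndarray, X: np.ndarray, columns: list[str]) -> LinearFit:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError(f"rank-deficient design with columns {columns}")
    resid = y - X @ coef
    dof = max(X.shape[0] - X.shape[1], 1)
    return LinearFit(columns=columns, coef=coef, resid_sd=float(np.sqrt((resid**2).sum() / dof)))


def _fit_arrays(arr: _Arrays, spec: MediationSpec) -> ComponentModels:
    n = arr.a.size
    if np.unique(arr.a).size < 2:
        raise ValueError("exposure is constant; mediation undefined")
    k = len(spec.mediators)
    n_par = 2 + arr.bmat.shape[1] + k * (2 if spec.interaction else 1) + 2
    if n < n_par + 5:
        raise ValueError(f"too few complete cases ({n}) for the requested models")
    ones = np.ones((n, 1))
    a_col = arr.a[:, None]

    xl = np.hstack([ones, a_col, arr.bmat])
    l_model = _ols(arr.ell, xl, ["intercept", "exposure", *arr.baseline_columns])

    xm = np.hstack([ones, a_col, arr.bmat, arr.ell[:, None]])
    m_cols = ["intercept", "exposure", *arr.baseline_columns, "confounder"]
    m_models = [_ols(arr.m[:, j], xm, m_cols) for j in range(k)]

    blocks = [ones, a_col, arr.m, arr.ell[:, None], arr.bmat]
    y_cols = ["intercept", "exposure", *spec.mediators, "confounder",
              *arr.baseline_columns]
    if spec.interaction:
        blocks.append(a_col * arr.m)
        y_cols += [f"exposure_x_{mm}" for mm in spec.mediators]
    y_model = _ols(arr.y, np.hstack(blocks), y_cols)
    return ComponentModels(l_model, m_models, y_model, list(arr.baseline_columns))


def fit_component_models(data: pd.DataFrame, spec: MediationSpec) -> ComponentModels:
    """Fit the L-, M-, and Y-models on complete cases."""
    return _fit_arrays(_extract_arrays(data, spec), spec)


def _y_mean(
    models: ComponentModels,
    spec: MediationSpec,
    a: float,
    m_draw: np.ndarray,  # (n, D, K)
    ell: np.ndarray,  # (n, D)
    bmat: np.ndarray,  # (n, B)
) -> np.ndarray:
    """Expected outcome from the Y-model at (a, m, l, baseline); (n, D)."""
    coef = models.y_model.coef
    k = len(spec.mediators)
    i = 0
    out = np.full(ell.shape, coef[i])
    i += 1
    out = out + coef[i] * a
    i += 1
    out = out + np.tensordot(m_draw, coef[i : i + k], axes=([2], [0]))
    i += k
    out = out + coef[i] * ell
    i += 1
    nb = bmat.shape[1]
    if nb:
        out = out + (bmat @ coef[i : i + nb])[:, None]
    i += nb
    if spec.interaction:
        out = out + a * np.tensordot(m_draw, coef[i : i + k], axes=([2], [0]))
    return out


def _estimate_from_models(
    models: ComponentModels,
    bmat: np.ndarray,
    spec: MediationSpec,
    rng: np.random.Generator,
    analytic: bool = False,
) -> MediationEstimate:
    """Randomized-analog effects from fitted models.

    ``analytic=True`` evaluates the g-formula expectations exactly (zero
    residual draws, one replicate): because the outcome model is linear in
    mediators and confounder, the paired residual draws cancel in every
    effect difference, so this returns the same numbers the Monte-Carlo
    path does - it is used inside the bootstrap for speed.
    """
    n = bmat.shape[0]
    k = len(spec.mediators)
    if analytic:
        d = 1
        eps_l = np.zeros((n, 1))
        eps_m = np.zeros((n, 1, k))
    else:
        d = spec.n_mc_draws
        eps_l = rng.normal(0.0, models.l_model.resid_sd, size=(n, d))
        m_sds = np.array([mm.resid_sd for mm in models.m_models])
        eps_m = rng.normal(size=(n, d, k)) * m_sds[None, None, :]

    nb = bmat.shape[1]

    def l_mean(a: float) -> np.ndarray:
        c = models.l_model.coef
        out = np.full(n, c[0] + c[1] * a)
        if nb:
            out = out + bmat @ c[2 : 2 + nb]
        return out

    def draw_m(a_star: float, l_star: np.ndarray) -> np.ndarray:
        out = np.empty((n, d, k))
        for j, mm in enumerate(models.m_models):
            c = mm.coef
            mean = c[0] + c[1] * a_star
            if nb:
                mean = mean + bmat @ c[2 : 2 + nb]
            out[:, :, j] = mean[:, None] + c[2 + nb] * l_star + eps_m[:, :, j]
        return out

    l0 = l_mean(0.0)[:, None] + eps_l
    l1 = l_mean(1.0)[:, None] + eps_l
    g0 = draw_m(0.0, l0)  # randomized draws from the a*=0 mediator law
    g1 = draw_m(1.0, l1)

    ey_11 = _y_mean(models, spec, 1.0, g1, l1, bmat).mean()
    ey_00 = _y_mean(models, spec, 0.0, g0, l0, bmat).mean()
    ey_10 = _y_mean(models, spec, 1.0, g0, l1, bmat).mean()
    ey_01 = _y_mean(models, spec, 0.0, g1, l0, bmat).mean()

    r_te = float(ey_11 - ey_00)
    r_nde = float(ey_10 - ey_00)
    r_nie = float(ey_11 - ey_10)
    pie = float(ey_01 - ey_00)

    # four-way pieces: controlled direct effect at the mean of G(0)
    m_ref = np.broadcast_to(g0.mean(axis=(0, 1)), (n, d, k))
    cde = float(
        _y_mean(models, spec, 1.0, m_ref, l1, bmat).mean()
        - _y_mean(models, spec, 0.0, m_ref, l0, bmat).mean()
    )
    int_ref = r_nde - cde
    int_med = r_nie - pie

    pm_raw = r_nie / r_te if abs(r_te) > 0 else np.nan
    pm_defined = abs(r_te) > spec.te_tolerance and (r_nie * r_te >= 0)
    pm = pm_raw if pm_defined else np.nan
    pai = (
        (int_ref + int_med) / r_te
        if (spec.interaction and abs(r_te) > spec.te_tolerance)
        else 0.0
    )
    return MediationEstimate(
        r_te=r_te,
        r_nde=r_nde,
        r_nie=r_nie,
        pm=pm,
        pm_raw=float(pm_raw) if np.isfinite(pm_raw) else np.nan,
        pm_defined=bool(pm_defined),
        pai=float(pai),
        cde=cde,
        int_ref=float(int_ref),
        int_med=float(int_med),
        pie=pie,
    )


def estimate_effects(
    models: ComponentModels,
    data: pd.DataFrame,
    spec: MediationSpec,
    rng: np.random.Generator | None = None,
) -> MediationEstimate:
    """Counterfactual imputation of the randomized-analog effects."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    arr = _extract_arrays(data, spec, baseline_columns=models.baseline_columns)
    return _estimate_from_models(models, arr.bmat, spec, rng)


def bootstrap_mediation(data: pd.DataFrame, spec: MediationSpec) -> MediationEstimate:
    """Point estimates on the full data plus percentile bootstrap CIs.

    The bootstrap resamples subjects with replacement, refits the component
    models, and re-estimates the effects per replicate. More than 5% failed
    replicates is an error.
    """
    rng = np.random.default_rng(spec.seed)
    arr = _extract_arrays(data, spec)
    models = _fit_arrays(arr, spec)
    point = _estimate_from_models(
        models, arr.bmat, spec, np.random.default_rng(rng.integers(2**31))
    )

    stats: dict[str, list[float]] = {k: [] for k in ("r_te", "r_nde", "r_nie", "pm_raw", "pai")}
    n = arr.a.size
    failures = 0
    for _ in range(spec.n_boot):
        idx = rng.integers(0, n, size=n)
        boot = _Arrays(
            a=arr.a[idx], ell=arr.ell[idx], m=arr.m[idx], y=arr.y[idx],
            bmat=arr.bmat[idx], baseline_columns=arr.baseline_columns,
        )
        try:
            bm = _fit_arrays(boot, spec)
            est = _estimate_from_models(
                bm, boot.bmat, spec,
                np.random.default_rng(rng.integers(2**31)), analytic=True,
            )
        except (ValueError, np.linalg.LinAlgError):
            failures += 1
            continue
        for key in stats:
            stats[key].append(getattr(est, key))
    if failures > 0.05 * spec.n_boot:
        raise RuntimeError(f"{failures}/{spec.n_boot} bootstrap replicates failed to fit")
    lo_q = (1.0 - spec.ci_level) / 2.0
    ci = {}
    for key, vals in stats.items():
        vals_arr = np.asarray(vals, dtype=float)
        vals_arr = vals_arr[np.isfinite(vals_arr)]
        if vals_arr.size:
            ci[key] = (
                float(np.quantile(vals_arr, lo_q)),
                float(np.quantile(vals_arr, 1.0 - lo_q)),
            )
    ci["pm"] = ci.get("pm_raw", (np.nan, np.nan))
    return replace(point, ci=ci, n_boot=spec.n_boot - failures)
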