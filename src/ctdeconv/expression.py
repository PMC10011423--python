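"""Composition PCA, moderated gene-wise linear models, and preranked GSEA.

The differential-expression machinery mirrors the limma workflow: ordinary
least squares per gene, then empirical-Bayes shrinkage of the residual
variances toward a common prior. The prior (d0, s0^2) is estimated by
matching the moments of log s^2 to a scaled F distribution (the standard
inverse-chi-square scheme), the posterior variance is the weighted average
s~^2 = (d0 s0^2 + d s^2) / (d0 + d), and the moderated t has d0 + d degrees
of freedom. Significance is the conjunction q < 0.05 (BH) and |log2FC| >=
0.1.

Preranked gene-set enrichment follows the weighted running-sum statistic:
hits increment by |r|^w / sum_hits |r|^w (w = 1), misses decrement by
1/(N - Nh), the enrichment score is the extremum of the running sum, and
the null comes from gene-label permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from ._stats import bh_adjust, trigamma_inverse
from .abundance import build_design
from .deconv import ProportionEstimates


@dataclass
class ProportionPCs:
    scores: pd.DataFrame  # samples x n_pcs
    loadings: pd.DataFrame  # types x n_pcs
    variance_explained: np.ndarray  # fraction per retained PC
    n_pcs: int = 5


def proportion_pca(props: ProportionEstimates | pd.DataFrame, n_pcs: int = 5) -> ProportionPCs:
    """Column-centered, unscaled PCA of the proportion matrix via SVD.

    Exactly ``n_pcs`` components are retained regardless of variance
    explained, matching the fixed five-PC choice of the downstream models.
    """
    p = props.proportions if isinstance(props, ProportionEstimates) else props
    if p.shape[0] < n_pcs + 1 or p.shape[1] < n_pcs + 1:
        raise ValueError(f"need more than {n_pcs} samples and cell types for {n_pcs} PCs")
    x = p.to_numpy(dtype=float)
    centered = x - x.mean(axis=0)
    if np.allclose(centered, 0.0):
        raise ValueError("proportion matrix is constant; PCA undefined")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2 / (s**2).sum()
    scores = u[:, :n_pcs] * s[:n_pcs]
    return ProportionPCs(
        scores=pd.DataFrame(
            scores, index=p.index, columns=[f"PC{i + 1}" for i in range(n_pcs)]
        ),
        loadings=pd.DataFrame(
            vt[:n_pcs].T, index=p.columns, columns=[f"PC{i + 1}" for i in range(n_pcs)]
        ),
        variance_explained=var[:n_pcs],
        n_pcs=n_pcs,
    )


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[float, float, np.ndarray]:
    """Empirical-Bayes shrinkage of gene-wise residual variances.

    Fits s^2 ~ s0^2 F(df, d0) by matching the mean and variance of log s^2,
    then returns (d0, s0^2, posterior variances). d0 = inf when the observed
    spread of log s^2 does not exceed its sampling variance, in which case
    every posterior variance equals s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 2:
        raise ValueError("need at least 2 genes to estimate the variance prior")
    if (s2 <= 0).any():
        s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess > 0:
        d0 = 2.0 * trigamma_inverse(excess)
        s0_sq = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        post = (d0 * s0_sq + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
        post = np.full_like(s2, s0_sq)
    return float(d0), float(s0_sq), post


def moderated_lm(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    coef_of_interest: str,
    *,
    fc_cutoff: float = 0.1,
    q_cutoff: float = 0.05,
    prior_df: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Gene-wise OLS with empirical-Bayes moderated t for one coefficient.

    ``expr`` is genes x samples on the log2 scale; ``design`` is samples x
    covariates including the intercept. Coefficients are identical to OLS;
    moderation only shrinks the variances and changes the degrees of
    freedom. ``prior_df`` overrides the estimated d0: 0 disables shrinkage
    (ordinary t), inf pools all genes to the common prior variance.
    """
    if not expr.columns.equals(design.index):
        raise ValueError("expression columns and design rows must align")
    X = design.to_numpy(dtype=float)
    n, p_cols = X.shape
    if np.linalg.matrix_rank(X) < p_cols:
        raise ValueError("design matrix is rank deficient")
    d_resid = n - p_cols
    if d_resid < 1:
        raise ValueError("no residual degrees of freedom")
    y = expr.to_numpy(dtype=float)  # genes x samples
    xtx_inv = np.linalg.inv(X.T @ X)
    pinv = xtx_inv @ X.T
    beta = y @ pinv.T  # genes x p
    resid = y - beta @ X.T
    s2 = (resid**2).sum(axis=1) / d_resid
    d0, s0_sq, s2_post = squeeze_variances(s2, d_resid)
    if prior_df is not None:
        d0 = float(prior_df)
        if d0 == 0:
            s2_post = s2.copy()
        elif np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
        else:
            s2_post = (d0 * s0_sq + d_resid * s2) / (d0 + d_resid)

    j = list(design.columns).index(coef_of_interest)
    v_j = xtx_inv[j, j]
    b = beta[:, j]
    t_mod = b / np.sqrt(s2_post * v_j)
    df_total = d0 + d_resid
    if np.isfinite(df_total):
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    else:
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    q = bh_adjust(p)
    table = pd.DataFrame(
        {
            "logfc": b,
            "t_mod": t_mod,
            "p": p,
            "q": q,
            "s2": s2,
            "s2_post": s2_post,
            "significant": (q < q_cutoff) & (np.abs(b) >= fc_cutoff),
        },
        index=expr.index,
    )
    info = {
        "d0": d0,
        "s0_sq": s0_sq,
        "df_residual": d_resid,
        "df_total": float(df_total),
        "fc_cutoff": fc_cutoff,
        "q_cutoff": q_cutoff,
    }
    return table, info


def run_de_models(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    pcs: ProportionPCs | None = None,
    *,
    fc_cutoff: float = 0.1,
    q_cutoff: float = 0.05,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Base and composition-adjusted differential expression models.

    The base design is intercept + case + gestational_age + fetal_sex +
    study; the adjusted model appends the PC scores. With ``pcs=None`` the
    adjusted model is identical to the base model.
    """
    if not expr.columns.equals(meta.index):
        if set(expr.columns) != set(meta.index):
            raise ValueError("expression samples and metadata differ")
        meta = meta.loc[expr.columns]
    base_design = build_design(meta)
    tables: dict[str, pd.DataFrame] = {}
    infos: dict[str, dict] = {}
    tables["base"], infos["base"] = moderated_lm(
        expr, base_design, "case", fc_cutoff=fc_cutoff, q_cutoff=q_cutoff
    )
    if pcs is None:
        tables["celltype_adjusted"] = tables["base"].copy()
        infos["celltype_adjusted"] = dict(infos["base"])
    else:
        adj_design = pd.concat([base_design, pcs.scores.loc[base_design.index]], axis=1)
        tables["celltype_adjusted"], infos["celltype_adjusted"] = moderated_lm(
            expr, adj_design, "case", fc_cutoff=fc_cutoff, q_cutoff=q_cutoff
        )
    summary = {
        m: {
            "n_significant": int(t["significant"].sum()),
            "n_up": int((t["significant"] & (t["logfc"] > 0)).sum()),
            "n_down": int((t["significant"] & (t["logfc"] < 0)).sum()),
            **infos[m],
        }
        for m, t in tables.items()
    }
    return tables, summary


def enrichment_score(
    ranked: pd.Series, gene_set: set[str], weight: float = 1.0
) -> float:
    """Weighted Kolmogorov-Smirnov-like running-sum enrichment score."""
    order = ranked.sort_values(ascending=False)
    hits = order.index.isin(gene_set)
    n = len(order)
    nh = int(hits.sum())
    if nh == 0 or nh >= n:
        raise ValueError("gene set must hit at least one and not all ranked genes")
    w = np.abs(order.to_numpy(dtype=float)) ** weight
    hit_w = np.where(hits, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        hit_w = hits.astype(float)
        denom = float(nh)
    p_hit = np.cumsum(hit_w) / denom
    p_miss = np.cumsum(~hits) / (n - nh)
    dev = p_hit - p_miss
    return float(dev[np.argmax(np.abs(dev))])


def preranked_gsea(
    ranked: pd.Series,
    sets: dict[str, set[str]],
    n_permutations: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Preranked GSEA with a gene-label permutation null.

    NES is ES divided by the mean |null ES| of matching sign; the
    permutation p is add-one smoothed over same-sign null exceedances; q is
    BH across gene sets (a documented simplification of the tool-default
    NES-binned FDR).
    """
    ranked = ranked.dropna()
    if not np.isfinite(ranked.to_numpy()).all():
        raise ValueError("ranking statistics must be finite")
    order = ranked.sort_values(ascending=False)
    n = len(order)
    rng = np.random.default_rng(seed)
    w_abs = np.abs(order.to_numpy(dtype=float)) ** weight

    rows = []
    for set_id, genes in sets.items():
        present = order.index.isin(set(genes))
        nh = int(present.sum())
        if nh < 2 or nh >= n:
            warnings.warn(f"gene set {set_id!r} has {nh} ranked genes; skipped")
            continue
        es = enrichment_score(order, set(genes), weight)
        null_es = np.empty(n_permutations)
        for b in range(n_permutations):
            pos = rng.choice(n, size=nh, replace=False)
            hit = np.zeros(n, dtype=bool)
            hit[pos] = True
            hit_w = np.where(hit, w_abs, 0.0)
            denom = hit_w.sum()
            if denom == 0:
                denom = float(nh)
                hit_w = hit.astype(float)
            dev = np.cumsum(hit_w) / denom - np.cumsum(~hit) / (n - nh)
            null_es[b] = dev[np.argmax(np.abs(dev))]
        same_sign = null_es * np.sign(es) > 0
        denom_nes = np.abs(null_es[same_sign]).mean() if same_sign.any() else np.nan
        nes = es / denom_nes if denom_nes and np.isfinite(denom_nes) else np.nan
        n_ge = int((same_sign & (np.abs(null_es) >= abs(es))).sum())
        perm_p = (1.0 + n_ge) / (1.0 + n_permutations)
        rows.append(
            {
                "gene_set": set_id,
                "es": es,
                "nes": nes,
                "perm_p": perm_p,
                "n_genes": nh,
                "n_permutations": n_permutations,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["gene_set", "es", "nes", "perm_p", "q", "n_genes", "n_permutations"]
        ).set_index("gene_set")
    out = pd.DataFrame(rows).set_index("gene_set")
    out["q"] = bh_adjust(out["perm_p"].to_numpy())
    return out
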