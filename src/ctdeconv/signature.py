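"""Marker detection and signature-matrix assembly for deconvolution.

Markers are found one-vs-rest per cell type with the two-sided Wilcoxon
rank-sum test (exact for small groups without ties, normal approximation
with tie correction otherwise) and BH-adjusted within each type's test
family. The signature matrix unions each type's top-G markers (significant
at q < 0.01, ranked by descending log2 fold-change) for G swept between a
300-gene floor and a 500-gene ceiling, and keeps the G whose candidate
matrix has the smallest 2-norm condition number - the standard
feature-selection scheme of CIBERSORT-style deconvolution.

The log2 fold-change convention is the widely used single-cell one:
log2((mean(expm1(x_in)) + 1) / (mean(expm1(x_out)) + 1)) on library-size
log-normalized values, i.e. fold change of mean CP10K expression with a
pseudocount of 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .containers import NormalizedCells


def one_vs_rest_markers(norm: NormalizedCells, labels: pd.Series) -> pd.DataFrame:
    """Per (gene, type) Wilcoxon rank-sum marker statistics.

    Returns a table with columns gene, cell_type, log2fc, p, q, pct_in,
    pct_out. q-values are BH-adjusted within each cell type's family of
    gene tests. Genes constant across all cells get p = 1 by convention.
    """
    labels = pd.Series(labels)
    labels = labels.loc[norm.cells]
    types = sorted(labels.unique())
    if len(types) < 2:
        raise ValueError("need at least 2 cell types")
    counts = labels.value_counts()
    small = counts[counts < 3]
    if len(small):
        raise ValueError(f"every type needs >= 3 cells; too small: {small.index.tolist()}")

    dense = np.asarray(norm.matrix.todense())
    linear = np.expm1(dense)
    frames = []
    for t in types:
        in_mask = (labels == t).to_numpy()
        a = dense[:, in_mask]
        b = dense[:, ~in_mask]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if min(a.shape[1], b.shape[1]) < 8:
                # per-gene call so scipy's exact small-sample method applies
                # gene by gene (the vectorized path picks one method globally)
                p = np.array(
                    [
                        stats.mannwhitneyu(a[g], b[g], alternative="two-sided").pvalue
                        for g in range(a.shape[0])
                    ],
                    dtype=float,
                )
            else:
                res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided")
                p = np.asarray(res.pvalue, dtype=float)
        p[~np.isfinite(p)] = 1.0  # constant genes: no separation
        mean_in = linear[:, in_mask].mean(axis=1)
        mean_out = linear[:, ~in_mask].mean(axis=1)
        log2fc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
        frames.append(
            pd.DataFrame(
                {
                    "gene": norm.genes,
                    "cell_type": t,
                    "log2fc": log2fc,
                    "p": p,
                    "q": bh_adjust(p),
                    "pct_in": (a > 0).mean(axis=1),
                    "pct_out": (b > 0).mean(axis=1),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class SignatureMatrix:
    """Linear-scale mean expression of selected signature genes x cell types."""

    matrix: pd.DataFrame
    chosen_g: int
    kappa: float
    g_floor: int = 300
    g_ceiling: int = 500
    de_q_cutoff: float = 0.01

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    @property
    def cell_types(self) -> pd.Index:
        return self.matrix.columns


def condition_number(matrix: np.ndarray | pd.DataFrame) -> float:
    """2-norm condition number of the column-normalized matrix.

    Columns are scaled to unit Euclidean norm (no centering, so exactly
    orthogonal type profiles keep kappa = 1); kappa is the ratio of the
    largest to smallest singular value, infinite for singular input.
    """
    a = np.asarray(matrix, dtype=float)
    norms = np.linalg.norm(a, axis=0)
    if (norms == 0).any():
        return np.inf
    s = np.linalg.svd(a / norms, compute_uv=False)
    if s[-1] <= s[0] * 1e-12:
        return np.inf
    return float(s[0] / s[-1])


def type_profiles(norm: NormalizedCells, labels: pd.Series) -> pd.DataFrame:
    """Per-type mean expression on the linear (CP10K) scale."""
    labels = pd.Series(labels).loc[norm.cells]
    dense = np.expm1(np.asarray(norm.matrix.todense()))
    cols = {}
    for t in sorted(labels.unique()):
        cols[t] = dense[:, (labels == t).to_numpy()].mean(axis=1)
    return pd.DataFrame(cols, index=norm.genes).rename_axis(columns="cell_type")


def build_signature(
    profiles: pd.DataFrame,
    markers: pd.DataFrame,
    *,
    g_floor: int = 300,
    g_ceiling: int = 500,
    de_q_cutoff: float = 0.01,
) -> SignatureMatrix:
    """Assemble the signature matrix minimizing the condition number.

    For each G in [g_floor, g_ceiling] the candidate gene set is the union
    over types of that type's top-G significant markers (all of them when a
    type has fewer than G); the G with the smallest condition number of the
    candidate matrix wins, ties broken by the smallest G.
    """
    sig_markers = markers[markers["q"] < de_q_cutoff]
    ranked: dict[str, list[str]] = {}
    for t in profiles.columns:
        sub = sig_markers[sig_markers["cell_type"] == t]
        if sub.empty:
            raise ValueError(f"cell type {t!r} has no significant markers at q < {de_q_cutoff}")
        sub = sub.sort_values(["log2fc", "gene"], ascending=[False, True])
        ranked[t] = sub["gene"].tolist()

    best: tuple[float, int, list[str]] | None = None
    prev_set: frozenset[str] | None = None
    for g in range(g_floor, g_ceiling + 1):
        gene_set = frozenset().union(*(frozenset(r[:g]) for r in ranked.values()))
        if gene_set == prev_set:
            continue  # same candidate as previous G; kappa unchanged
        prev_set = gene_set
        gene_list = sorted(gene_set)
        kappa = condition_number(profiles.loc[gene_list])
        # strict improvement beyond float noise, so ties go to the smallest G
        if np.isfinite(kappa) and (best is None or kappa < best[0] * (1.0 - 1e-9)):
            best = (kappa, g, gene_list)
    if best is None:
        raise ValueError("signature singular at every feature-count G")
    kappa, chosen_g, gene_list = best
    return SignatureMatrix(
        matrix=profiles.loc[gene_list].copy(),
        chosen_g=chosen_g,
        kappa=kappa,
        g_floor=g_floor,
        g_ceiling=g_ceiling,
        de_q_cutoff=de_q_cutoff,
    )
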