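"""Single-cell QC, normalization, replicate concordance, splitting, pseudo-bulk.

QC follows the common UMI / detected-gene / mitochondrial-fraction recipe:
cells are dropped when their total UMI count falls below 500, when fewer
than 200 genes are detected, or when their mitochondrial mapping rate is a
high outlier within its batch - above the batch median plus a multiple
(default 4, per-batch override) of the normal-consistent scaled median
absolute deviation (MAD x 1.4826). Normalization is the standard
library-size CP10K log transform: ln(1 + 1e4 * x / cell_total).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .containers import CellCounts, NormalizedCells, validate_cell_meta

PSEUDOBULK_SCENARIOS = ("all", "fetal_only", "maternal_only", "female_fetal", "male_fetal")


@dataclass
class QCThresholds:
    min_umis: int = 500
    min_genes: int = 200
    mito_mads: float = 4.0
    mito_mads_by_batch: dict[str, float] = field(default_factory=dict)
    mito_gene_set: tuple[str, ...] = ()
    mad_scale: float = 1.4826

    def __post_init__(self) -> None:
        if self.min_umis <= 0 or self.min_genes <= 0 or self.mito_mads <= 0:
            raise ValueError("QC thresholds must be positive")


def qc_filter(
    counts: CellCounts, meta: pd.DataFrame, th: QCThresholds | None = None
) -> tuple[CellCounts, pd.DataFrame, dict]:
    """Apply the three QC rules and report per-rule exclusion counts.

    A cell may trip several rules; the report lists both per-rule counts and
    the number of unique cells removed. The mitochondrial rule is one-sided
    (high outliers only) and computed within each batch.
    """
    th = th or QCThresholds()
    validate_cell_meta(meta, counts.cells)
    meta = meta.loc[counts.cells]
    x = counts.matrix
    totals = np.asarray(x.sum(axis=0)).ravel()
    n_genes_det = np.asarray((x > 0).sum(axis=0)).ravel()

    fail_umi = totals < th.min_umis
    fail_genes = n_genes_det < th.min_genes

    mito_genes = pd.Index(th.mito_gene_set)
    fail_mito = np.zeros(len(counts.cells), dtype=bool)
    mito_cutoffs: dict[str, float] = {}
    if len(mito_genes) > 0:
        present = counts.genes.isin(mito_genes)
        if not present.any():
            warnings.warn(
                "none of the mitochondrial genes are present; skipping the "
                "mitochondrial QC rule"
            )
        else:
            mito_total = np.asarray(x[present].sum(axis=0)).ravel()
            with np.errstate(invalid="ignore", divide="ignore"):
                rate = np.where(totals > 0, mito_total / np.maximum(totals, 1), 0.0)
            for batch, idx in meta.groupby("batch", observed=True).groups.items():
                pos = counts.cells.get_indexer(idx)
                r = rate[pos]
                med = np.median(r)
                mad = np.median(np.abs(r - med))
                k = th.mito_mads_by_batch.get(str(batch), th.mito_mads)
                cutoff = med + k * th.mad_scale * mad
                mito_cutoffs[str(batch)] = float(cutoff)
                fail_mito[pos] = r > cutoff

    fail_any = fail_umi | fail_genes | fail_mito
    keep = ~fail_any
    if not keep.any():
        raise ValueError("no cells remain after QC filtering")
    kept_cells = counts.cells[keep]
    report = {
        "n_input": int(len(counts.cells)),
        "n_removed_umi": int(fail_umi.sum()),
        "n_removed_genes": int(fail_genes.sum()),
        "n_removed_mito": int(fail_mito.sum()),
        "n_removed_unique": int(fail_any.sum()),
        "n_kept": int(keep.sum()),
        "mito_cutoffs": mito_cutoffs,
    }
    return counts.subset_cells(kept_cells), meta.loc[kept_cells], report


def lognormalize(counts: CellCounts) -> NormalizedCells:
    """Library-size normalize and log-transform: ln(1 + 1e4 * x / total)."""
    totals = np.asarray(counts.matrix.sum(axis=0)).ravel()
    zero = totals == 0
    if zero.any():
        bad = counts.cells[zero][:5].tolist()
        raise ValueError(f"cells with zero total counts, e.g. {bad}")
    mat = counts.matrix.astype(float).tocsc()
    scale = 1e4 / totals
    mat = mat.multiply(sparse.csr_matrix(scale[None, :])).tocsr()
    mat.data = np.log1p(mat.data)
    return NormalizedCells(mat, counts.genes, counts.cells)


def technical_concordance(
    norm: NormalizedCells, meta: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Spearman correlation of cluster-mean expression between technical reps.

    For every donor with at least two technical replicates, and every cell
    type present in both members of a replicate pair, the per-gene mean
    normalized expression is computed per (cluster, replicate) and the two
    vectors are rank-correlated. Clusters present in only one replicate are
    skipped with a warning.
    """
    validate_cell_meta(meta, norm.cells)
    if "cell_type" not in meta.columns or meta["cell_type"].isna().any():
        raise ValueError("technical_concordance requires cell_type labels")
    meta = meta.loc[norm.cells]
    dense = np.asarray(norm.matrix.todense())
    rows = []
    for donor, dmeta in meta.groupby("donor", observed=True):
        reps = sorted(dmeta["technical_replicate"].unique())
        if len(reps) < 2:
            continue
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                ra, rb = reps[i], reps[j]
                a_meta = dmeta[dmeta["technical_replicate"] == ra]
                b_meta = dmeta[dmeta["technical_replicate"] == rb]
                clusters = set(a_meta["cell_type"]) | set(b_meta["cell_type"])
                for cl in sorted(clusters):
                    ca = a_meta.index[a_meta["cell_type"] == cl]
                    cb = b_meta.index[b_meta["cell_type"] == cl]
                    if len(ca) == 0 or len(cb) == 0:
                        warnings.warn(
                            f"cluster {cl!r} present in only one replicate of "
                            f"donor {donor!r}; skipped"
                        )
                        continue
                    va = dense[:, norm.cells.get_indexer(ca)].mean(axis=1)
                    vb = dense[:, norm.cells.get_indexer(cb)].mean(axis=1)
                    rho = stats.spearmanr(va, vb).statistic
                    rows.append((donor, ra, rb, cl, rho, len(ca), len(cb)))
    if not rows:
        raise ValueError("no replicate pairs share any cluster")
    table = pd.DataFrame(
        rows,
        columns=["donor", "rep_a", "rep_b", "cluster", "rho", "n_cells_a", "n_cells_b"],
    )
    summary = {
        "mean_rho": float(table["rho"].mean()),
        "sd_rho": float(table["rho"].std(ddof=1)) if len(table) > 1 else 0.0,
        "n_pairs": int(len(table)),
    }
    return table, summary


def split_balanced(
    meta: pd.DataFrame, fraction: float = 0.5, seed: int = 0
) -> tuple[pd.Index, pd.Index]:
    """Split cells into train/test with balanced per-type proportions.

    Per type, floor(n * fraction) cells go to train and the remainder to
    test (the extra cell of an odd-sized type lands in test). Types with
    fewer than 2 cells are assigned entirely to train with a warning.
    """
    if "cell_type" not in meta.columns or meta["cell_type"].isna().any():
        raise ValueError("split_balanced requires a cell_type label for every cell")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list = []
    test: list = []
    for cl, cmeta in meta.groupby("cell_type", observed=True, sort=True):
        ids = cmeta.index.to_numpy()
        if len(ids) < 2:
            warnings.warn(f"cell type {cl!r} has fewer than 2 cells; all to train")
            train.extend(ids)
            continue
        perm = rng.permutation(len(ids))
        n_train = int(np.floor(len(ids) * fraction))
        train.extend(ids[perm[:n_train]])
        test.extend(ids[perm[n_train:]])
    return pd.Index(train, name="cell_id"), pd.Index(test, name="cell_id")


def make_pseudobulk(
    counts: CellCounts,
    meta: pd.DataFrame,
    scenario: str = "all",
    seed: int = 0,
) -> tuple[pd.Series, pd.Series]:
    """Sum raw counts over a scenario-selected cell subset.

    Scenarios select all cells, only fetal, only maternal, or only one fetal
    sex. The sex scenarios keep the baseline maternal share by down-sampling
    maternal cells, and the male scenario additionally down-samples male
    fetal cells to the female fetal count so both sex mixtures have the same
    size. Returns the pseudo-bulk column (per-gene count sums) and the true
    per-type proportion vector of the selected cells.
    """
    if scenario not in PSEUDOBULK_SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {PSEUDOBULK_SCENARIOS}")
    validate_cell_meta(meta, counts.cells)
    meta = meta.loc[counts.cells]
    rng = np.random.default_rng(seed)

    fetal = meta.index[meta["origin"] == "fetal"]
    maternal = meta.index[meta["origin"] == "maternal"]
    if scenario == "all":
        selected = meta.index
    elif scenario == "fetal_only":
        selected = fetal
    elif scenario == "maternal_only":
        selected = maternal
    else:
        sex = "female" if scenario == "female_fetal" else "male"
        fmeta = meta.loc[fetal]
        female_fetal = fmeta.index[fmeta["sex"] == "female"]
        male_fetal = fmeta.index[fmeta["sex"] == "male"]
        n_target = len(female_fetal)
        if sex == "female":
            keep_fetal = female_fetal
        else:
            if len(male_fetal) > n_target:
                keep_fetal = pd.Index(
                    rng.choice(male_fetal.to_numpy(), size=n_target, replace=False)
                )
            else:
                keep_fetal = male_fetal
        # maintain the baseline maternal share relative to fetal cells
        if len(fetal) > 0 and len(maternal) > 0:
            n_mat = int(round(len(maternal) * len(keep_fetal) / len(fetal)))
            n_mat = min(n_mat, len(maternal))
            keep_mat = pd.Index(
                rng.choice(maternal.to_numpy(), size=n_mat, replace=False)
            )
        else:
            keep_mat = maternal
        selected = keep_fetal.append(keep_mat)
    if len(selected) == 0:
        raise ValueError(f"scenario {scenario!r} selects zero cells")

    sub = counts.subset_cells(selected)
    bulk = pd.Series(
        np.asarray(sub.matrix.sum(axis=1)).ravel(), index=counts.genes, name="pseudobulk"
    )
    types = pd.Index(sorted(meta["cell_type"].unique()), name="cell_type")
    tallies = meta.loc[selected, "cell_type"].value_counts()
    props = pd.Series(0.0, index=types, name="true_proportion")
    props.loc[tallies.index] = tallies.to_numpy(dtype=float)
    props /= props.sum()
    return bulk, props
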