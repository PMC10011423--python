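"""Synthetic single-cell datasets and case-control bulk cohorts.

The generator emulates the study design the pipeline targets: a multi-donor,
multi-batch single-cell map of a solid tissue (placental villous tissue is
the motivating case) with type-specific marker structure, fetal/maternal
origin and fetal sex labels; and a case-control bulk cohort in which case
status shifts cell-type proportions on the log-odds scale and additionally
perturbs a designated gene set directly. Everything the downstream stages
estimate - mixture proportions, prevalence odds ratios, direct expression
effects, and the mediated fraction of gene-level effects - is recorded as
ground truth, so the whole pipeline is testable without external data.

Counts follow a gamma-Poisson (negative binomial) model per gene and cell
type, the standard over-dispersed model for RNA counts. Case shifts are
applied as additive offsets to the log of a Dirichlet draw followed by
renormalization (logistic-normal style); a single-type shift of s multiplies
that type's proportion odds by exactly exp(s), which is the estimand the
beta-regression stage targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import sparse

from .containers import BulkExpression, CellCounts


def _default_alpha(k: int) -> tuple[float, ...]:
    # A few dominant types and a tail of rarer ones, loosely mirroring the
    # composition of term villous tissue (trophoblasts and stromal cells
    # dominant, immune subsets rare).
    base = np.array([8.0, 6.0, 5.0, 4.0, 3.0, 2.0, 1.5, 1.0])
    if k <= base.size:
        return tuple(base[:k])
    extra = np.full(k - base.size, 1.0)
    return tuple(np.concatenate([base, extra]))


def _default_shift(k: int) -> tuple[float, ...]:
    # Cases gain the first type (e.g. extravillous trophoblasts, POR ~ 2.5)
    # and lose the second and third (stromal/macrophage-like types).
    shift = np.zeros(k)
    shift[0] = np.log(2.5)
    if k > 1:
        shift[1] = -np.log(2.0)
    if k > 2:
        shift[2] = -np.log(1.5)
    return tuple(shift)


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults define a desk-scale cohort: 8 cell types over 2000 genes, six
    donors of 500 cells in two batches, and a 330-sample case-control bulk
    cohort (165 per arm) with gestational age 38.0 +/- 1.5 weeks in controls
    and 35.8 +/- 2.2 weeks in cases, reproducing the roughly two-week
    case-control gap reported in term preeclampsia cohorts and giving
    gestational age the exposure-induced-confounder role the mediation stage
    must handle.
    """

    n_genes: int = 2000
    n_cell_types: int = 8
    n_markers_per_type: int = 30
    marker_log2fc: float = 2.0
    n_donors: int = 6
    n_batches: int = 2
    batch_sd: float = 0.15
    cells_per_donor: int = 500
    base_dirichlet_alpha: tuple[float, ...] | None = None
    case_logodds_shift: tuple[float, ...] | None = None
    direct_effect_genes: tuple[str, ...] | None = None
    direct_effect_log2fc: float = 1.0
    n_samples_per_arm: int = 165
    bulk_noise_sd: float = 0.3
    dispersion: float = 2.0
    seed: int = 0
    # Cohort structure beyond the core knobs
    mean_library_size: float = 2000.0
    n_studies: int = 4
    maternal_types: tuple[int, ...] | None = None
    control_ga: tuple[float, float] = (38.0, 1.5)
    case_ga: tuple[float, float] = (35.8, 2.2)
    ga_expr_log2_slope: float = 0.01
    ga_proportion_slope: tuple[float, ...] | None = None
    dissociation_bias: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        k = self.n_cell_types
        if self.base_dirichlet_alpha is None:
            self.base_dirichlet_alpha = _default_alpha(k)
        if self.case_logodds_shift is None:
            self.case_logodds_shift = _default_shift(k)
        if self.maternal_types is None:
            # Last two types maternal; with the default alpha their expected
            # share is ~8%, so ~90% of cells are fetal, mirroring the heavy
            # fetal predominance of villous tissue.
            self.maternal_types = tuple(range(max(k - 2, 1), k))
        if self.direct_effect_genes is None:
            start = self.n_cell_types * self.n_markers_per_type
            stop = min(start + 20, self.n_genes)
            self.direct_effect_genes = tuple(
                f"G{i:05d}" for i in range(start, stop)
            )
        self.validate()

    def validate(self) -> None:
        for name in (
            "n_genes",
            "n_cell_types",
            "n_markers_per_type",
            "n_donors",
            "n_batches",
            "cells_per_donor",
            "n_samples_per_arm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        if self.n_markers_per_type * self.n_cell_types > self.n_genes:
            raise ValueError(
                "n_markers_per_type x n_cell_types exceeds the gene universe"
            )
        alpha = np.asarray(self.base_dirichlet_alpha, dtype=float)
        if alpha.size != self.n_cell_types or (alpha <= 0).any():
            raise ValueError(
                "base_dirichlet_alpha must be strictly positive with one "
                "entry per cell type"
            )
        shift = np.asarray(self.case_logodds_shift, dtype=float)
        if shift.size != self.n_cell_types:
            raise ValueError("case_logodds_shift must have one entry per type")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        universe = set(self.gene_ids())
        unknown = set(self.direct_effect_genes) - universe
        if unknown:
            raise ValueError(f"direct_effect_genes outside gene universe: {sorted(unknown)[:5]}")

    def gene_ids(self) -> pd.Index:
        return pd.Index([f"G{i:05d}" for i in range(self.n_genes)], name="gene")

    def type_names(self) -> pd.Index:
        return pd.Index([f"type{t}" for t in range(self.n_cell_types)], name="cell_type")

    def marker_table(self) -> pd.DataFrame:
        """Planted marker assignment: gene id, cell type, log2 fold-change."""
        rows = []
        genes = self.gene_ids()
        types = self.type_names()
        for t in range(self.n_cell_types):
            lo = t * self.n_markers_per_type
            for g in range(lo, lo + self.n_markers_per_type):
                rows.append((genes[g], types[t], self.marker_log2fc))
        return pd.DataFrame(rows, columns=["gene", "cell_type", "log2fc"])


@dataclass
class SimTruth:
    """Ground truth recorded by the bulk cohort generator."""

    true_proportions: pd.DataFrame  # samples x types, rows sum to 1
    true_por: pd.Series  # per type, population POR implied by the case shift
    true_direct_log2fc: pd.Series  # per gene
    mediation_truth: pd.DataFrame  # per gene: sum_alpha_beta, beta_a, pm_true

    def __post_init__(self) -> None:
        rowsum = self.true_proportions.sum(axis=1).to_numpy()
        if not np.allclose(rowsum, 1.0, atol=1e-9):
            raise ValueError("true_proportions rows must sum to 1 within 1e-9")


def _expected_rates(config: SimConfig) -> np.ndarray:
    """Relative expression per (gene, type, batch) before library scaling.

    Returns an array of shape (n_batches, n_cell_types, n_genes) whose rows
    sum to 1, so every cell has the same expected library size regardless of
    type or batch.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 11]))
    g, k, b = config.n_genes, config.n_cell_types, config.n_batches
    base = rng.lognormal(mean=0.0, sigma=1.0, size=g)
    type_factor = np.ones((k, g))
    boost = 2.0 ** config.marker_log2fc
    for t in range(k):
        lo = t * config.n_markers_per_type
        type_factor[t, lo : lo + config.n_markers_per_type] = boost
    batch_factor = np.exp(rng.normal(0.0, config.batch_sd, size=(b, g)))
    rates = base[None, None, :] * type_factor[None, :, :] * batch_factor[:, None, :]
    rates /= rates.sum(axis=2, keepdims=True)
    return rates


def type_mean_profiles(config: SimConfig, total: float = 1_000_000.0) -> pd.DataFrame:
    """Expected linear-scale expression per gene and type (batch-averaged).

    Each type profile is scaled to sum to ``total`` (counts-per-million by
    default, the usual scale of a bulk reference); this is the mixing matrix
    the bulk cohort generator uses, so planted log2 effects survive the
    log2(1 + x) transform essentially undistorted.
    """
    rates = _expected_rates(config).mean(axis=0)  # types x genes
    profiles = rates.T * total
    return pd.DataFrame(profiles, index=config.gene_ids(), columns=config.type_names())


def simulate_single_cell(
    config: SimConfig,
) -> tuple[CellCounts, pd.DataFrame, pd.Series]:
    """Draw a labeled multi-donor single-cell count matrix.

    Returns the counts, the per-cell metadata (donor, batch, origin, sex,
    technical replicate, cell type), and the per-cell true type labels
    (redundant with the metadata column, returned for convenience).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 23]))
    k = config.n_cell_types
    rates = _expected_rates(config)
    alpha = np.asarray(config.base_dirichlet_alpha, dtype=float)
    bias = (
        np.zeros(k)
        if config.dissociation_bias is None
        else np.asarray(config.dissociation_bias, dtype=float)
    )

    donor_sex = ["female" if d % 2 == 0 else "male" for d in range(config.n_donors)]
    cell_rows: list[pd.DataFrame] = []
    blocks: list[sparse.csr_matrix] = []
    cell_counter = 0
    for d in range(config.n_donors):
        batch = d % config.n_batches
        p = rng.dirichlet(alpha)
        if bias.any():
            logp = np.log(p) + bias
            p = np.exp(logp - logp.max())
            p /= p.sum()
        type_counts = rng.multinomial(config.cells_per_donor, p)
        for t in range(k):
            n_c = int(type_counts[t])
            if n_c == 0:
                continue
            mu = rates[batch, t] * config.mean_library_size  # per-gene mean
            lam = rng.gamma(config.dispersion, 1.0, size=(n_c, config.n_genes))
            lam *= mu[None, :] / config.dispersion
            counts = rng.poisson(lam)
            blocks.append(sparse.csr_matrix(counts.T))
            ids = [f"C{cell_counter + i:06d}" for i in range(n_c)]
            cell_counter += n_c
            origin = "maternal" if t in config.maternal_types else "fetal"
            sex = "female" if origin == "maternal" else donor_sex[d]
            rep = np.full(n_c, f"D{d}_repA", dtype=object)
            if d < 2:  # first two donors carry a technical replicate
                half = n_c // 2
                rep[half:] = f"D{d}_repB"
            cell_rows.append(
                pd.DataFrame(
                    {
                        "donor": f"D{d}",
                        "batch": f"B{batch}",
                        "origin": origin,
                        "sex": sex,
                        "technical_replicate": rep,
                        "cell_type": config.type_names()[t],
                    },
                    index=pd.Index(ids, name="cell_id"),
                )
            )
    meta = pd.concat(cell_rows)
    matrix = sparse.hstack(blocks, format="csr")
    counts = CellCounts(matrix, config.gene_ids(), meta.index)
    return counts, meta, meta["cell_type"].copy()


def _case_shift_proportions(p: np.ndarray, shift: np.ndarray) -> np.ndarray:
    logp = np.log(p) + shift
    out = np.exp(logp - logp.max(axis=-1, keepdims=True))
    return out / out.sum(axis=-1, keepdims=True)


def population_por(
    alpha, shift, n_draws: int = 200_000, _seed: int = 1234
) -> np.ndarray:
    """Population prevalence odds ratio implied by a log-odds shift.

    The beta-regression stage estimates the odds ratio of *mean*
    proportions, odds(E[p | case]) / odds(E[p | control]). Because the case
    shift acts on each Dirichlet draw before averaging, this population
    quantity differs slightly from exp(shift) whenever proportions vary
    across samples (Jensen's gap), and exactly equals it only in the
    zero-variance limit. Evaluated by fixed-seed Monte-Carlo integration
    (cached), so it is a deterministic function of (alpha, shift).
    """
    return _population_por_cached(
        tuple(np.asarray(alpha, dtype=float)),
        tuple(np.asarray(shift, dtype=float)),
        int(n_draws),
        int(_seed),
    ).copy()


@lru_cache(maxsize=64)
def _population_por_cached(
    alpha: tuple, shift: tuple, n_draws: int, _seed: int
) -> np.ndarray:
    alpha_arr = np.asarray(alpha, dtype=float)
    shift_arr = np.asarray(shift, dtype=float)
    rng = np.random.default_rng(_seed)
    p = rng.dirichlet(alpha_arr, size=n_draws)
    p1 = _case_shift_proportions(p, shift_arr)
    e0 = p.mean(axis=0)
    e1 = p1.mean(axis=0)
    return (e1 / (1.0 - e1)) / (e0 / (1.0 - e0))


def shift_for_por(target_por: float, type_index: int, alpha) -> float:
    """Log-odds shift for one type whose population POR equals the target.

    Inverts :func:`population_por` for a single-type shift by bisection, so
    a cohort built with the returned shift has a ground-truth prevalence
    odds ratio of exactly ``target_por`` for that type.
    """
    if target_por <= 0:
        raise ValueError("target_por must be positive")
    alpha = np.asarray(alpha, dtype=float)
    k = alpha.size

    def f(s: float) -> float:
        shift = np.zeros(k)
        shift[type_index] = s
        return np.log(population_por(alpha, shift)[type_index]) - np.log(target_por)

    from scipy.optimize import brentq

    lo, hi = (-8.0, 8.0)
    return float(brentq(f, lo, hi, xtol=1e-6))


def simulate_bulk_cohort(
    config: SimConfig, profiles: pd.DataFrame
) -> tuple[BulkExpression, pd.DataFrame, SimTruth]:
    """Draw a case-control bulk cohort mixed from type profiles.

    Per sample: proportions from Dirichlet(base_dirichlet_alpha); in cases
    the log-proportions are shifted by ``case_logodds_shift`` and
    renormalized. Bulk expression is proportions x profiles^T; designated
    direct-effect genes are multiplied by 2^direct_effect_log2fc in cases;
    gestational age enters every gene with a small uniform log2 slope; the
    matrix is then log2(1+x)-transformed with Gaussian noise of sd
    ``bulk_noise_sd`` added, and flagged log2-scale.
    """
    config.validate()
    if list(profiles.columns) != list(config.type_names()):
        raise ValueError("profiles columns must match the configured cell types")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 47]))
    k = config.n_cell_types
    n = 2 * config.n_samples_per_arm
    case = np.repeat([0, 1], config.n_samples_per_arm)
    sample_ids = pd.Index([f"S{i:04d}" for i in range(n)], name="sample_id")

    ga = np.where(
        case == 1,
        rng.normal(config.case_ga[0], config.case_ga[1], size=n),
        rng.normal(config.control_ga[0], config.control_ga[1], size=n),
    )
    ga = np.clip(ga, 24.0, 43.0)

    alpha = np.asarray(config.base_dirichlet_alpha, dtype=float)
    shift = np.asarray(config.case_logodds_shift, dtype=float)
    ga_slope = (
        np.zeros(k)
        if config.ga_proportion_slope is None
        else np.asarray(config.ga_proportion_slope, dtype=float)
    )
    p = rng.dirichlet(alpha, size=n)
    total_shift = case[:, None] * shift[None, :] + np.outer(ga - 38.0, ga_slope)
    p = _case_shift_proportions(p, total_shift)

    prof = profiles.to_numpy(dtype=float)  # genes x types
    mix = p @ prof.T  # samples x genes
    genes = profiles.index
    direct = genes.isin(config.direct_effect_genes)
    fc = np.ones((n, len(genes)))
    fc[:, direct] = np.where(
        case[:, None] == 1, 2.0 ** config.direct_effect_log2fc, 1.0
    )
    fc *= 2.0 ** (config.ga_expr_log2_slope * (ga - 38.0))[:, None]
    mix = mix * fc
    log2_expr = np.log2(1.0 + mix)
    if config.bulk_noise_sd > 0:
        log2_expr = log2_expr + rng.normal(0.0, config.bulk_noise_sd, size=mix.shape)

    bulk = BulkExpression(
        pd.DataFrame(log2_expr.T, index=genes, columns=sample_ids), scale="log2"
    )
    meta = pd.DataFrame(
        {
            "case": case,
            "gestational_age": ga,
            "fetal_sex": rng.choice(["female", "male"], size=n),
            "study": [f"study{i % config.n_studies}" for i in range(n)],
        },
        index=sample_ids,
    )

    truth = SimTruth(
        true_proportions=pd.DataFrame(p, index=sample_ids, columns=profiles.columns),
        true_por=pd.Series(
            population_por(alpha, shift), index=profiles.columns, name="true_por"
        ),
        true_direct_log2fc=pd.Series(
            np.where(direct, config.direct_effect_log2fc, 0.0), index=genes
        ),
        mediation_truth=_mediation_truth(config, profiles, p, case),
    )
    return bulk, meta, truth


def _mediation_truth(
    config: SimConfig, profiles: pd.DataFrame, p: np.ndarray, case: np.ndarray
) -> pd.DataFrame:
    """Linearized per-gene mediation decomposition implied by the generator.

    The exposure->mediator path alpha_a is the realized mean case-control
    difference in proportions; the mediator->outcome path beta_m,t for gene g
    is the derivative of log2(1 + sum_t p_t * profile_gt) in p_t at the
    control-mean composition; the direct path beta_a equals the planted
    direct log2 fold-change. pm_true = sum(alpha*beta) / (beta_a +
    sum(alpha*beta)), defined only when the denominator is nonzero.
    """
    prof = profiles.to_numpy(dtype=float)
    alpha_a = p[case == 1].mean(axis=0) - p[case == 0].mean(axis=0)
    p0 = p[case == 0].mean(axis=0)
    mix0 = prof @ p0  # genes
    beta_m = prof / (np.log(2.0) * (1.0 + mix0))[:, None]  # genes x types
    sum_ab = beta_m @ alpha_a
    beta_a = np.where(
        profiles.index.isin(config.direct_effect_genes),
        config.direct_effect_log2fc,
        0.0,
    )
    denom = beta_a + sum_ab
    with np.errstate(divide="ignore", invalid="ignore"):
        pm = np.where(np.abs(denom) > 1e-12, sum_ab / denom, np.nan)
    return pd.DataFrame(
        {"sum_alpha_beta": sum_ab, "beta_a": beta_a, "pm_true": pm},
        index=profiles.index,
    )


def simulate_mediation_cohort(
    n: int,
    alpha_a: np.ndarray,
    beta_m: np.ndarray,
    beta_a: float,
    *,
    confounder_on_exposure: float = 0.0,
    confounder_on_mediators: np.ndarray | None = None,
    confounder_on_outcome: float = 0.0,
    sigma_l: float = 1.0,
    sigma_m: float = 1.0,
    sigma_y: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Linear-Gaussian mediation cohort with closed-form effect truth.

    Structure: A ~ Bernoulli(1/2); baseline covariate C ~ N(0,1);
    L = confounder_on_exposure * A + 0.3 * C + eps_l (the exposure-induced
    confounder); M_j = alpha_a[j] * A + confounder_on_mediators[j] * L + eps_m;
    Y = beta_a * A + sum_j beta_m[j] * M_j + confounder_on_outcome * L
    + 0.2 * C + eps_y.

    Returns the cohort and the closed-form randomized-interventional effects:
    r_nde = beta_a + confounder_on_outcome * confounder_on_exposure,
    r_nie = sum_j beta_m[j] * (alpha_a[j] + confounder_on_mediators[j] *
    confounder_on_exposure), r_te their sum, pm = r_nie / r_te.
    """
    rng = np.random.default_rng(seed)
    alpha_a = np.asarray(alpha_a, dtype=float)
    beta_m = np.asarray(beta_m, dtype=float)
    kk = alpha_a.size
    lm = (
        np.zeros(kk)
        if confounder_on_mediators is None
        else np.asarray(confounder_on_mediators, dtype=float)
    )
    a = rng.integers(0, 2, size=n).astype(float)
    c = rng.normal(size=n)
    ell = confounder_on_exposure * a + 0.3 * c + rng.normal(0.0, sigma_l, size=n)
    m = (
        a[:, None] * alpha_a[None, :]
        + ell[:, None] * lm[None, :]
        + rng.normal(0.0, sigma_m, size=(n, kk))
    )
    y = (
        beta_a * a
        + m @ beta_m
        + confounder_on_outcome * ell
        + 0.2 * c
        + rng.normal(0.0, sigma_y, size=n)
    )
    data = pd.DataFrame({"exposure": a, "confounder": ell, "baseline": c, "outcome": y})
    for j in range(kk):
        data[f"M{j + 1}"] = m[:, j]
    r_nde = beta_a + confounder_on_outcome * confounder_on_exposure
    r_nie = float(beta_m @ (alpha_a + lm * confounder_on_exposure))
    r_te = r_nde + r_nie
    truth = {
        "r_te": r_te,
        "r_nde": r_nde,
        "r_nie": r_nie,
        "pm": r_nie / r_te if abs(r_te) > 1e-12 else np.nan,
    }
    return data, truth
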