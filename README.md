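# ctdeconv

Reference-based cell-type deconvolution of bulk tissue gene expression,
with downstream differential cell-type abundance, composition-adjusted
differential expression, and causal mediation analysis.

## The problem

Bulk expression profiles of heterogeneous tissue convolve two things: the
expression programs of the constituent cell types and the *proportions* in
which those types are present. In case–control studies of tissues such as
placental villi — where disorders like preeclampsia are suspected to shift
the balance between trophoblast, stromal, and immune populations — a gene
that appears "differentially expressed" in bulk tissue may simply mark a
cell type whose abundance changed. `ctdeconv` implements the full analysis
chain needed to disentangle these possibilities:

1. **Reference construction.** From labeled single-cell RNA-seq counts,
   per-type markers are found by one-vs-rest Wilcoxon rank-sum tests
   (BH-adjusted within each type, log₂FC on mean CP10K expression). The
   signature matrix **S** (genes × types, linear scale) unions each type's
   top-*G* markers at q < 0.01, sweeping *G* between a 300-gene floor and a
   500-gene ceiling and keeping the *G* that minimizes the condition number
   κ(S) = σ_max/σ_min of the column-normalized candidate — lower κ means a
   better-posed inverse problem.
2. **Deconvolution.** Each bulk profile **b** is modeled as **b ≈ S w**,
   **w ≥ 0**, solved by non-negative least squares or linear-kernel ν-SVR
   (ν ∈ {0.25, 0.5, 0.75}, best reconstruction kept), with weights
   normalized to proportions. Per-sample goodness of fit is the Pearson r
   and RMSE between **S w** and **b** over the signature genes, with an
   add-one permutation p-value (50 gene-label shuffles).
3. **Validation.** A 50/50 cell split with balanced type proportions:
   signature from the training half, pseudo-bulk mixtures of known
   composition from the test half (all cells, fetal-only, maternal-only,
   single-sex fetal scenarios), and recovery scored by Pearson r / RMSE.
4. **Differential abundance.** Each type's proportion is regressed on case
   status with beta regression (logit mean link, constant precision),
   adjusted for gestational age, fetal sex, and study source; exact zeros
   become (1/2)/n. The exponentiated case coefficient is a prevalence odds
   ratio with Wald CI.
5. **Composition-adjusted differential expression.** Gene-wise linear
   models with empirical-Bayes moderated t (limma-style inverse-χ²
   shrinkage of residual variances), run with and without the first five
   principal components of the proportion matrix as covariates;
   significance = BH q < 0.05 **and** |log₂FC| ≥ 0.1. Preranked GSEA on the
   moderated t is included.
6. **Mediation.** For a gene of interest, how much of the case–control
   expression difference flows *through* composition? Estimated by the
   g-formula with randomized-interventional analogs of natural effects —
   required because gestational age is an exposure-induced confounder of
   the mediator–outcome relation — with percentile bootstrap CIs:
   proportion mediated PM = r_NIE / r_TE.

A fully parameterized synthetic-cohort generator (`ctdeconv.simulate`)
produces single-cell datasets with planted marker structure and
case–control bulk cohorts with known proportions, abundance shifts, direct
expression effects, and mediation decomposition, so every stage is testable
end to end without external data.

## Worked example

```python
from ctdeconv import (SimConfig, simulate_single_cell, run_insilico_validation,
                      simulate_bulk_cohort, type_mean_profiles, deconvolve,
                      differential_abundance_all, proportion_pca, run_de_models,
                      lognormalize, one_vs_rest_markers, build_signature)
from ctdeconv.signature import type_profiles

cfg = SimConfig(seed=7)                      # 8 cell types, 2000 genes, 6 donors
counts, cells, _ = simulate_single_cell(cfg)

report = run_insilico_validation(counts, cells, scenario="all", seed=7)
print(f"pseudo-bulk recovery: r = {report.pearson_r:.3f} "
      f"(95% CI {report.ci95[0]:.3f}-{report.ci95[1]:.3f}), RMSE = {report.rmse:.4f}")

norm = lognormalize(counts)
sig = build_signature(type_profiles(norm, cells["cell_type"]),
                      one_vs_rest_markers(norm, cells["cell_type"]))
print(f"signature: {len(sig.genes)} genes, condition number = {sig.kappa:.2f}")

bulk, samples, truth = simulate_bulk_cohort(cfg, type_mean_profiles(cfg))
props = deconvolve(bulk, sig, method="nnls", seed=7)
abundance, _ = differential_abundance_all(props, samples)
row = abundance.loc["type0"]
print(f"type0 POR = {row.por:.2f} (95% CI {row.ci_lo:.2f}-{row.ci_hi:.2f}), "
      f"p = {row.wald_p:.2e}; generator truth = {truth.true_por['type0']:.2f}")

pcs = proportion_pca(truth.true_proportions)
_, summary = run_de_models(bulk.matrix, samples, pcs)
print(f"significant genes: base = {summary['base']['n_significant']}, "
      f"composition-adjusted = {summary['celltype_adjusted']['n_significant']}")
```

Output:

```
pseudo-bulk recovery: r = 0.993 (95% CI 0.960-0.999), RMSE = 0.0086
signature: 250 genes, condition number = 5.86
type0 POR = 3.11 (95% CI 2.77-3.49), p = 6.78e-84; generator truth = 3.03
significant genes: base = 127, composition-adjusted = 21
```

Reading the output: the train/test pseudo-bulk validation recovers the
known composition almost perfectly (r = 0.993); deconvoluted proportions
from the noisy bulk cohort detect the planted abundance shift of `type0`
(estimated POR 3.11 against a generator ground truth of 3.03); and of the
127 genes differentially expressed in the composition-naive model, only 21
survive adjustment for the five proportion PCs — 20 of which are exactly
the genes the generator perturbed directly, i.e. the adjustment removes
the composition-driven signal and keeps the genuine cell-intrinsic one.

## Command line

Every stage is also a subcommand of the `ctdeconv` console script:
`simulate`, `qc`, `signature`, `deconvolve`, `validate`, `abundance`,
`de`, `gsea`, `mediate`, and `pipeline` (YAML-configured end-to-end run
with stamped, reproducible artifacts). Run `ctdeconv COMMAND --help` for
the file formats: MatrixMarket + features/barcodes sidecars for single-cell
counts, genes-as-rows TSV for expression, CSV metadata with columns
`case`, `gestational_age`, `fetal_sex`, `study`, GMT gene sets.

## Methods

See `docs/methods.md` for model details, parameter defaults and their
rationale, what the synthetic generator does and does not emulate, and
known limitations.
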