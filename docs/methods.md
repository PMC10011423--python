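# Methods

This note documents the models implemented in `ctdeconv`, the defaults and
the reasoning behind them, what the synthetic-data generator emulates, and
the numerical choices that affect results.

## Single-cell preprocessing

Quality control removes cells failing any of three rules: total UMIs < 500,
detected genes < 200, or a mitochondrial mapping rate above the batch
median plus *k* scaled median absolute deviations (MAD × 1.4826, the
normal-consistency factor; *k* = 4 by default with a per-batch override,
since permissiveness is commonly tuned per batch). The mitochondrial rule
is one-sided: only high-mito cells are outliers of interest. The filter is
idempotent and reports per-rule and unique exclusion counts, because a cell
can trip several rules.

Normalization is library-size CP10K with log transform,
ln(1 + 10⁴·x/total), making a cell's profile invariant to sequencing
depth. Technical-replicate concordance is the Spearman correlation of
cluster-averaged normalized expression between replicate pairs within a
donor, summarized as mean ± sd across (cluster, pair) combinations.

The balanced split assigns ⌊n·fraction⌋ cells of each type to training and
the remainder (including the odd cell) to the test set — a fixed,
documented tie-break. Pseudo-bulk mixtures sum **raw** counts over the
selected cells, mimicking bulk library construction; normalization happens
inside the deconvolution step. The single-sex fetal scenarios keep the
baseline maternal share by down-sampling maternal cells proportionally, and
the male scenario additionally down-samples male fetal cells to the female
fetal count so the two sex mixtures are the same size.

## Signature construction

Markers are one-vs-rest per type: two-sided Wilcoxon rank-sum (exact for
small tie-free groups, normal approximation with tie correction otherwise),
log₂ fold-change defined as log₂((mean CP10K in + 1)/(mean CP10K out + 1)),
and BH adjustment within each type's family of gene tests. Within a type,
candidates are the q < 0.01 markers ranked by descending log₂FC, ties
broken lexicographically by gene id for determinism.

The signature matrix holds linear-scale (de-logged CP10K) type means,
because the mixing model is linear. Feature selection sweeps the per-type
count *G* from 300 to 500, forming the union of top-*G* lists
(union-then-deduplicate) and computing the 2-norm condition number of the
candidate matrix with columns scaled to unit Euclidean norm — scaling
without centering, so exactly orthogonal type profiles attain the ideal
κ = 1. The smallest κ wins; ties (within a 10⁻⁹ relative tolerance) go to
the smallest *G*. At desk scale, types typically have fewer than 300
significant markers, in which case all candidate sets coincide and the
floor is chosen.

## Deconvolution

Both solvers operate on shared genes only (intersection; absent genes are
dropped, never imputed; more than 50% missing is an error). NNLS runs on
the linear scale with unit-norm column scaling and unscales the weights
afterwards. ν-SVR (linear kernel, ν ∈ {0.25, 0.5, 0.75}, lowest
reconstruction RMSE wins) runs on a z-scored mixture against a *globally*
standardized signature — global rather than per-column standardization,
because per-column scaling folds each type's column sd into its weight and
biases the recovered proportions (measured: ~0.03 per-type error on
noiseless mixtures, versus < 10⁻² with global scaling). Negative SVR
weights are clipped to zero. Either way, weights are normalized to sum to
one, making estimates invariant to any positive rescaling of the mixture.

Per-sample fit statistics are the Pearson r and RMSE between the
reconstructed and observed mixture over shared genes, in the solver's fit
space. The permutation p shuffles the mixture's gene labels, re-solves, and
uses add-one smoothing: p = (1 + #{r_perm ≥ r_obs})/(1 + n_perm), with 50
permutations by default; r (not RMSE) is the permuted statistic.

## Differential abundance

Each modeled proportion follows Beta(μφ, (1−μ)φ) with logit(μ) = Xβ and
constant log-precision (no dispersion covariates). The design is intercept
+ case + gestational age + fetal sex + study dummies. Exact zeros map to
(1/2)/n and exact ones symmetrically to 1 − (1/2)/n; types at zero in every
sample are excluded and counted. Tests are two-tailed Wald at nominal 0.05
with no cross-type multiplicity correction; the prevalence odds ratio is
exp(β_case) with CI exp(β̂ ± 1.96·se). Maximum likelihood is delegated to
statsmodels' Beta regression (Newton, BFGS fallback).

A subtlety the generator must respect: the regression targets
odds(E[p|case])/odds(E[p|control]). A per-sample log-odds shift of *s*
multiplies each *sample's* odds by eˢ exactly (for a single shifted type),
but the odds ratio of the *mean* proportions is smaller than eˢ by a Jensen
gap whenever proportions vary across samples. `SimTruth.true_por` therefore
records the population quantity (fixed-seed Monte-Carlo integration over
the Dirichlet), and `shift_for_por` inverts it so a cohort can be built
with an exact target POR. With several types shifted at once, the
renormalization moves the other types' PORs off 1 — single-type shifts are
used wherever an exact truth is needed.

## Differential expression

Gene-wise OLS coefficients are untouched by moderation; only variances are
shrunk: s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d), with (d₀, s₀²) from matching the
mean and variance of log s²_g to a scaled-F model (trigamma inversion by
Newton with the asymptotic start; verified to machine precision against the
Bioconductor reference implementation). The moderated t has d₀ + d degrees
of freedom; d₀ = ∞ (no excess spread of log s²) collapses every posterior
variance to the common prior s₀², and a `prior_df` override exposes the
d₀ = 0 (no shrinkage) and d₀ = ∞ limits. Significance requires both BH
q < 0.05 and |log₂FC| ≥ 0.1, read conjunctively.

Composition adjustment appends the first five PCs of the proportion matrix
(column-centered, unscaled SVD; exactly five retained regardless of
variance explained, clamped only when a small cohort has fewer than six
types or samples). Preranked GSEA uses the weighted running sum (hit
increments |r|¹/Σ|r|¹, miss decrements 1/(N−N_h)), gene-label permutation
null, NES = ES / mean(|null ES| of matching sign), add-one permutation p,
and BH across sets — a documented simplification of the desktop tool's
NES-binned FDR.

## Mediation

Linear-Gaussian component models: L (confounder) on exposure + baseline;
each mediator on exposure + baseline + L; outcome on exposure + mediators +
L + baseline, optionally with exposure × mediator terms. Mediator residuals
are drawn independently across the five PC mediators (orthogonal in-sample,
so residual cross-correlation is negligible).

Randomized-interventional analogs replace each subject's counterfactual
mediator with a draw from the exposure-specific mediator distribution given
baseline covariates, simulating L under the relevant exposure first — the
construction that remains identified when the confounder is affected by the
exposure. Effects are differences of g-formula expectations
E[Y(a, G(a*))]; the proportion mediated is r_NIE/r_TE on the difference
scale, reported only when |r_TE| exceeds a tolerance and r_NIE shares its
sign (the raw ratio is always retained). The four-way decomposition
evaluates the controlled direct effect at the mean of G(0); the proportion
attributable to interaction is (INT_ref + INT_med)/r_TE, and the intended
workflow mirrors standard practice: run with interaction, and if the PAI
interval spans zero, report the no-interaction model as primary.

Residual draws use common random numbers across counterfactual arms.
Because the fitted outcome model is linear in mediators and confounder, the
shared draws cancel exactly in every effect difference: estimates carry no
Monte-Carlo noise, additivity r_TE = r_NDE + r_NIE holds to machine
precision, and the bootstrap can evaluate the expectations analytically
(zero residuals, one draw) with identical results — which is what the
bootstrap loop does for speed. The Monte-Carlo path (default 200 draws per
subject) is retained as the general mechanism and for transparency.
Confidence intervals are percentile bootstrap over subjects (1000
replicates by default; percentile rather than bias-corrected, as the
simplest well-understood default), seeded and reproducible; more than 5%
failed replicate fits is an error.

## Synthetic cohort generator

The generator emulates the target study design: a multi-donor, multi-batch
single-cell map with per-type marker structure and fetal/maternal + sex
labels, and a case–control bulk cohort whose case status shifts
composition and directly perturbs a designated gene set.

Counts are gamma-Poisson (negative binomial) per gene and type: relative
rates are a lognormal baseline × marker boost (2^marker_log2fc for a type's
exclusive markers) × lognormal batch factor (sd `batch_sd` on the log
scale), renormalized so every cell has the same expected library size
(2000 UMIs). Donor compositions are Dirichlet draws; each cell type is
wholly fetal or maternal (the last two types maternal by default, giving
~90% fetal cells, matching the strong fetal predominance of villous
tissue); maternal cells are female, fetal cells carry the donor's fetal
sex; the first two donors carry technical replicates. A dissociation-bias
knob (per-type log-odds depletion) exists but defaults to zero, as no
realistic magnitude is established.

Bulk cohorts: sample proportions are Dirichlet draws; cases receive an
additive shift on the log proportions followed by renormalization
(logistic-normal style, giving a clean per-sample odds shift). The mixture
is proportions × type profiles (profiles scaled to counts-per-million so
the log2(1+x) pseudocount is negligible — with profiles at single-cell
library scale, planted log₂ effects of 1.0 were compressed to ~0.1 for
low-expressed genes). Direct-effect genes are multiplied by
2^direct_effect_log2fc in cases; gestational age is Normal(38, 1.5) weeks
in controls and Normal(35.8, 2.2) in cases — reproducing the ~2-week
case–control gap typical of term preeclampsia cohorts and creating the
exposure-induced-confounder structure — and enters every gene with a small
uniform log₂ slope (0.01/week). Gaussian noise (sd 0.3 log₂ units, a
typical microarray residual scale) is added after the log transform.
Defaults: 8 types over 2000 genes, 165 samples per arm (n = 330, the scale
of the motivating application), 4 study sources, case shift = +log 2.5 on
the first type and moderate negative shifts on the next two (an
extravillous-trophoblast-up / stromal-down pattern), 20 direct-effect genes
at log₂FC 1.

Recorded ground truth: per-sample proportions, the population POR per type
(see above), per-gene direct effects, and a linearized mediation
decomposition (exposure→proportion shifts × the derivative of
log₂(1 + mixture) in each proportion at the control mean, against the
direct log₂ effect). A separate linear-Gaussian mediation generator
(`simulate_mediation_cohort`) provides closed-form randomized-analog
effects for exact validation of the mediation machinery.

What the generator does **not** emulate: ambient RNA, doublets, UMI
saturation, spatial structure, platform differences between the reference
and the bulk assay (probe effects, cross-platform batch structure), or
cell-type-specific *expression* changes in cases beyond the planted direct
effects. Passing tests therefore demonstrate correctness of the estimators
under the stated model, not robustness to cross-platform artifacts — the
proprietary cross-platform batch correction of the original deconvolution
tool is explicitly out of scope, and only a simple optional location/scale
alignment is contemplated.

## Numerical choices and limitations

- Wilcoxon p-values switch between exact and tie-corrected asymptotic
  automatically (scipy); constant genes get p = 1 by convention.
- Condition numbers treat σ_min ≤ 10⁻¹²·σ_max as singular.
- Beta-regression Wald coverage is slightly below nominal under the
  generator's logistic-shifted Dirichlet (the shifted marginal is not
  exactly Beta): measured 94.4% over 1000 replicate cohorts at n = 330 for
  a true POR of 2.5.
- Deconvolution estimates RNA-fraction proportions; they equal cell-count
  fractions only when types have similar RNA content per cell, as they do
  in the generator by construction.
- Deconvolution noise propagates into downstream abundance models as
  attenuation/inflation of case coefficients; the calibration suites
  therefore validate the regression machinery on true proportions and the
  full chain separately.
- Proportions summing to one make the K-th PC degenerate; PCA retains five
  of K−1 informative directions (K = 27 at full scale, 8 at desk scale).
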