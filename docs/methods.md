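# Methods

This note documents the models, estimators, and numerical choices behind
`fusesurv`, in the spirit of the methods documentation shipped by
statistical packages: what is computed, under which assumptions, with
which defaults, and what the simulation-based tests do and do not show.

## Cohort simulator

The simulator (`fusesurv.datagen`) emulates the structure of a bulk
RNA-seq tumor cohort with right-censored overall survival:

* **Latent co-expression programs.** Each sample draws standard-normal
  scores on `n_programs` latent programs; genes load sparsely on
  programs (≈35% nonzero loadings, N(0, 0.6)) on top of a per-gene
  log-baseline N(log 20, 0.8). Counts are negative binomial
  (gamma–Poisson) with a single shared dispersion (default 2.0), a
  deliberate simplification: marginal realism is not what downstream
  tests measure.
* **Survival.** The true linear predictor is
  `r = scores · β_programs + clinical_design · β_clinical` (exact, stored
  in `GroundTruth`). Event times follow Weibull proportional hazards,
  `T = (−log U / (λ e^r))^{1/k}` with shape k = 1.5 and rate λ = 0.1 by
  default.
* **Censoring.** Administrative: the censoring time is the empirical
  `1 − censoring_target` quantile of the event times, jittered
  uniformly by ±10%. This is deterministic, monotone in the target, and
  lands the realized censored fraction within a few points of the
  target. One consequence worth knowing: the censoring survival
  function G(t) stays ≈1 below the administrative cutoff, so on these
  simulations Uno's IPCW concordance nearly (often exactly) coincides
  with Harrell's — real cohorts with gradual censoring will separate
  the two.
* **Clinical covariates.** Age N(60, 10²), gender Bernoulli(0.5), and a
  4-level stage variable obtained by discretizing a noisy monotone
  function of the first program score — so stage carries genuine
  prognostic signal, as pathological staging does. A config flag emits
  stage as missing to exercise the 2-covariate clinical path.
* Default effect sizes (`β_programs = (1.0, 0.7, −0.5, 0.0)`,
  `β_clinical = (0.4, 0.2, 0.5)`, 30% censoring, n = 500) were chosen
  once to give a true-predictor Harrell C around 0.8 — the upper range
  of what strong prognostic models achieve on real cohorts.

What the simulator does **not** emulate: batch effects, cohort-specific
library-size distributions, gene-length effects, FFPE artifacts, or
realistic TCGA marginals. Tests passing on these cohorts demonstrate
correctness of the estimators and the training machinery, not expected
performance on real tumors.

## Preprocessing and gene screening

Library-size normalization scales every sample to a fixed total
(default 10 000) before log1p; a fixed target removes sequencing-depth
variation, which is the intent of the bulk-data pipelines this step
stands in for. Vocabulary alignment reindexes columns to a fixed gene
universe, zero-filling absent genes.

The univariate Cox screen fits one covariate at a time by
Newton–Raphson on the **Breslow** partial log-likelihood (tied times
share the full risk set), vectorized across genes on standardized
covariates, with damped steps (|Δβ| ≤ 2 per iteration), convergence at
|Δβ| < 1e−9, and a 50-iteration cap. P-values are Wald by default
(`2Φ(−|β̂/se|)`); a likelihood-ratio option exists. Degenerate genes
(constant, separated, or non-convergent) are flagged and assigned p = 1
rather than dropped, keeping column bookkeeping stable. Selection takes
the `N_g` smallest p-values with ties broken by ascending vocabulary
index. Screening receives only training rows by construction; the
selected index set is applied unchanged to validation and test.

## Mock encoder and adapter contract

The embedding provider contract: input is a masked full-vocabulary
profile; two total-count tokens equal to the profile sum are appended;
max pooling yields width H (default 768), "all" pooling width 4H
(3072); the last `N_u` of L layers may be unfrozen; `N_u = 0` is
bitwise-frozen. The mock realization embeds each token scalar as
`v·u + g_t` and applies L token-wise affine+tanh layers — smooth, cheap,
fully seeded, with hand-written backprop so unfreezing produces real
gradient flow. The "all"-pooling composition (mean, max, standard
deviation over tokens, plus the final count-token feature) is this
package's own construction honoring the 4H width relation; nothing
deeper should be read into it, and it is isolated behind the adapter
contract precisely because real encoders may pool differently. Test
configurations default to V = 64, H = 16, L = 4 for speed; the
constructor defaults (V = 19 264, H = 768, L = 12) mirror the scale the
contract is meant for.

## Risk model and training

The head is fixed at four FC blocks (1024/512/256/128; linear → dropout
0.2 → ReLU) plus a linear scalar output. The loss is the negative Cox
partial log-likelihood with `t_j ≥ t_i` risk sets (Breslow convention
for ties), summed over events by default; a mean-over-events reduction
is available for comparability of learning rates across cohort sizes.
The loss and its gradient are computed via a sorted log-cumsum-exp
(max-shifted), O(n log n).

Training: AdamW (decoupled weight decay), global gradient-norm
clipping, full-batch steps (per-cohort batches in pan-cancer training so
risk sets never straddle cohorts), grid search over learning rate
{2e−5, 2e−4, 2e−3, 2e−2}, weight decay {0.001, 0.01, 0.1, 0.25}, and
clip norm {0.1, 1, 2, 5}, up to 200 epochs. Model selection: validation
Harrell C (validation loss available as a switch), early stopping with
patience 10 (a default chosen here; nothing pins it), best-epoch weight
snapshots, and deterministic re-initialization per grid point from the
config seed. Grid points that diverge to a non-finite loss are marked
failed and skipped. Dropout noise is driven by the training RNG only;
evaluation-mode predictions are deterministic.

Splits are 70/15/15 with events and censored cases partitioned
separately (largest-remainder rounding, remainder ties resolved in
train → val → test order), so censoring proportions are consistent
across splits. Pan-cancer pooling concatenates already-split cohorts,
preserving split and cohort labels; gene screening and selection remain
per-cohort — pooling changes only the supervised training set, not the
feature construction.

Desk-scale problem sizes: the recovery analyses use n = 500, 60 genes,
`N_g` = 32, and a 2×2×1 sub-grid of the full hyperparameter grid; these
are the package's default demonstration sizes and run in seconds to a
few minutes on one CPU. The fusion-width contracts (3075 and 1795) are
checked at the full default widths since they cost nothing.

## Evaluation stack

* **Harrell's C**: over comparable pairs (the earlier time has an
  event; an event tied in time with a censored subject counts the
  censored one as surviving longer), concordant pairs score 1, tied
  predicted risks 0.5, tied event times 0.5. Extending the half-credit
  convention from tied times to tied predictions matches the packages
  commonly used for this statistic.
* **Censoring distribution**: Kaplan–Meier on censoring indicators
  (1 − δ) from the training cohort.
* **Uno's C**: event-anchored pairs with anchor time below the horizon
  τ weighted `G(tᵢ)⁻²`; anchors with G = 0 are excluded (logged). τ
  defaults to the 90th percentile of training follow-up, censored times
  included (follow-up, not event, time).
* **Time-dependent AUC**: cumulative/dynamic, cases = events by t
  (IPCW-weighted), controls = at-risk past t. **iAUC** integrates the
  AUC curve over unique event times in (0, τ] by plain trapezoid,
  normalized by the spanned interval; an event-density weighting is
  available behind a flag since the external packages this summarizes
  do not all share one convention.
* **Bootstrap CIs**: percentile intervals from stratified resampling
  (events and censored cases separately, 2000 draws), returning NA when
  events < 5 or > 20% of resamples are degenerate.
* **KM / log-rank**: standard product-limit estimate and two-group
  log-rank chi-square with 1 df.

All concordance and AUC estimators are validated in the test suite
against independently coded O(n²) enumerators and against lifelines /
scikit-survival to 1e−10 or better.

## Redundancy (mutual information)

Features are discretized into equal-frequency bins — `floor(n^{1/3})`
bins by default (integer truncation of the cube root, the convention of
the classic discretized-MI estimators; at n = 1000 this gives 9 bins),
ties assigned to the lower bin — and MI is the plug-in estimate on the
empirical joint table in natural-log units (nats). Term summation is
done in sorted order so that I(X;Y) = I(Y;X) holds bit-exactly. The
plug-in estimator is positively biased by roughly
(k_x−1)(k_y−1)/(2n) nats under independence; with the default binning
at n = 1000 that bias is ≈0.032, which is why independent pairs
reliably fall below the 0.05-nat sanity bound.

"Risk" embedding dimensions are those with univariate Cox p < .05;
"non-redundant" risk embeddings additionally have MI < 0.3 nats with
every other embedding dimension and every gene column. The per-cohort
summary contrasts two embedding sets (e.g. frozen vs pan-tuned
encoder): mean MI per set, ΔMI, ΔC-index, and a concordance flag set
when the lower-MI set also shows the higher C-index. The cohort-level
"mean MI" aggregates over feature pairs within a cohort; aggregating
over samples is not meaningful for a statistic defined between feature
columns, so the pair-wise reading is the default and only a labeling
switch.

## Attribution

Expected gradients: integrated gradients along the straight path from
each background baseline to the explained sample (midpoint Riemann rule,
`n_steps` = 64 default), averaged over a background of 50 training
samples. For linear models this is exact; for the ReLU head the
integrand is piecewise constant along the path, so completeness
(Σφ = RS − E[RS], with E[RS] the mean background prediction) is
enforced per explained sample at tolerance `1e−2·|RS − E[RS]| + 1e−4`
and violations raise with a pointer to increase `n_steps` (256 is
comfortably sufficient for the network sizes used here). Dropout is
disabled during attribution. Feature-type shares partition mean-|φ|
mass exactly over the fusion layout (embedding / gene / clinical
blocks); the cross-cancer stability statistic counts, per feature, the
cohorts where it ranks in the top `⌈0.2·F⌉` by mean |φ|.

## Enrichment

Genes are ranked by Spearman correlation (average-rank ties; constant
genes get ρ = 0 and a flag) with one embedding dimension, sorted
descending with ties broken by gene identifier. Preranked GSEA uses the
weighted Kolmogorov–Smirnov running sum (hit steps ∝ |score|^p with
p = 1, miss steps uniform; the sum returns to zero exactly), a
gene-label permutation null (default 1000 permutations, shared across
sets of equal size within a call), NES = ES / mean |null ES| of
matching sign, and Benjamini–Hochberg FDR over the permutation
p-values. BH-over-permutation-p is deterministic at small permutation
counts, unlike the classic null-distribution FDR, and is the documented
divergence from the original GSEA procedure. Gene sets are supplied as
GMT; no ontology content is bundled. Median-split stratification puts
samples strictly above the median in the "high" group and warns when
more than half the values tie at the median.

## Known limitations

* The mock encoder has no attention and no pretrained knowledge; it
  exercises contracts (widths, determinism, unfreezing, gradient flow),
  not representation quality.
* Absolute survival probabilities are not calibrated anywhere; all
  evaluation is rank-based discrimination.
* The plug-in MI estimator's bias grows with bin count; comparisons are
  only meaningful at a fixed discretization.
* Permutation p-values are lower-bounded at 1/(n_perm + 1); small
  n_perm coarsens the FDR.
* The simulator's administrative censoring makes IPCW weights nearly
  trivial; censoring-robustness of Uno's estimator is exercised by the
  oracle tests, not by the simulation defaults.
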