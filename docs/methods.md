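# Methods

This note documents the statistical models, the synthetic-cohort generator,
the numerical choices and the known limitations of `remodelnet`.

## Study design being modeled

The pipeline targets a two-cohort biomarker-discovery design. A *test cohort*
of 32 acute-infarction patients, split 16/16 by 4-month ejection fraction
(EF ≤ 40 % = LV dysfunction, "low"; EF > 40 % = "high"), is profiled on
two-channel oligonucleotide arrays (~25,000 genes, log₂ patient/reference
ratios against a common reference RNA). A *validation cohort* of 115 patients
carries clinical covariates (age, sex, time to reperfusion, troponin T,
creatine phosphokinase) and a candidate biomarker. Discovery proceeds from
differential expression through an angiogenesis annotation filter and
protein-interaction clustering to small gene panels evaluated as classifiers;
validation uses association tests and reclassification statistics.

## Preprocessing

* **Lowess normalization** removes intensity-dependent dye bias: M is replaced
  by M − f(A) where f is a locally weighted regression of M on A
  (statsmodels lowess, tricube weights). Defaults: span 0.4, 3 robustness
  iterations — the method is standard but its parameters are a package
  choice; results are insensitive over spans 0.3–0.6 on smooth inputs.
* **Replicate presence filter**: a gene is kept when non-missing on at least
  3 of 4 hybridization replicates ("present" = non-missing; spot-quality
  flags are upstream of the inputs this package reads). Dye-swap replicates
  have M negated before the retained replicates are averaged — the natural
  combination rule when the fluorophores are exchanged.
* **Patient presence filter**: keep genes non-missing in at least
  ⌈fraction × n⌉ samples, boundary inclusive (exactly 50 % presence is kept).
  Both filters are idempotent and never alter retained values.

## Differential expression

Fold changes are geometric: per-class means are taken on the log₂ scale and
`FC = 2^(x̄_low − x̄_high)`; a gene is called at threshold t when FC ≥ t or
FC ≤ 1/t (default t = 1.3). A gene with an empty class is reported
not-evaluable rather than silently passed.

The SAM statistic is `d_i = (x̄_low,i − x̄_high,i)/(s_i + s₀)` with `s_i` the
pooled standard error and s₀ the exchangeability constant chosen by the
standard percentile search: candidate s₀ values at the 0, 5, …, 100th
percentiles of s are scored by the coefficient of variation of the
window-wise MAD of d (about 100 equal-occupancy windows of s), and the
minimizer is kept; with fewer than 100 genes the fallback is s₀ = median(s).
The null distribution is built from class-label permutations — all distinct
splits when there are no more than the requested number (e.g. all C(6,3) = 20
for a 3 vs 3 design), otherwise a seeded sample of distinct splits. Per gene
we report a permutation p-value (fraction of permutations with |d*| ≥ |d| for
that gene) and a q-value: the median across permutations of the pooled count
of permuted |d*| exceeding the gene's |d|, divided by the observed count,
clipped to [0, 1] and made monotone in |d|. No π₀ estimate is applied, which
makes the q-values mildly conservative (the simulated null call rate at
q ≤ 0.05 is well below 5 %). A variance floor of 1e-8 guards constant genes.

Top-k ranking uses the two-class signal-to-noise ratio
`(x̄_low − x̄_high)/(s_low + s_high)` — the default phenotype-ranking metric of
the standard gene-set analysis tool — with lexicographic tie-breaking for
determinism.

## MCODE complex detection

Vertex weighting, expansion and post-processing follow the classic
molecular-complex-detection algorithm. The weight of v is k × density of the
highest k-core of the subgraph induced by v and its neighbors (loop-free
density 2E/(n(n−1)); a clique K_n gives weight n − 1). Complexes grow from
the highest-weight unassigned seed, admitting neighbors whose weight is at
least (1 − vwp) × seed weight (default vwp 0.2); each vertex joins at most one
complex. Complexes without a 2-core are discarded; haircut (default on) trims
the complex to its 2-core, so every reported member has internal degree ≥ 2;
fluff (default off) appends unassigned neighbors whose closed-neighborhood
density exceeds a threshold. The score is density × size, and ordering is
deterministic (score, then size, then seed id). If post-processing
disconnects a complex, the component containing the seed is kept.

One behavior worth knowing: two equally dense modules joined by a *direct*
bridge edge merge into a single complex at any vwp, because both bridge
endpoints carry the full module weight. Planted-structure recovery is
therefore assessed on the union of planted members in the tests.

## Ridge-penalized logistic panels

`RidgeLogit` minimizes −log-likelihood + (ridge/2)·‖w‖² with the intercept
unpenalized, by damped Newton/IRLS (step-halving on the penalized deviance;
convergence when the largest coefficient update falls below 1e-8, cap 100
iterations). The default ridge of 1e-8 leaves the fit essentially
unpenalized but keeps coefficients finite on separable data; fitted
probabilities may then saturate at 0/1, which is the honest behavior of a
near-unpenalized model at n = 32 and is handled by exact ties in the midrank
AUC. The linear predictor is clipped at ±500 (beyond float saturation of the
logistic) so that saturated predictions tie exactly rather than carry
meaningless sub-resolution orderings across folds.

Subset evaluation pools out-of-fold probabilities from seeded stratified
10-fold cross-validation into a single ROC (pooling is more stable than
per-fold AUC averaging at n = 32). Missing expression values are imputed by
training-fold gene means, and features are standardized with training-fold
parameters only, so no information leaks from held-out samples. All subsets
share one fold assignment, making AUCs directly comparable. Every subset of
size 1..3 of the candidate panel (plus the full panel) is enumerated;
ranking is AUC descending, ties by smaller size then lexicographic ids.
AUC is the tie-corrected midrank Mann-Whitney statistic; TPR/FPR are taken
at the 0.5 probability cutoff.

## Validation statistics

* **Spearman**: midrank ρ; exact two-sided p by full rank-permutation
  enumeration for n ≤ 9, else the t approximation.
* **Mann-Whitney**: midrank U; exact two-sided p by enumeration over all
  C(n, n_a) group assignments when n ≤ 12 (the usual exact method does not
  cover ties; enumeration over midranks does), else the tie-corrected normal
  approximation.
* **Fisher exact** on 2×2 tables with the sample odds ratio.
* **Single-marker association**: OLS of EF% on the marker (or logistic on the
  EF class), plus the marker's ROC AUC for the low-EF class, oriented by the
  marker's own association direction so an informative marker scores > 0.5.
* **Clinical model**: logistic regression of the low-EF class on age, sex
  (female indicator) and time to reperfusion, optionally plus a marker,
  fitted with the same tiny ridge; Wald p-values per covariate; AUC of fitted
  probabilities; classification table at 0.5. A marker duplicating a
  covariate is permitted (the ridge keeps the fit defined and the
  probabilities unchanged) but flagged as collinear; constant covariates are
  rejected.
* **Classification tables** are stored true-class × predicted-class with
  percent correct per true class (reported rounded half-up to 1 decimal,
  unrounded retained). Cases are EF ≤ 40 %, controls EF > 40 %, and "up"
  reclassification means crossing the probability threshold toward predicted
  low EF.
* **NRI** comes in two modes. The individual mode applies the definition to
  paired per-patient probabilities. The net-from-tables mode is an explicit
  approximation when only marginal 2×2 tables are available: change in
  correct cases over n_cases plus reduction of misclassified controls over
  n_controls. It equals the individual NRI only when movement within each
  class is unidirectional; individual crossings are unobservable from
  marginals.

## Synthetic cohorts

`SimulationConfig` defaults encode the emulated design: 25,000 genes,
16 + 16 samples, 525 planted differentially expressed genes (299 up in the
low-EF group) with per-gene log₂ effects uniform between log₂(1.3) and 1.0,
Gaussian noise SD 0.4 on the log₂ scale, 5 % missingness completely at
random, a 494-gene annotation overlapping the planted set by 28 (20/8 by
direction), a 441-node interactome with planted near-clique modules of sizes
(16, 12, 9) at internal edge probability 0.95 over a background edge
probability 0.0025 (yielding ≈ 460 edges), and a planted predictive trio —
three up-in-low genes with a 2-noise-SD shift placed inside the first module
and inside the annotation overlap. Non-trio module members are drawn from
annotated non-differential genes (interaction partners need not be
differentially expressed). Test-cohort EF is uniform within the class ranges
45–73 % (high) and 20–40 % (low).

The validation cohort (61 low / 54 high EF) ties EF to covariates through a
Gaussian copula: latent correlations are 2·sin(πρ_s/6) for continuous margins
(Spearman targets: age −0.35, time to reperfusion −0.26, TnT −0.25, CPK
−0.25, biomarker −0.28), and the binary sex margin (15 % female, target
+0.20) gets the analytic point-biserial inflation √(p(1−p))/φ(Φ⁻¹(p)) to
offset dichotomization attenuation. Marginals: age ~ Normal(60, 12) truncated
to [32, 90]; time to reperfusion ~ LogNormal(median 3.5 h, σ 0.6) truncated
at the 12-hour enrollment cap; TnT and CPK ~ truncated LogNormals spanning
the observed ranges (0.03–26.1 ng/mL, 602–9383 U/L); biomarker ~ LogNormal.
EF values are assigned rank-monotonically (lowest latent ranks → uniform in
[15, 40], rest → (40, 86]) so class counts are exact and Spearman targets are
preserved. Under this construction a Spearman of −0.28 with the 61/54 split
implies a marker AUC near 0.63.

What the generator does *not* emulate: probe-level two-channel quantification,
dye-swap structure and spatial artifacts; gene–gene expression correlation
(genes are independent given class); informative missingness; covariate
correlations beyond each variable's link to EF. Passing tests therefore
demonstrate correctness of the algorithms under the declared statistical
structure, not performance on real arrays.

## Problem sizes in tests and the acceptance script

Unit tests use scaled-down studies (hundreds to a few thousand genes); the
acceptance checks run the full default study (25,000 genes × 32 samples,
100 SAM permutations) across 20 seeds, and the acceptance script uses 10
recovery seeds, 5 null-simulation seeds and 10 clinical seeds — sizes chosen
to keep a complete run in the minutes range on one CPU while leaving the
Monte-Carlo rates stable to a few percent.

## Known limitations

* At a per-gene 2-SD planted effect and n = 32, pooled-CV AUCs of the trio
  and its sub-pairs saturate at 1.0; with ranking ties resolved toward
  smaller subsets, the exact planted trio is rarely the single top-ranked
  subset even though its AUC is high — exhaustive enumeration at this sample
  size exhibits a strong winner's curse. The reliable recovery statement is
  about the trio's own cross-validated AUC, not its exact rank.
* SAM q-values omit π₀ estimation and are conservative.
* The net-from-tables NRI is an approximation by construction.
* Published complex scores from nested cluster listings cannot be reproduced
  by any loop-free simple-graph scoring; the package reports the standard
  density × size score.
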