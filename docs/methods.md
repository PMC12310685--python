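# Methods

## Overview

`drsynergy` implements a resistance-informed feature framework for drug
combination synergy regression. Its premise: a drug's **resistance
signature** — the per-gene expression difference between cell lines that
resist the drug and cell lines sensitive to it — is a functional
representation of the drug that predicts combination synergy better than
chemical structure bits or the plain drug-induced expression signature.
The package provides the signature derivation, symmetric pair-feature
assembly, a classical regressor panel, a stratified repeated
cross-validation protocol, over-representation analysis for interpretation,
and an exhaustive pair-ranking screen. A seeded synthetic-cohort generator
with planted ground truth makes every stage testable end to end.

## Sensitivity labeling

For each drug, cell lines are split at the median of that drug's IC50
values: IC50 below the median is *sensitive*, at or above the median is
*resistant* (ties at the median are resistant). The median is per-drug, not
global; with an even number of lines it is the midpoint of the two central
order statistics. The split is invariant to positive rescaling of the IC50s
(so concentration units do not matter), and degenerate all-equal inputs
yield an all-resistant labeling rather than an error.

## Signatures

Both signatures are per-gene mean differences with identical testing
machinery:

* **DS** (drug signature): `delta = mean(treated) − mean(control)`, so
  "up" means drug-induced. A `flip_sign` flag exposes the opposite
  orientation for callers who prefer it.
* **DRS** (drug resistance signature):
  `delta = mean(resistant) − mean(sensitive)`, so "up" means
  resistance-associated. The expression compartment representing a cell
  line is a parameter: the drug-treated profile (default) or the untreated
  baseline. Both carry the planted signal in the synthetic cohorts, and
  both are supported because either convention is defensible for real data.

Treated samples are first filtered to a canonical condition (dose
"10uM", time "24h" by default — the stamp the generator writes), keeping
all controls.

Per gene we use a two-sided Welch (unequal-variance) t-test; moderated /
empirical-Bayes statistics are deliberately out of scope. Multiple testing
is Benjamini–Hochberg step-up across genes. A gene is called "up" when
`delta ≥ delta_threshold` (strictly positive), and `q ≤ q_threshold`
(defaults 0 and 0.05); "down" mirrored. Genes with zero within-group
variance in *both* groups get `p = 0` if the means differ (else 1) and are
flagged `degenerate` rather than propagating NaNs.

## Pair-feature assembly

A drug is represented by its fingerprint bit vector (*structure* regime) or
by its signature delta vector over a gene subset (*DS* / *DRS* regimes; the
subset defaults to the union of genes significant for any drug). Two drug
vectors are combined order-invariantly — the encoding is not dictated by
any convention, so we chose one with a testable symmetry:

* `sum_absdiff` (default): `[f(A)+f(B), |f(A)−f(B)|]`, dimension
  `2·|subset|`, exactly invariant to pair orientation;
* `sorted_concat`: concatenation in lexicographic drug-id order.

Optionally a cell line's basal expression (mean over its control samples)
over the same gene subset is appended as cellular context. The regime
comparison gives every regime identical context features, so regimes differ
only in the drug representation. Rows whose drugs (or cell lines, when
context is on) lack a representation are dropped and counted in the
provenance, never silently.

## Models

LASSO (penalty chosen by internal 5-fold CV over a 50-point alpha grid),
AdaBoost (100 estimators), Random Forest (200 trees, leaf size 2) and
XGBoost (200 trees, depth 4, learning rate 0.1, hist method). All defaults
are fixed in `synergy_models.DEFAULT_HYPERPARAMETERS` and embedded verbatim
in the fitted state; all learners are seeded and single-threaded for exact
reproducibility. A constant training target triggers a warning and a
constant predictor. Prediction rejects any feature-name/order mismatch with
the training schema. External score tables (e.g. from a deep model trained
elsewhere) can be evaluated through the CV protocol without retraining by
passing the vector in place of a model spec.

## Evaluation protocol

Stratified k-fold cross-validation for a continuous target: synergy scores
are quantile-binned (10 bins by default; bins with fewer than k members are
merged into a neighbor), and each bin is shuffled and dealt round-robin into
k = 5 folds, so per-fold target distributions match the global one. The
whole split is repeated 10 times with seeds `base_seed + r`. Metrics per
held-out fold: MSE, RMSE, R², Pearson, Spearman, and AUC where predictions
rank the binary label `y_true ≥ 10` (the conventional synergy-score
threshold); one-class folds record AUC as missing. Aggregates are the mean,
SD and 95% t-interval (n−1 df) over repeat-level means; a single repeat
yields a point CI flagged degenerate. Models are compared by a two-sided
paired t-test over repeat-level means, valid because fold plans are a pure
function of (target, k, bins, seed) and hence shared.

Feature standardization, when requested, is refit on each training split —
a mutation test asserts that corrupting test rows cannot change the fitted
model. Signatures themselves are computed once from the expression/IC50
cohort, not per fold: those data are disjoint from the synergy labels being
predicted, so this is not target leakage.

## Enrichment

Over-representation of a query gene set in GMT-defined pathways uses the
one-sided hypergeometric upper tail `P(X ≥ k | N, K, n)` with the universe
N = genes measured in the signature table (not the genome), BH-adjusted
across pathways. Ranked (GSEA-style) tests are out of scope. Volcano tables
report `−log10 p` with `p = 0` mapped to the largest representable value
and flagged.

## Pair ranking

All C(n,2) unordered pairs (no self-pairs) are scored per cell line with a
fitted model; output sorts by predicted score descending with lexicographic
(drug_a, drug_b) tie-breaks, so ranked tables are fully deterministic and
invariant to input drug order. Unrepresentable drugs are excluded with a
logged ledger in the screen's provenance.

## Synthetic cohorts

The generator emulates the statistical structure the framework assumes, not
any particular platform. Latent per-cell-line *program activities*
`a[p,c] ~ N(0,1)` drive everything:

* baseline expression of a program's genes is shifted by
  `resistance_effect · a[p,c]` (default 1.5 SD) on top of N(0,1) gene means
  and N(0, `noise_sd`=1) noise;
* each drug targets one program (round-robin);
  `log IC50[d,c] = a[p(d),c] + N(0, 0.3)`, so high program activity ⇒ high
  IC50 ⇒ resistant, and the median split recovers the program's sign;
* treated samples add a `perturbation_effect` (1 SD) on the drug's program
  genes plus fresh noise, stamped dose "10uM" / time "24h" so the
  canonical-condition filter is exercised;
* synergy `s = 5 + 10 · 1[p(d1) ≠ p(d2)] · z(a[p(d1),c] + a[p(d2),c]) +
  N(0, 2)`: a bonus only for complementary-program pairs, scaled by the
  standardized combined activity — synergy lives where resistance lives;
* fingerprints are Bernoulli(0.5) bits with no synergy signal, making the
  structure regime an informative negative control.

Defaults: 1000 genes, 80 cell lines, 10 drugs, 4 programs × 25 genes. These
sizes keep the default analyses and the test suite at desk scale (the full
regime comparison runs in about two minutes on one CPU) while leaving the
planted effects at realistic magnitudes: a 1.5 SD resistance shift across a
40/40 split yields per-gene t-statistics near 10, comfortably detectable,
whereas the 1 SD treatment perturbation is partially masked by the 1.5 SD
resistance variance, giving the DS regime the weaker (but non-trivial)
recovery one would expect. The recovery benchmark uses a single 100-gene
program because a drug's DRS can only recover its *own* program's genes.

What the generator does **not** emulate: landmark-gene inference, dose
response curve shapes, correlated gene-gene noise, batch structure,
mixtures of programs per drug, or chemically meaningful fingerprints.
Passing tests therefore demonstrate that the pipeline recovers the signal
class it is designed for — not that real LINCS/GDSC/DrugComb data contain
such a signal at these magnitudes.

One caveat surfaced by the truth tables: fingerprint bits uniquely identify
drugs, so a flexible learner given structure features plus cellular context
can still partially memorize per-pair effects. The structure regime is
"noise" in the sense of carrying no generalizable synergy mechanism, not in
the sense of being uninformative to a memorizing model; the DRS margin in
the regime comparison is measured against this honest baseline. Relatedly,
in cell lines where all program activities are negative, the generative
truth itself places same-program (near-baseline) pairs at the top of the
screen — complementarity enrichment among top-ranked pairs is expected in
the predicted-synergistic set, not uniformly in every cell line.

## Numerical choices and degenerate inputs

* Even-count medians are midpoints; median ties label resistant.
* BH is the standard step-up; q-values are monotone in p-rank and ≥ p.
* Welch p-values with both groups constant are defined by the mean
  difference (0 or 1) and flagged.
* R², Pearson, Spearman and AUC are reported as missing (NaN) when
  undefined (constant vectors, one-class labels) instead of raising.
* Quantile bins with duplicate edges are dropped; bins smaller than k are
  merged leftward.
* All RNG flows through `numpy.random.default_rng` seeds carried in configs;
  tree learners run single-threaded with fixed `random_state`.

## Known limitations

* No moderated t-statistics; with very few replicates per group the Welch
  test is underpowered relative to empirical-Bayes alternatives.
* The DRS compartment choice (treated vs. baseline) changes real-data
  results; both are implemented but only the synthetic cohort guarantees
  they agree.
* The classical panel's hyperparameters are fixed defaults, not tuned per
  dataset; the deep multi-modal model family is intentionally not
  implemented (external predictions can be evaluated via the score-table
  hook).
* Leave-drug-out / leave-cell-line-out generalization is out of scope; the
  CV protocol measures interpolation over (pair, cell line) rows.
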