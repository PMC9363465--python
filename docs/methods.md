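# Methods

## Single-sample enrichment and the FPS

The per-sample enrichment score is a rank-weighted cumulative walk.  Within a
sample, genes are ranked by descending value; a gene at average rank *k* from
the top carries weight r = N + 1 − k, ties sharing the mean of their rank
span.  Walking down the ranking, in-set genes advance the hit curve by
r^α normalized over the set's total weight, out-of-set genes advance the miss
curve by 1/(N − |S|), and the score is the sum of (hit − miss) over all
positions — the area between the two curves, not their maximal gap.  α
defaults to 0.25; at α = 0 the score depends on ranks only and is invariant
under any strictly monotone transform of the expression values.  The walk
order among exactly tied values is fixed by gene id so scores are
deterministic.

The ferroptosis score is the difference of enrichments, FPS = ES(pro) −
ES(anti).  The main alternative, mean z-score of pro genes minus mean z-score
of anti genes, is available as `method="zmean"`; the two orderings agree
closely on simulated cohorts (rank correlation > 0.9) but the enrichment form
is the default because it is rank-based, single-sample and robust to the
scale of each gene.  Scores are cohort z-scaled into `fps_z` (population SD);
no per-sample min-max normalization is applied by default.

Dichotomization is at the cohort median: strictly above the median is
`high`, everything else (including exact ties at the median) is `low`.  An
even cohort therefore splits in half, e.g. 62 samples into 31/31.

Samples missing more than half of the signature genes keep their score but
are flagged `group = NA` and excluded from group-based tests.

## Signature screening

Candidate genes arrive annotated with a biological role (pro- or
anti-ferroptosis).  Screening tests each candidate's overall-survival
association — `logrank_median` (log-rank on the gene's median split, the
default) or `cox_continuous` (univariate Cox Wald p) — and keeps genes with
p below the threshold (default 0.05, raw p; Benjamini-Hochberg adjustment is
available behind `adjust="bh"`).  The annotated role is never flipped by the
screen: the role encodes ferroptosis biology while the screen only tests
outcome association.  Hazard direction is reported for audit.  Screening is
invariant to candidate order (candidates are processed in sorted-gene order).

## Statistical primitives

Implemented from their definitions in `ferroscore.stats`; scipy supplies only
distribution tail functions.

- **Wilcoxon rank-sum** — exact enumeration of the U distribution when the
  combined n ≤ 10 without ties, otherwise a normal approximation with tie
  correction and continuity correction (both toggleable).  Two-sided by
  default, as are all tests in the package.
- **2×2 chi-square** — Yates continuity correction on by default; it is the
  convention under which the package's contingency analysis of a 22/9 vs
  11/20 responder table prints p = 0.01.
- **Spearman** — average ranks, t-approximation for p.
- **BH-FDR** — step-up with suffix-min enforcement, order-preserving.
- **Kaplan-Meier** — product-limit; subjects censored at an event time are
  kept in the risk set at that time (censoring processed after events), the
  standard convention, verified against lifelines.
- **Log-rank** — (ΣO − E)² / ΣV with the hypergeometric variance per
  distinct event time.
- **Cox partial likelihood** — Newton-Raphson with step-halving so the log
  likelihood never decreases; convergence at |ΔlogL| < 1e-9 or 50
  iterations; Efron tie handling by default (Breslow available).  Monotone
  likelihood (a covariate perfectly ordering the events) is reported as
  `converged=False` with a diagnostic rather than a silently huge
  coefficient; the detection criterion is a standardized coefficient
  exceeding 20.  A score test at β = 0 is provided; with a binary covariate
  and no tied events it equals the log-rank chi-square, which the tests
  verify to 1e-8.

## Propensity-score matching

The propensity model is logistic regression fitted by iteratively reweighted
least squares (convergence |ΔlogL| < 1e-10 or 100 iterations); categorical
covariates are one-hot encoded (drop-first), constant columns dropped with a
warning.  Perfect separation is detected (fitted probabilities pinned to the
labels) and flagged, with propensities clipped to [1e-6, 1 − 1e-6].

Matching is greedy 1:1 nearest-neighbour without replacement on the
logit-propensity scale with a caliper of 0.2 × the pooled-across-groups SD of
the logit propensity — the dominant convention in the matching literature.
High-FPS samples are processed in descending propensity order; distance ties
break lexicographically by sample id, so matching is fully deterministic.
Balance is reported as standardized mean differences using the pre-match
pooled SD for both before and after, so the two numbers share a scale.

Differential testing runs the two-sided Wilcoxon rank-sum between matched
high and low samples per feature (unpaired by design — robust to pair-level
missingness; a signed-rank variant exists behind `paired=True`), with
BH-FDR within each omics layer, since layer-wise significant counts are the
quantity of interest.  Effects are mean(high) − mean(low): log2 fold change
for expression/protein layers, delta-beta for methylation.  Significance
requires q below the threshold and |effect| at or above the effect threshold;
the effect threshold defaults to 0 (q-only) and both thresholds are recorded
in the run summary.

## Pre-ranked GSEA

Features are ranked by sign(effect) × (−log10 p), ties broken by |effect|
then id.  The enrichment score is the classic weighted Kolmogorov-Smirnov
walk (hit steps ∝ |score|^weight, weight 1 by default; miss steps uniform),
taking the running-difference extreme of larger magnitude.  Significance uses
a gene-label permutation null — appropriate because the input is a pre-ranked
list from matched tests, so sample permutation is unavailable — with null
sets drawn per set-size class and shared within a class.  NES divides ES by
the mean |null ES| of the same sign; the empirical two-sided p compares |ES|
against the |null| distribution with a +1 pseudo-count, so p is never exactly
zero; q is BH across the collection.  nperm (default 1000) and the seed are
recorded.  The null-walk extremes are computed in closed form at hit
positions only, which the tests verify against the position-by-position walk.

## Immune associations

- CYT is the geometric mean of GZMA and PRF1 on the linear scale (input is
  un-logged from log2(x+1); pseudocount 1 by default).
- GEP is a weighted mean of the 18-gene T-cell-inflamed panel on the log
  scale with uniform default weights, renormalized over the measured subset;
  at least 80% of the panel must be measured.  Published weights can be
  supplied as a user file.
- Response analysis builds the high/low × R/NR table and applies the Yates
  chi-square; survival splits report Kaplan-Meier curves per group, the
  log-rank p and which group survives longer.
- BCR/TCR richness, TIL fraction and PD-L1 protein are consumed as
  precomputed per-sample features; deriving them from repertoire or image
  data is out of scope.

## Synthetic cohorts

The generator draws a latent ferroptosis activity f ~ N(0,1) per sample and
a confounder c = ρf + √(1−ρ²)ε (ρ = `confounder_strength`, default 0.5),
surfaced as tumor purity (a logistic squash of c) and an ordinal stage.  A
feature's value is λf + γc + noise: signature genes use λ = ±`loading_strength`
(default 1.0, 16 pro + 16 anti genes — a signature of 32, the scale of
curated ferroptosis panels), planted differential features use λ chosen so the
expected high-vs-low group difference equals `planted_effect` (default 1.5)
noise SDs, and confounder-only features use γ analogously with λ = 0.
Expression layers sit on a log2 scale around baseline 6; methylation latent
values pass through a logistic squash so beta values stay in (0,1).  Survival
is exponential with log-hazard log(h₀) − `hazard_beta`·f (default baseline
1/700 per day, β = 0.7 — median survival around 16 months at f = 0, in the
range of metastatic melanoma cohorts) with uniform early censoring applied to
a `censor_rate` fraction (default 0.3).  Response is Bernoulli with logit
`response_slope`·f (default 1.5, which gives high-vs-low response contrasts
of the size seen in responder-enriched cohorts).

`generate_icb_cohort` conditions a 62-sample cohort on exactly 33 responders
by calibrating the logistic intercept to the target count and
rejection-sampling Bernoulli vectors until the count is exact — the true
conditional law — then re-draws progression-free survival so responders
progress more slowly (`pfs_response_hr`, default 0.4).
`generate_confounded_pair` adds 50 confounder-only features per layer and
returns the latent-median group labels, the stress test behind the matching
step: on such cohorts the naive group comparison shows false-positive rates
near 1 on confounder-only features while the matched analysis stays near the
nominal level.

What the generator does **not** emulate: single-cell dropout and library-size
structure, spatial autocorrelation, batch effects, gene-gene correlation
beyond the shared latent factors, and non-proportional hazards.  Passing
tests therefore demonstrate correctness of the algorithms under the assumed
generative structure, not robustness to every real-data pathology.

## Problem sizes and determinism

Simulation-based checks use compact cohorts (60-200 samples, 100-1000
features, 100 seeds for calibration and confounding studies, 1000
permutations for GSEA), sizes at which every targeted effect is comfortably
detectable.  All randomness flows from explicit seeds — `numpy` Generators
created from the config seed or a CLI `--seed` — and repeated runs are
byte-identical, which the tests assert on CLI outputs.

## Known limitations

- No stratified or time-varying Cox, no competing risks.
- Matching is greedy 1:k without replacement only; no optimal matching or
  weighting estimators.
- GSEA p-values are bounded below by 1/(nperm+1); no multilevel refinement.
- Gene identifiers are matched case-sensitively after whitespace trimming
  (an alias map file can bridge id dialects); the default namespace is gene
  symbols.
- Dense text matrices only; no HDF5/sparse ingestion.
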