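# Methods

`ensemblemark` studies a failure mode of transcriptomic biomarker validation:
the same cohort, classifier and endpoint can yield a significant or a null
hazard ratio depending on how the raw probe intensities were pre-processed.
The package implements the whole loop at desk scale — a synthetic probe-level
cohort generator, the factorial of 24 pre-processing schedules, the two
marker classifiers, stage-adjusted survival evaluation, closed-form power,
and the ensemble method that converts cross-schedule disagreement into a
per-patient confidence metric.

## Synthetic cohort model

`CohortSpec` / `generate_cohort` emulate a four-site lung-adenocarcinoma
validation cohort (default 111 + 111 + 110 + 110 = 442 patients; stage mix
26% IA, 37% IB, 21% II, 16% III).

**Survival.** Event times are exponential. Patient `j` with stage `s` and
latent prognosis group `g ∈ {good, poor}` has hazard

    λ_j = λ0 · stage_hr[s] · planted_hr^{1[g = poor]}

with `λ0 = ln 2 / baseline_median_survival` (default median 60 months for a
good-prognosis stage-IA patient) and default stage multipliers
(1.0, 1.4, 2.0, 2.8). Latent group (fair coin) is independent of stage, so
the *stage-adjusted* Cox hazard ratio between latent groups is exactly
`planted_hr`; the exponential family makes proportional hazards hold
exactly, including after five-year truncation. Censoring is independent
exponential with the per-patient rate `μ_j = λ_j · c/(1−c)` so the censoring
probability is exactly `censor_rate = c` (default 0.47, matching a cohort
with 236/442 events).

**Expression.** Gene `g`'s true log2 expression in patient `j` at site `s` is

    base_g + effect_g · 1[j poor] + batch_{s,g} + N(0, biological_sd)

Baselines are Uniform(5, 11); marker and housekeeping genes draw from
Uniform(8, 11) — signature genes are by construction measurable above
optical background, and housekeeping genes are canonically highly expressed.
The planted effect is a ±`effect_log2` shift (default 1.0) with signs
(+, +, −) on the three-gene markers and (+, +, +, −, −, −) on the six-gene
markers. Batch shifts are drawn per (site, gene) at `batch_shift_sd`
(default 0.3): an array-wide per-site constant would be absorbed entirely by
quantile and housekeeping normalization, leaving separate-vs-combined
handling with nothing to disagree about, whereas gene-level batch structure
is what multi-site microarray studies actually report.

**Probes.** Every gene has a primary 11-probe ProbeSet and, with probability
0.5, a secondary one. A probe with affinity `a_p` (N(0, 0.7)) and GC
fraction `gc_p` (Uniform(0.25, 0.75)) reads

    intensity = 2^(signal + a_p + N(0, noise_sd_j)) + bg · (0.5 + gc_p) · 2^N(0, 0.3)

`noise_sd_j` is *probe-level measurement noise* (default 0.5; patients
flagged by `high_noise_fraction` use `high_noise_sd`, default 2.5). Placing
this noise at the probe level is load-bearing: each summarization algorithm
weights the same noisy probes differently (median polish vs Tukey biweight
vs multiplicative ALS vs a different ProbeSet under the alternative
annotation), so higher probe noise directly produces cross-schedule
disagreement — the phenomenon the ensemble method exploits — and mean
concordance decreases monotonically in `noise_sd`. Noise placed at the
gene × patient level instead is shared by all schedules and produces
consistently wrong, falsely "robust" calls. The strictly positive background
grows with GC fraction, giving GC-aware correction real signal to exploit.

**Annotations.** The default map designates each gene's primary ProbeSet.
The alternative map (emulating updated Entrez-based ProbeSet definitions)
designates the secondary ProbeSet where one exists, drops 10% of genes and
swaps the ProbeSets of another 10%, never touching marker or housekeeping
genes so every schedule stays runnable.

What the generator does *not* emulate: real probe-sequence chemistry
(mismatch probes, saturation), correlated gene modules, non-proportional
hazards, informative censoring, or stage-dependent marker effects. Passing
tests therefore demonstrate that the analysis machinery behaves as designed
under its stated model, not that any particular biomarker validates in real
data.

## Pre-processing schedules

A schedule is (algorithm, log2 flag, annotation, handling):
4 algorithms — of which RMA/GCRMA are log2-only and MAS5/MBEI run in both
natural and log2 space (6 variants) — × 2 annotations × 2 handling modes
= 24, enumerated in lexicographic (algorithm, scale, annotation, handling)
order so ensemble columns are reproducible. The algorithm cores are
documented simplifications of the vendor pipelines (the study object is
sensitivity to algorithm *families*, not vendor-exact internals):

- **RMA**: background subtraction (per-array mode of the dimmest-quartile
  intensity distribution, floored at 0.5 × the smallest positive value) →
  quantile normalization (sorted values replaced by mean order statistics;
  ties get the mean of their candidate values) → log2 → per-ProbeSet Tukey
  median polish (row sweep first, ≤ 10 iterations, 1e-8 relative tolerance
  on total absolute residual; midpoint convention for ties). The ProbeSet
  value per array is the overall effect plus the column effect.
- **GCRMA**: as RMA, but the per-probe background is a monotone function of
  GC content: log2 intensity is regressed on GC fraction among the dimmest
  quartile of probes (per array) and the prediction subtracted in natural
  scale with the same positivity floor.
- **MAS5**: PM-only signal `2^biweight(log2 probes)` per ProbeSet per array
  (one-step Tukey biweight about the median, MAD scaling, c = 5,
  eps = 1e-4), then each array scaled so its 2%-trimmed mean equals 500 (the
  vendor convention; any constant works — classifiers median-normalize).
  The ideal-mismatch machinery is omitted.
- **MBEI (Li–Wong)**: arrays median-scaled to a common median after optional
  pseudo-count addition, then each ProbeSet fitted with the multiplicative
  model `intensity ≈ φ_i · θ_j` by alternating least squares with
  `Σφ² = n_probes`, convergence at 1e-6 relative change in θ or 100
  iterations (non-convergence warns and returns the last iterate). The
  SE-based probe-outlier rejection of the original procedure is omitted.

`handling = combined` merges all sites before one pass; `separate` runs per
site and classification then uses per-site medians, pooling the calls.
Gene-level values are the designated ProbeSet's row under the chosen
annotation. MAS5/MBEI natural→log2 variants are the elementwise log2 of the
natural output, so the driver computes each (algorithm, annotation,
handling) cell once.

## Classifiers

Markers are normalized housekeeping-first: subtract the per-array mean
housekeeping log2 level (divide by the geometric mean in natural scale),
then centre each marker at its across-patient median (divide by the gene
median in natural scale). These operations commute with log2, so the
natural-scale path equals `2^` of the log2 path.

**Three-gene rule.** Indicators are 1 iff the normalized value is *strictly*
above the cohort median (values at the median count as below — "above the
median" read strictly); `RiskScore = 4·m1 + 3·m2 − 3·m3`; good iff
score ≤ 2. Medians come from the classification cohort: per site under
separate handling, everyone under combined. Because median dichotomization
is invariant to strictly increasing transforms, the log2 flag (and any
per-gene "statistical scaling") cannot change three-gene calls — this is
property-tested. The rule never leaves a patient unclassified.

**Six-gene rule.** Euclidean distances of the normalized six-gene vector to
two fixed cluster centers; `r = d_good/d_poor` assigns the nearer label
unless `r` lies in the closed ambiguity band [0.9, 1.11], in which case the
patient is unclassified and ignored downstream. (The band is treated as
closed; boundary hits have probability zero on continuous data.) The
centers of such a classifier are training-cohort constants that no synthetic
cohort shares, so `generate_cluster_centers` produces synthetic stand-ins:
per-group means of normalized six-gene vectors over a training split, with
normalization computed within the split only so the centers depend on no
other patient. Centers live in
log2-normalized scale; natural-scale schedules compare against their
elementwise `2^c`, so the log-transform factor genuinely changes six-gene
calls while leaving three-gene calls invariant.

## Survival evaluation

Overall survival is truncated at 60 months (late events recoded as censored
at the horizon). Cox fits maximize the partial likelihood with Efron tie
handling (the common default; the choice is documented rather than
load-bearing), poor = 1 vs good = 0, stage entering as indicator covariates
with IA as reference — covariate adjustment rather than stratification, so
the group effect is a single hazard ratio. HR = exp(β), 95% CI =
exp(β ± 1.96·SE), p from the Wald z. A call group without events is a
monotone-likelihood case and raises `NonIdentifiableError`; within-stage
subgroup fits are unadjusted. Five-year binary metrics use *raw* survival:
poor+died ≤ 60 → TP, poor+survived → FP, good+alive at 60 → TN, good+died →
FN; censoring before 60 months excludes the patient (counted), censoring at
exactly 60 counts as alive; empty denominators yield `None`, never silent
0/0.

The univariate screen median-dichotomizes every feature under every
schedule and fits the binary-covariate Efron partial likelihood with a
package-authored vectorized Newton solver (`BinaryCoxEngine`; the survival
structure is factorized once, so thousands of feature × schedule ×
permutation fits stay cheap). It is cross-checked against lifelines to 1e-6
and against a brute-force likelihood grid to 1e-4 in the test suite. Raw
p ≤ 0.05 with no multiplicity correction, deliberately: the quantity of
interest is how often a feature *recurs* across schedules, not a corrected
discovery set.

## Power

`schoenfeld_power(NE, HR, α) = Φ(√NE · |ln HR| / 2 − z_{1−α/2})` — two-sided,
equal allocation; `|ln HR|` makes protective markers (HR < 1) valid queries.
At HR = 1 the value is exactly α/2. Power curves run over HR 1.00–2.50 in
0.01 steps and report the smallest grid HR reaching power 0.8. The
Monte-Carlo cross-check follows 8·NE patients per replicate until the NE-th
event (type II censoring) and counts two-sided log-rank rejections: fixing
the event count while keeping risk sets near equal allocation is the regime
the formula describes; an all-events design (N = NE) lets the allocation
drift and sits visibly below the formula at small NE.

## Ensemble robustness

Each patient is a vector of 24 calls. Robust ⇔ all calls identical and none
unclassified — an unclassifiable schedule is itself discordant evidence, so
it breaks unanimity. Ambiguous patients are evaluated with the reference
schedule's call (RMA, default annotation, separate handling — the original
protocol); ambiguous patients the reference schedule left unclassified are
excluded from that fit and reported. A generalized majority-vote mode with
agreement threshold τ ∈ (0.5, 1] is provided for ensembles of other sizes;
τ = 1 reproduces strict unanimity exactly (tested). Concordance is the
fraction of schedules agreeing with the majority call, with ties broken in
(good, poor, unclassified) order.

## Numerical and scale choices

- Simulations in tests and the acceptance suite run at reduced scale chosen
  as the package's own desk-scale defaults: recovery of the planted hazard
  ratio uses 50 replicates of the full 442-patient design (14 genes, since
  only survival is consumed); ensemble-robustness replicates use 4 × 60
  patients and 20 genes; the sensitivity screen uses 240 patients, 30 genes
  and 20 permutations.
- All randomness flows from `numpy.random.default_rng(seed)`; a fixed spec
  is bit-reproducible, and `run_study` manifests record SHA-256 hashes of
  every output.
- Known limitations: vendor pipelines are simplified as described; the
  six-gene centers are synthetic placeholders; the generator's independence
  assumptions (genes, patients, censoring) are idealized; no FDR control in
  the screen by design.
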