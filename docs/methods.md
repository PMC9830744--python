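# Methods

`survens` implements homogeneous ensemble feature selection for
right-censored survival data: a base selector is fit on many bootstrap
resamples of a training fold, the resulting ranked feature lists are
aggregated into one ranking or one subset, a threshold separates the
relevant features, and a ridge-penalized Cox model fit on the survivors
is scored on the held-out fold. Stability of the selected subsets and
held-out concordance are the two evaluation axes.

## Model and assumptions

Survival data are (xᵢ, tᵢ, δᵢ) with tᵢ > 0 the follow-up time and
δᵢ ∈ {0,1} the event indicator (δ = 0 censored). All model fits assume
proportional hazards, h(t|x) = h₀(t)·exp(xᵀβ), and random censoring
independent of covariates. Features are continuous, Boolean or
categorical; categoricals are one-hot expanded at fit time and any
per-dummy importance is mapped back to the original feature as the
maximum absolute score over its dummies, so all ensemble bookkeeping is
per original feature.

Within every cross-validation fold, continuous features are z-scored
with mean/sd estimated on the training rows only (sample sd, ddof = 1;
zero-sd features map to all-zeros and are flagged), and missing values
are filled by a train-fitted median/mode imputer (a pluggable hook — a
chained-equations imputer can be substituted through the same
fit/transform contract). Nothing outside the training rows touches any
fitted parameter; a test asserts this leakage guard directly.

## Base selectors

* `unicox` (filter): each feature's score is Harrell's C-index of a
  single-covariate Cox fit on that feature alone. Because the fit picks
  the direction that suits the sample, null features score slightly
  above 0.5 in-sample (≈0.53 at m = 60); this is a property of the score
  definition, not a bug, and the probe machinery is tested against a
  paired null rather than against 0.5 exactly.
* `lasso` / `enet` (sparse): L1/elastic-net penalized Cox
  (`CoxnetSurvivalAnalysis`); scores are |coefficients| (comparable
  because the data are normalized first), the selected set is the
  nonzero support. The regularization strength is chosen by the
  `CVPenalty` policy by default: a short alpha path, 3-fold internal
  cross-validation scored by held-out Breslow partial log-likelihood,
  internally seeded. A deterministic `PathFractionPenalty`
  (coefficients at the alpha nearest 0.25·alpha_max) and a
  `FixedPenalty(alpha)` are provided for reproducible unit tests and
  speed-critical runs; penalty choice is the main runtime knob, since
  the default costs four path fits per selector call.
* `glmboost` (sparse): componentwise gradient-boosted Cox; coefficient
  magnitudes as scores, nonzero support as the subset.
* `rsf` (filter): random survival forest scored by permutation
  importance; negative importances are clipped to 0 so scores can enter
  weight aggregation.
* A likelihood-based boosting selector has no adapter in this
  environment; requesting it raises a registry error listing what is
  available. Any callable returning a valid `SelectorResult` can be
  registered alongside the built-ins.

## Random probes

One probe per continuous and per categorical feature — an independent
permutation of that column — is appended to each bootstrap sample and
re-permuted on every bootstrap iteration. Boolean features get no
probe: a permutation of a two-valued column leaves many entries fixed,
so such probes inherit real signal. Probes participate in selection and
aggregation like ordinary features; the probe threshold is applied to
the aggregated ranking, and probes are stripped from every final subset
regardless of threshold. Probe names are namespaced
(`__probe__<source>`).

## Aggregators

All per-list rankings order features by score descending with the
feature name as a deterministic tiebreak. Sparse selectors contribute
partial lists; unlisted features take the worst rank (normalized rank
1) and score 0, which makes every aggregator total.

* **Mean rank (MR)** — arithmetic mean of per-list ranks; equivalent to
  a Borda count (verified on random instances). Its reported score is
  |universe|+1 − mean rank so "higher is better" holds for the
  score-based thresholds.
* **Mean weight (MW)** — arithmetic mean of importance scores.
* **Robust Rank Aggregation (RRA)** — normalized rank = position /
  |universe| (features + probes), so the null is uniform on (0,1]. For
  each feature with sorted normalized ranks r(1) ≤ … ≤ r(n) over n
  lists, ρ = min_k β_{k,n}(r(k)) with β the binomial tail
  Σ_{l≥k} C(n,l)x^l(1−x)^{n−l}, computed through the survival function
  for numerical stability. Features with ρ below the chosen p-value are
  selected; ρ is reported uncorrected by default (a Bonferroni ×n flag
  reproduces the original RRA significance correction). The uncorrected
  null is anti-conservative — P(ρ < t) ≥ t — which a simulation test
  documents.
* **Threshold Algorithm (TA)** — Fagin-style top-k over the
  score-sorted lists with a sum aggregate: at depth d the stopping
  threshold is the sum of the d-th scores; any feature first seen gets
  its full aggregate by random access; the scan stops when the current
  k-th best aggregate reaches the threshold. Equal to brute-force
  top-k-by-total-score on every instance of an exhaustive small sweep.
* **MedRank (MA)** — sequential access by depth, visiting lists in
  index order (a documented determinism convention); a feature is
  output the moment it has appeared in more than 20% of the lists
  (fraction configurable; 20% suits weak signals where few features
  appear in half the lists), stopping once k features are out.

k for TA/MA defaults to the round-half-up mean of the per-list subset
sizes; filter ensembles have no natural subset length, so k falls back
to ⌈0.25·p⌉ with a warning.

## Thresholds

Applied to the aggregated ranking of MR/MW (RRA/TA/MA threshold
themselves and refuse a separate threshold). Every threshold returns a
subset of the original, non-probe features; degenerate empty selections
fall back to all features with a logged warning so the downstream model
can always be fit.

* **fixed:f** — top round-half-up(f·p) features, probes excluded from
  both the count and the result.
* **q75** — features strictly above the 75% quantile (linear
  interpolation) of the aggregated scores.
* **kde** — Gaussian kernel density estimate of the 1-D score
  distribution; cluster centres are local maxima, and assuming most
  features are irrelevant, the highest peak is the irrelevant cluster.
  The cut is the first local minimum above that peak; features strictly
  above it survive. Bandwidth is Silverman's rule 0.9·sd·m^(−1/5) — the
  sd form, not the IQR-robust variant, because with ~90% of scores in
  one tight cluster the IQR collapses to the within-cluster spread and
  the undersmoothed density splits the irrelevant cluster, letting
  stragglers past the cut. If the density has a single maximum the
  bandwidth is shrunk by 0.75 and re-estimated (≤10 times, a bounded-
  runtime choice); once multimodal the estimate is final, and if no
  minimum lies above the top peak no thresholding is performed. The
  density is evaluated on 512 grid points over [min−3h, max+3h], with
  plateau-aware sign-change extrema detection (between well-separated
  clusters the density underflows to exactly zero). On unimodal score
  distributions this procedure finds no valid cut in roughly a third to
  a half of random samples and otherwise cuts above the main peak; the
  fallback keeps all features either way.
* **probe** — features scoring strictly better than the best probe's
  aggregated score; a feature tying the best probe is discarded
  (conservative reading of "ranked below"). Sparse special case: if no
  probe was ever selected in any bootstrap there is nothing to compare
  against, and everything the sparse ensemble selected is kept.

## Stability metrics

Kuncheva's index (pairs of equal-size subsets), Lustgarten's adjusted
measure (unequal sizes) and Somol–Novovičová relative weighted
consistency CW_rel (whole systems, the harness headline, because final
subsets vary in size). CW_rel uses D = N mod |Y| and H = N mod n with N
the total occurrence count over n subsets; a `d_convention` flag
switches D to n mod |Y| for comparison with renderings that state the
remainder that way. Degenerate zero denominators (e.g. every subset
equal to the universe) return 1.0 if all subsets are identical, else
0.0, with a warning. All three metrics are verified against independent
brute-force formula evaluations on exhaustive small systems, and CW_rel
is fuzzed to stay in [0,1].

## Evaluation harness

`run_experiment` executes, per fold of an event-stratified k-fold CV
repeated R times (default 5×5 → 25 final subsets): normalize and impute
(train-fitted) → B bootstrap samples (default 50) → probe injection per
bootstrap → base selector per bootstrap → aggregate → threshold → strip
probes → ridge-Cox fit (L2 `CoxPHSurvivalAnalysis`, fixed default
alpha = 1.0 for determinism) on the selected features → Harrell's C on
the held-out fold. Folds are stratified by event indicator because at
93% censoring unstratified folds can easily contain no events.
`run_individual` is the non-ensemble baseline: one selector fit per
fold (sparse selectors supply their own subset and reject a threshold;
filters require one). Both runs share folds under the same master seed
for paired comparison.

Harrell's C counts a pair comparable iff the earlier time had the event
(equal times: exactly one event); risk ties count ½. The combined model
score is the Euclidean distance √(CW_rel² + mean C²), both coordinates
on their natural [0,1] scales, unweighted. Consensus features across a
collection of runs: rank models by Euclidean score, call a feature
"selected by a model" when it appears in more than half of that model's
fold subsets, and report features selected by at least `min_fraction`
(default 0.5, optionally 0.8) of the top `top_n` (default 10) models.

## Seeding

One master seed drives everything through
`SeedSequence(master, spawn_key=(repeat, fold, bootstrap, stream))`
paths: CV assignment, each bootstrap draw, each probe permutation and
each selector's internal seed derive independent, individually
reproducible streams. Identical configuration + seed gives
byte-identical result JSON.

## Synthetic data

The generator emulates the statistical shape of ageing-cohort studies
(defaults: m = 873, p = 140 of which 100 continuous / 25 Boolean / 15
categorical, 8 prognostic features with log-hazard 1.0, 93% target
censoring) without reproducing any real study's variables or
correlation structure. Event times follow a proportional-hazards model
with exponential baseline (rate 1/baseline_scale, default mean event
time 10 years at η = 0), linear predictor η = Σβⱼxⱼ over the planted
continuous features; Booleans are Bernoulli(0.5), categoricals uniform
over 3–5 levels, and an optional equicorrelation among continuous
features runs through a shared Gaussian factor. Censoring times are
independent exponentials whose rate is found by monotone root search so
that mean(1 − exp(−c·tᵢ)) over the drawn event times equals the target
censoring fraction (for iid Exp(1) event times this recovers the closed
form c/(1+c)). An optional administrative horizon (off by default)
emulates a fixed study length. What passing tests on these data do not
show: robustness to informative censoring, longitudinal structure,
real-world correlation patterns or missingness mechanisms beyond
completely-at-random.

## Scaled-down evaluation conditions

The packaged end-to-end comparison (tests and `scripts/acceptance.py`)
runs on replicate cohorts of m = 300 with p = 60 (44/8/8 by kind),
8 planted features at β = 1.0 and 50% censoring, using B = 20 bootstraps
with the penalized-Cox selector and RRA at p = 0.15 against the
individual selector on shared folds — sizes chosen so a full replicate
set completes in minutes on one core while leaving the stability
contrast measurable. Under these conditions the ensemble matches the
individual pipeline's held-out concordance to well within 0.03 and is
at least as stable on most replicate cohorts.

## Known limitations

* The univariate filter's in-sample C-index is biased above 0.5 for
  null features at small m (see above).
* CW_rel's remainder terms make it non-monotone under subset-size
  changes; duplicating a subset is only guaranteed not to lower it when
  the replaced subset has the same size.
* The KDE threshold assumes the irrelevant features dominate; with a
  majority of relevant features the highest peak is the wrong cluster
  and the cut is meaningless.
* The probe threshold needs at least one non-Boolean feature.
* MedRank's output order depends on the (fixed, documented) within-depth
  list order; permuting list order can reorder ties.
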