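# Methods

This note documents the models, the numerical choices, and the design
decisions behind `seqimp`, and states what the synthetic generators and the
test suite do and do not establish.

## Data model

A `SequencePanel` is an n×T matrix of integer state codes over an ordered
`Alphabet`, with `-1` marking a missing (imputable) cell and `-2` structural
padding for ragged input (excluded from every statistic). Panels with a
fully missing sequence are rejected: every algorithm here conditions on at
least one observed cell per sequence. All user-facing time indices are
1-based inclusive.

A **gap** is a maximal run of missing cells. Given predictor-window sizes
(np, nf), gaps are classified as *internal* (≥ np contiguous observed cells
before and ≥ nf after), *initial* (starting at t=1), *terminal* (ending at
t=T), or *left-/right-/both-hand* when the flanking observed runs fall short
of the window on one or both sides. Flank counts are **contiguous** observed
cells only: a neighbouring gap truncates availability, which is the operative
constraint given the stage order below.

## MICT

One imputation pass runs four stages:

1. **Internal gaps**, by decreasing remaining length G. At each G a single
   model (per G for plain MICT) is trained on all fully observed
   displacement windows — target t with predictors at offsets −np…−1 and
   +G…+G+nf−1 — and the leftmost missing cell of every gap currently of
   length G is drawn from it. Cells impute strictly left→right within a
   gap, with the future block anchored beyond the *remaining* gap; imputed
   cells count as observed predictors for later steps. (An alternating-edges
   order is a conceivable variant; the worked-example semantics used here
   are leftmost-first, which we implement exclusively.)
2. **Initial gaps**, far right to left, each cell drawn from a backward
   model X_t | X_{t+1..t+k} with k = nf (or np when the preset is past-only:
   the future is the only side available, so past-only configurations
   borrow their window size; symmetric for terminal gaps).
3. **Terminal gaps**, far left to right, with the mirrored forward model.
4. **Edge-constrained gaps**, treated as internal with np reduced to the
   available flank (left-hand), nf reduced (right-hand), or both
   (both-hand).

Training windows are harvested from cells observed in the *original* panel;
previously imputed cells serve as prediction-time predictors but are not
recycled as training rows.

**Sparse-training fallback ladder.** When a training set has fewer than
`min_train_rows` (default 10) rows: (1) reduce the window to at most one
cell per side; (2) fall back to a first-order Markov model pooled over all
adjacent observed pairs (direction matching the available side); (3) fall
back to the marginal observed-state distribution. Every fallback is recorded
in the fit log. MICT-timing first widens the radius one step at a time
(logged) before entering this ladder, preserving the timing idea as long as
any local data exists.

**RNG design.** One master seed; per-imputation streams are spawned through
`numpy.random.SeedSequence`, so the M imputations are exchangeable but the
whole `MultipleImputation` is bit-reproducible. Models are cached within one
pass per distinct (stage, G, window, target-position) step, so the fit log
counts exactly one fit per distinct step.

## MICT-timing

Identical staging, but the model for a target cell at time t is trained only
on windows whose **target** position lies in {t−radius … t+radius} ∩ [1, T]
(the filter applies to the predicted position, matching the windows-per-
sequence counting semantics of the method), and gaps of equal length at
different positions therefore use different models. Radius T−1 makes every
time frame cover the whole axis, reproducing MICT's training sets exactly —
this equivalence is asserted in the tests. The default radius is 0 with one
predictor on each side, the configuration that performs best in published
comparisons on time-heterogeneous data.

## Imputation models

* **Multinomial**: scikit-learn softmax regression on one-hot expanded
  predictor states (plus optional fixed covariates), L2 penalty λ = 1e-3 on
  the weights. Perfect-prediction protection combines the penalty with an
  ε-blend (ε = 1e-6) toward the uniform distribution over the response
  categories seen in training, so every fitted probability for a seen
  category is strictly inside (0, 1). This is a deliberate, documented
  approximation of the data-augmentation approach usually cited for this
  problem, which has no published settings for this use.
* **Random forest**: 100 trees, √p features per split, unlimited depth —
  the conventional default parameterization. Class probabilities are the
  fraction of *trees voting* for the class (hard votes), not averaged leaf
  probabilities; this matches how the method is used in the imputation
  literature and explains its known weakness (near-degenerate vote
  distributions).
* Response categories absent from training receive probability exactly 0:
  imputation can never invent a state unseen in the training windows. The
  single exception is a degenerate single-category response under
  protection, where ε leaks uniformly to the rest of the alphabet so the
  seen category stays strictly below 1; the two contracts cannot hold
  simultaneously in that corner.
* Predictor categories unseen at prediction time map to the all-zeros
  one-hot block (reference level), never an error.

## FCS

Each time point is a variable. Missing cells start from their column's
observed marginal; the sampler then makes `n_iterations` (default 10)
ascending passes over the originally incomplete columns, refitting each
column's model on the rows originally observed there — predictors being the
current working values of the chosen set (`P1`, `PF1`, `P5`, `PF5`, `all`,
`past`, clipped to [1, T]) — and redrawing the originally missing cells of
that column only (the sequential chained-equations reading). Empty predictor
sets (t = 1 under past-only) redraw from the marginal. Collinearity under
`all` is handled by the ridge penalty rather than predictor pruning. No
convergence diagnostic is computed; the iteration count is the stopping
rule.

## VLMC

Contexts are history suffixes read backwards from the present, stored with
next-state counts up to `max_depth` (default 6 — unstated in the sources we
follow; bounded for tractability on length-72 monthly sequences). Positions
near a subsequence start contribute to the truncated contexts they do have.
Pruning is bottom-up with parent-chain removal:

* **context algorithm** — keep a node when the deviance
  2·Σ_s n(s|c)·log(p̂(s|c)/p̂(s|suffix(c))) exceeds the (1−q) χ² quantile
  with |A|−1 degrees of freedom; candidate q ∈ {0.1, 0.05, 0.04, 0.03,
  0.02, 0.01, 0.001};
* **Learn-PSA rule** — keep a node when some observed next-state probability
  differs from the suffix's by a factor ≥ r; candidates r ∈ {1, 1.05, 1.1,
  1.2, 1.5}; contexts observed fewer than twice are pruned regardless (a
  minimum-count guard standing in for the original P_min machinery, which
  has no published settings here).

The threshold is chosen by AIC = −2·loglik + 2·(#leaves)·(|A|−1), ties going
to the smaller tree. Likelihoods use longest-matching-context MLE
distributions (always finite, since the matched node's counts include the
scored position). Imputation fits the tree **once** on the observed
subsequences; the M imputations differ only in their draws, which use
add-1/|A| smoothing so unseen continuations stay possible. Gaps fill left to
right; the first cell of an initial gap draws from the panel-wide observed
state distribution. Because draws condition only on the prefix, permuting a
sequence's future can never change a cell's imputation distribution.

## Amputation generators

The published hazard constants are the defaults: initial gap 0.06, gap start
0.20 after a high-risk state and 0.03 otherwise, continuation 0.66,
attrition 0.10/0.015 from time ⌈T/2⌉+1 onward, 40% protected-complete
fraction, 75% per-sequence missingness cap with per-sequence regeneration
(redo), and 200 cases for the small-sample variant. Hazards are evaluated
against the **true** pre-amputation states — the generator sees complete
data, which is what makes the mechanism MAR-like by design rather than
MCAR. A gap may restart immediately after ending (renewal process). The
high-risk state list is a required configuration field, chosen per panel so
missingness can occur at any time. The redo rule regenerates only the
offending sequence, which mildly truncates the realized hazard distribution;
validation of the raw hazards therefore disables redo (and protection).

## Estimands and pooling

* timing: P̂(X_t = s) per state and time;
* duration: mean spell length per state, pooled over sequences; states with
  no spells carry a distinct "no spells" sentinel (NaN), never 0;
* sequencing: RR(a→b) = P̂(next=b | cur=a) / P̂(next=b | cur≠a), pooled over
  time (a per-time variant would be possible; the pooled form is the one
  implemented). Infinite RRs are capped at 1e6 and flagged; undefined
  conditioning events are dropped with a note. Raw transition counts remain
  accessible for alternative definitions.

All three are functions of per-sequence counts, so the sequence bootstrap
(B = 1000 by default) resamples a multinomial weight vector against a
precomputed row-statistics matrix rather than re-scanning the panel.

Rubin's rules: T = W̄ + (1+1/M)·B with t-reference degrees of freedom
(M−1)(1 + W̄/((1+1/M)B))², ∞ when B = 0. M defaults to 5 and is always
explicit in the API — no single published value exists for it.

## Simulation-study engine

Per repetition: resample n sequences with replacement, ampute, impute M
times per method, compute estimands and bootstrap variances per completed
panel, pool. The truth θ is the estimand on the original complete panel,
fixed across repetitions (a per-resample truth is available behind a flag).
Reported per estimand: bias with MCSE, 95%-interval coverage with MCSE
(√(c(1−c)/n_rep)), empirical and mean model variance. Aggregation mirrors
standard simulation-study reporting: mean absolute bias per family, and the
proportions of Monte Carlo intervals (±1.96·MCSE) containing 0 bias and the
0.95 nominal coverage. Method failures are counted and excluded per
repetition. Identical master seed and configuration give a bit-identical
performance table. Timing estimands whose true frequency falls below a
configurable floor can be excluded (their coverage is degenerate; default
floor 0 keeps everything). An optional on-disk per-repetition cache makes
long studies resumable; per-repetition seeds derive from the master seed
independently of execution order, so resumed runs match uninterrupted ones
exactly.

## Synthetic generators

`GeneratorSpec` draws Markov panels with a per-time transition rule. The
presets emulate archetypes of real life-course panels by their printed
summary characteristics — alphabet size, length, overall transition rate
(≈1.6% for the stable civil-status-like preset up to ≈36.5% for the
volatile satisfaction-like one), process-time heterogeneity, monthly
seasonality (school→employment concentrated at months 12, 24, …, 72), and
near-irreversibility — **not** the micro-structure of any proprietary
dataset. Passing tests therefore demonstrate qualitative behaviour
(rankings, calibration, hazard recovery), not numeric reproduction of any
real-data study.

## Problem sizes used in validation

Generator-hazard recovery uses a 30000×20 panel (large enough for ≥100,000
in-gap continuation steps and tight 3-SE bands). Oracle calibration of the
study engine runs 100 repetitions on a 300×15 panel with M = 2 and B = 400
bootstrap replicates — at that size the bootstrap-variance noise (≈7%
relative) is well inside the binomial tolerance of the coverage check. The
seasonal comparison runs 20 repetitions of MICT vs radius-0 MICT-timing
(both PF1, so the time frame is the only difference) on a 300×72 monthly
panel with M = 3, scoring timing estimands for the seasonal pair's states
within one month of the spikes.

## Known limitations

* Univariate panels only; no multichannel or time-varying-covariate
  support. Fixed categorical covariates enter the primary MICT,
  MICT-timing and FCS fits (one-hot alongside the sequence predictors);
  the sparse-data fallback rungs and VLMC remain sequence-only.
* MNAR mechanisms are not simulated.
* The sequencing relative-risk formula is one reasonable pooled definition;
  users needing a different one should compute it from the transition
  counts.
* VLMC refits once per incomplete panel, not per imputation; draw-level
  variability is captured, refit-level variability is not.
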