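# Methods

## The synthetic cohort

The generator emulates a single-university PTSD screening survey. A cohort
draw produces `n_total` questionnaire records (default 596) of which
`n_valid` (default 488) are complete; the remainder have exactly one item
or covariate knocked out to missing, so the completeness-based validity
filter reproduces the 488/108 split by construction. Within the valid
subset the demographic margins — 200 male / 288 female, age bands
475 / 10 / 3 (18–25 / 25–30 / > 30), 485 trauma-exposed — are imposed by
stratified assignment (build the exact count vectors, shuffle), not by
independent sampling. Margins therefore hold exactly at every seed, which
is what makes the printed-count checks deterministic.

Each respondent carries a latent PTSD probability

p = logit⁻¹(β₀ + β₁·gender + β₂·age + β₃·event_role + β₄·exposure_time + β₅·parent_died)

with default slopes (−0.831, −1.243, 0.117, 0.519, −1.968) and codings
gender 1 = male, age 1 = 18–25, event_role ordinal 0/1/2, exposure_time
log-normal(meanlog 0, sdlog 0.5) in abstract time units (0 for the
unexposed), parent_died 1 = both parents alive (Bernoulli 0.95). Under
these codings the negative slopes mean women, older respondents, and the
bereaved are at higher risk, matching the direction of the slope signs.
The codings are configuration, not fact: survey instruments rarely state
their reference categories, so they are documented rather than assumed
universal. The intercept β₀ = 1.5 is a generator choice (risk-factor
tables do not report a constant); it puts screen-positive prevalence near
30%, a realistic figure for a trauma-exposed student sample and
comfortably away from the rare-event regime where Wald intervals misbehave.

A binary PTSD status is drawn as Bernoulli(p). This, not the
item-derived screen flag, is the outcome used in parameter-recovery
simulations, because it follows the logistic model exactly; regressing
the screen flag instead estimates an attenuated, misspecified projection
(see below), which is the realistic situation the pipeline's risk stage
operates in.

### Item link

The 17 item responses come from an ordered-threshold rule: a respondent's
latent severity is p plus a person-level Gaussian draw (sd 0.25, shared
across their items); each item adds independent Gaussian noise (sd 0.15)
and is cut at fixed thresholds 0.2 / 0.4 / 0.6 / 0.8 into codes 1–5.
The link is monotone — E[total] is non-decreasing in p — and degenerates
correctly (p = 0 with zero noise gives all 1s, total 17; p = 1 gives all
5s, total 85).

The person-level term is essential, not decorative. Item noise alone
averages out across 17 items (sd of the mean severity ≈ 0.15/√17 ≈ 0.04),
which would make "total ≥ 38" a near-deterministic threshold on p and
hence on the linear predictor — the screen-positive regression would then
be quasi-separated and its coefficients numerically unbounded. The
person-level term models symptom variability not explained by the five
covariates, which every real scale exhibits, and keeps
P(screen-positive | covariates) a smooth function. What the generator
still does **not** emulate: item-specific factor loadings, differential
item functioning, response styles, or informative missingness. Passing
tests show the pipeline's statistical machinery is correct under a clean
monotone item process; they do not validate the PCL-C's psychometrics.

### Therapy panels

Pre/post panels for the effectiveness stage use the nine-index system
(T1 PANSS total, T2–T4 its positive/negative/general subscales, T5 SSSI,
T6 SQLS, T7–T9 social/ability/treatment stigma). Listing psychosis-scale
instruments as PTSD therapy indices is clinically unusual; the panel is
implemented verbatim as a labelled index system without endorsing the
instrument choice. Default pre-therapy means (76, 18, 20, 38, 30, 60, 15,
12, 10) sit in each instrument's plausible symptomatic range, the default
post shift is negative on every index (improvement), and noise is
Gaussian with sd 2 at both phases; all three vectors are arguments. Since
the source comparisons exist only as unreadable figures, the panel values
are synthetic by design and the analysis is validated against the known
configured shift instead.

## Checklist scoring

Totals are plain sums; severity bands are half-open integer intervals
17–37 / 38–49 / 50–85; screening uses total ≥ 38 by default with the
strict ≥ 50 standard available via the `threshold` argument. Cluster
positivity counts items scored ≥ 3 within each cluster and compares with
minima 1 / 3 / 2. The item-to-cluster map is not stated by the scoring
rules themselves; the default is the standard PCL-C layout (1–5
re-experiencing, 6–12 avoidance/numbness, 13–17 hyperarousal), which is
consistent with the 1/3/2 minima and cluster sizes 5/7/5, and the map is
overridable through `ScaleDefinition`. Missing items are rejected, never
imputed.

## The GA-BP model

**Normalisation.** Min–max rescaling (x − x_min)/(x_max − x_min) composed
with an affine map onto a configurable target interval. The target
defaults to [−1, 1]; passing [0, 1] gives the plain unit-interval formula.
This reconciles the two conventions in circulation without losing either.

**Network.** Three layers; hidden units apply the logistic sigmoid
(tanh available), the output layer is linear so its range is
unconstrained. Training is full-batch gradient descent on the MSE
averaged over all samples and output nodes, stopping at `max_epochs`
(default 200, the point where the training-step study plateaus) or at an
error goal. The backpropagation deltas are the standard ones — output
delta = residual (linear output), hidden delta = (delta · Wᵀ) ⊙ σ′ — and
are verified against central finite differences to < 1e-5 relative error,
because the usual printed statements of the update rule are too garbled
to transcribe symbol-for-symbol. Batch mode, a single hidden layer, and
plain gradient descent (no momentum/Adam) are deliberate scope limits.

**Chromosome coding.** A chromosome is the parameter vector in the fixed
order: input→hidden weights row-major, hidden biases, hidden→output
weights row-major, output biases (layout version 1, recorded in saved
models). Its length satisfies L = i·k + k·j + k + j, which equals the
parameter count for every architecture — an identity the tests enforce.
(The often-quoted "81 real numbers" for a 12-hidden-node, one-output
network is not attainable from this formula for any integer input count;
the formula is trusted.) Gene bounds default to [−1, 1] for all
weights and thresholds.

**Fitness** is F = k_f · Σ|y − a| over all samples and output nodes, with
k_f = 1 by default (the coefficient is never pinned down, and it cancels
in selection anyway). Non-finite predictions map to infinite fitness.

**Selection.** Roulette on a minimised fitness needs a transform — raw
proportionality would favour the worst individual — so selection scores
are 1/(F + ε) with ε = 1e-12, making the lowest-F individual the most
likely parent. The empirical selection law is checked against the
analytic probabilities by Monte-Carlo.

**Crossover** is symmetric arithmetic blending at a random position set
(each gene with probability 1/2) with a single b ~ U[0,1], applied with
probability 0.8; children are convex combinations, hence always within
bounds.

**Mutation.** Per-gene with probability 0.1; the standard non-uniform
form a + (a_max − a)·f(g) (upper branch, drawn when r > 0.5) or
a + (a_min − a)·f(g), with f(g) = r₂·(1 − g/G)², which shrinks to zero at
the final generation and cannot leave the bounds. The variant with the
reversed upper-branch sign — which can undershoot and must be clipped —
is available behind `printed_convention=True` for comparison.

**Loop.** Exactly G generations (default 50) of select → crossover →
mutate, with one elite: the best-so-far individual replaces the worst
child each generation. The best-fitness trace is therefore
non-increasing, which the tests assert across seeds. Only
generation-count stopping is implemented. The GA's best chromosome is
decoded into initial weights and the network is then refined by
backpropagation (the GA-BP hybrid); with zero generations this
degenerates to best-of-random-population initialisation.

**Grid searches** train one plain-BP network per grid value (hidden nodes
4–14, learning rate 0.02–0.2, or epoch count), holding everything else
fixed and sharing one seed per grid so comparisons are paired; the metric
is training-set MSE (no validation split is prescribed for these studies,
so none is defaulted). The argmin on synthetic data is reported
mechanically and is *not* asserted to match any particular published
choice, since that depends on the original, unavailable survey data.

## Logistic risk model

The fitter is in-house IRLS (equivalently Newton-Raphson on the exact
score), converging when the log-likelihood improves by < 1e-8, with
standard errors from the inverse observed information. Perfect separation
is detected two ways — coefficient norm blow-up, and fitted probabilities
saturating at the observed outcomes — and raised as an error rather than
silently returning meaningless estimates; a singular information matrix
raises a collinearity error naming the involved columns. Wald intervals
exp(B ± 1.96·SE) and chi-square(1) tail P-values are the only interval
and test methods offered, matching the standard table layout; profile
likelihood is out of scope. Age enters as a binary 18–25 indicator by
default because the risk table carries a single age row.

A note on published tables of this kind: derived columns do not always
satisfy their defining identities (e.g. B = 0.519, SE = 0.168 gives
OR = e^0.519 = 1.680 and Wald = 9.543 exactly, where 1.657 and 9.935 have
appeared in print). This package computes the derived columns only from
B and SE via the exact formulas and never reproduces inconsistent
printed values; the tests pin the identities.

The recovery harness regenerates cohorts (margins rescaled by the
largest-remainder rule to the requested n), fits the Bernoulli PTSD
status on the five covariates, and reports per-coefficient bias and
empirical 95% interval coverage — the integration property the generator
exists to support.

## Effectiveness evaluation

Agreement between the model and a reference evaluation is summarised by
MAE, RMSE, Pearson r, and maximum deviation (MAE ≤ RMSE ≤ max always);
correlation is reported as undefined (None) when either vector is
constant rather than silently returning NaN. The reference scale is
continuous by default — in the pipeline the observed checklist total
plays the expert role and the network predicts it from the 17 items on a
held-out 20% of the cohort.

Pre/post change uses a two-sided paired t-test per index (the minimal
inferential wrapper; no test is prescribed by the comparison's source),
with the all-zero-difference case reported as a NaN sentinel rather than
an arbitrary statistic. The default focus is the three top-level
instruments T1/T5/T6; no multiplicity correction is applied across
indices because the analysis is single-index by design.

`run_pipeline` chains simulate → score → train → risk → panels, failing
with the stage name on any error, and writes a manifest with parameters
and SHA-256 digests of every artifact; identical config and seed
reproduce identical digests.

## Problem sizes and numerical choices

Unit and property tests run at deliberately small scale (networks up to
8 nodes per layer, cohorts of tens to hundreds); the heavier behavioural
checks use: 20 paired seeds at 200 epochs for GA-BP versus BP on a
30-point sine regression; 100,000 draws for the roulette law (tolerance
0.01); 200 replicates of n = 20,000 cohorts for recovery (bias bound
0.05, coverage band [0.92, 0.975], binomially compatible with 200
replicates of a nominal 0.95 interval). Finite-difference gradient checks
use central differences with step 1e-6 at relative tolerance 1e-5.
All randomness flows through explicitly seeded `numpy` generators; no
global state is touched.

## Known limitations

- The synthetic cohort is a statistical stand-in: real PCL-C data exhibit
  item-level structure the ordered-threshold link does not model, and the
  pipeline's green tests certify the machinery, not any clinical claim
  about the therapy's efficacy.
- The GA-BP comparison shows the hybrid is no worse on average under the
  documented conditions; it is not a general superiority theorem.
- The logistic stage assumes no interactions, no survey weights, and
  complete cases only (the validity filter removes incomplete records
  upstream; there is no imputation).
- Exposure-time units are abstract; only the coefficient scale, not the
  distribution family, matters for the recovery results.
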