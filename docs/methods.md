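# Methods

This note documents the statistical procedures implemented in `bst`, the
assumptions behind the synthetic-data generator, and the numerical and
design choices made where the underlying protocol left room.

## 1. Questionnaire scoring

Likert answers map to [0, 1] scores: 4-option items score 1, 0.6667,
0.3333, 0 from "definitely true" down to "not at all true"; 5-option items
score 1, 0.75, 0.50, 0.25, 0 from "always" down to "never". Reverse-keyed
items allocate the same decimals in the opposite direction; the published
truncated decimals are used verbatim (a reversed "mainly true" scores
0.3333, not 1 − 2/3), so scored output is bit-compatible with the printed
protocol. Matching is case-insensitive after trimming; unknown labels are
hard errors carrying row and item id.

Each of the six factors (responsiveness/satiety, lack of fussiness,
interest in food; owner intervention, restriction of human food, exercise
taken — 7/3/3/4/4/5 items) scores as the sum of its item scores divided by
the sum of item maxima. The composites weight factors by their item
counts: FMS = (7·RS + 3·LF + 3·IF)/13 and OCS = (4·OI + 4·RHF + 5·EX)/13.
The weighted OCS formula is treated as authoritative over the looser
"mean of the three owner factors" phrasing, because it is stated as an
equation.

**Missing answers.** The protocol is silent; the factor formula's
structure is extended naturally: a factor is scored over answered items
only and flagged when more than half its items are missing; composites
require all three factors. Flagged rows are kept, never dropped.

**Item key.** The instrument's per-item factor assignment and reverse
keying are published separately from the scoring protocol; the package
ships a synthetic 26-item default key with the correct factor sizes (two
reverse-keyed items, one per scale width) and accepts a replacement key as
YAML, keeping the published weights fixed.

## 2. Cohort rules

Inclusion filters use strict inequalities exactly as printed: age > 1
(eating patterns unestablished earlier), age < 19 (likely data-entry
errors above), owner BCS > 3 (lower is clinically underweight), BCS
present. The filter report itemises each rule separately *and* records the
joint exclusion count, since one record can fail several rules and the
printed per-rule counts need not sum to the total.

One clinic visit per dog is selected uniformly at random, reproducibly
from a seed and invariantly to row order (rows are ranked by (dog_id,
visit_id) before drawing). The 5-point BCS collapses 1–2 → underweight,
3 → ideal, 4–5 → overweight/obese, because the extreme scores are rarely
used and destabilise the model.

**Tertiles.** Cut points sit at the equal-split ranks of the sorted
values; every record tied with a cut value falls in the lower group. This
makes the assignment a pure function of the values (invariant to input
order) at the cost of group sizes differing by up to the boundary tie
count. All-identical values are rejected as degenerate. **Breed
averages** require strictly more than `min_n` dogs (default 10); the
threshold is a flag because "more than 10" and "10 or more" both appear in
the source material.

## 3. Firth-penalized logistic regression

Ordinary ML logistic estimates diverge under separation, which occurs
routinely in sparse breed × age × sex cells. The fitter maximises
l(β) + ½ log det I(β) (a Jeffreys-prior penalty) by Newton iteration on
the modified score U*(β) = Xᵀ(y − π + h(½ − π)), where h is the diagonal
of the weighted hat matrix:

* start at β = 0; tolerance 1e-8 on the largest modified-score component;
  at most 50 iterations;
* step-halving (up to 30 halvings) whenever a Newton step would decrease
  the penalized log-likelihood, so the accepted trajectory is
  non-decreasing;
* covariance = inverse Fisher information at the estimate, symmetrised;
* non-convergence returns a flagged fit with diagnostics, never a silent
  result; rank-deficient designs raise an error naming aliased columns.

The intercept-only penalized mode has the closed form p̂ = (k+½)/(n+1),
which the tests exploit as an oracle, together with direct numerical
maximisation of the penalized likelihood on separated data.

**Design.** Treatment coding with the alphabetically first level as
reference, stable and documented. Age enters as numeric whole years by
default; a categorical-age option exists for the main effect, but the
breed:age interaction always uses the numeric scale (a full categorical
interaction would add hundreds of columns for no stable gain at desk
scale). Within a binomial subset, columns aliased by empty cells are
removed before fitting (the design is full rank after aliased-column
removal) and each fit records which columns it kept.

## 4. The merged multinomial and standardized probabilities

The two reference-category binomials (underweight vs ideal,
overweight/obese vs ideal) merge by treating their linear predictors as
multinomial logits against 'ideal':

p_ideal = 1/(1 + e^{η_U} + e^{η_O}), p_under = e^{η_U}·p_ideal,
p_over = e^{η_O}·p_ideal.

This is the unique construction that reproduces each binomial model
conditionally (p_under/(p_under+p_ideal) = expit(η_U)), and it keeps the
two-binomial architecture of the original analysis rather than refitting a
direct multinomial. Probabilities are computed through a log-sum-exp
normalisation, so triples sum to 1 within 1e-10 at any predictor value.

Per-breed probabilities are standardized over a reference covariate
distribution: the empirical whole-population age distribution and a 50:50
sex ratio, i.e. the weighted average of the merged triple over the
age × sex grid with weights (age weight × ½). Standardization makes breeds
comparable regardless of their observed age/sex mix, and is invariant to
reference-level recoding (verified to 1e-10 in the tests).

**Confidence intervals** are simulated: coefficient vectors are drawn from
each fit's asymptotic multivariate normal (mean = estimate, covariance =
inverse Fisher information), **independently for the two fits** (their
joint sampling covariance is not identified from two separate fits); the
standardized probabilities are recomputed per draw and the 95% interval is
the empirical (2.5%, 97.5%) quantile band. Default 1,000 draws; fewer than
100 draws triggers a warning; non-PSD covariances are rejected. Coverage
of the true standardized overweight probability is verified by simulation
(200 replicate cohorts, 46 breeds, ~200 dogs/breed) to lie in the
0.90–0.99 band for a nominal 95% interval.

## 5. Linear modelling

OLS goes through statsmodels with formulas assembled from term lists in
`*`/`:` notation; sex and neuter status are coded 0/1 (female/entire = 0).
The 9-point owner BCS is treated as a numeric response. AIC is computed on
the n·log(RSS/n) + 2(k+1) scale, constant across the models being
compared. Rank-deficient designs raise an aliasing error naming the
offending columns.

**Stepwise selection** is backward elimination under marginality (a main
effect is never dropped while an interaction containing it remains): at
each step the candidate deletion with the lowest AIC is accepted if it
improves the current model, ties broken alphabetically, stopping at a
local minimum. This mirrors the default behaviour of the classical
stepwise procedure run from a full initial model.

**Breed-adjusted food motivation.** From the minimal model for FMS
(initial terms sex*neuter + sex*age + neuter*age), the sex, neuter and
sex:neuter coefficients adjust each dog's score as

adjusted = raw − β_sex(sex − mean_sex_breed) − β_neuter(neuter −
mean_neuter_breed) − β_int(sex·neuter − mean_int_breed),

with breed means taken from the analysis table. The printed formula's
parenthesisation is ambiguous; this centred reading is the only one under
which a null model (all β = 0), or a dog sitting exactly at its breed's
covariate means, leaves the raw score unchanged, and it keeps units
coherent. A term eliminated by model selection contributes zero
adjustment. Breed differences in adjusted FMS are then tested by one-way
ANOVA.

**Tertile-stratified effects.** The interaction model BCS ~ (OI + RHF +
EX + Sex + Neuter) × tertile + Sex×Neuter + Age is refit three times, once
per reference tertile; the main-effect coefficient of each management term
in a run is that tertile's within-group slope. The three runs are exact
reparameterizations — identical fitted values, R² and AIC — which the
implementation verifies internally. Group descriptives are compared by
pairwise pooled-variance t-tests (df = n₁+n₂−2, matching integer-df
reporting conventions; Welch available by flag) with Holm step-down
correction.

## 6. The synthetic-data generator

The generator emulates the empirical structure of the two study cohorts at
desk scale, with one root seed spawning independent child streams (breed
parameters, questionnaire arm, clinic arm) so the two arms share breed
ground truth.

**Breed structure.** 46 breeds; latent food motivation fm_b ~
N(0.633, 0.10²); breed overweight propensity (log-odds units, sd 0.5) is
constructed by Gram–Schmidt so its realised correlation with fm_b equals
the configured target (default 0.7) *exactly*, making the built-in signal
a known quantity for recovery tests. Breed sample weights are log-uniform
with a 35:1 imbalance, mimicking the heavy breed imbalance of the real
cohorts (clinic breed counts ranged ~3.3k–117k around a median of ~25k)
at reduced scale.

**Questionnaire arm** (default n = 14,960 dyads, the real response count).
Individual latent FM adds sex (+0.02 male), neuter (+0.06), age (+0.004/yr,
centred at 5.41) and N(0, 0.20) noise, so sex/age/neuter explain a few
percent of FM variance while breed explains ~15%, as observed. Ages are
drawn gamma(mean 5.41, sd 3.32) but deliberately widened to [0.5, 21] with
~2% tails outside the (1, 19) analysis window so the filters always have
work to do. An owner-control latent (mean 0.5, sd 0.15) correlates with FM
at 0.12 — the observed FMS–OCS correlation — exposed as a free parameter
because the full joint distribution of management behaviours is not
described. Likert items threshold a noisy item latent (item noise sd 0.12,
deterministic item intercepts in ±0.05) at equally spaced cuts; the cut
step (0.25) and centre shift (−0.09) were calibrated once so the measured
composite reproduces the questionnaire population's FMS mean ≈ 0.633 and
sd ≈ 0.246, and are not tuned thereafter. Reverse-keyed items emit labels
in the opposite order so scoring recovers a monotone signal.

Owner BCS is round(clamp(linear predictor + N(0, 0.9), 1, 9)) — an integer
9-point scale with floor/ceiling effects — where the predictor combines
latent FM (+0.8), breed obesity propensity (+0.5, a genetic channel beyond
measured food motivation, needed for breed to out-explain FMS in R²
comparisons as it does in the real cohort), owner control (−1.5), an
FM × control interaction (−3.0, the behavioural-susceptibility effect:
management matters more in food-motivated dogs), and small direct
sex/neuter/age effects (0.10/0.35/0.02) so conventional risk factors
explain a few percent of BCS. ~3% of BCS values are missing.

**Clinic arm** (default n = 27,600 dogs, 1–4 visits each, whole-year ages
1–15). The 3-category BCS state is drawn from the softmax model with
intercepts (−2.4 underweight, −0.3 overweight vs ideal, giving roughly
5/55/40% at baseline), the breed propensity on the overweight channel, and
additive age/sex log-odds effects (0.05/yr and 0.10 male on the overweight
channel); the merged categories are then split onto the 5-point scale
(30/70 within underweight, 70/30 within overweight/obese). The default of
~600 dogs/breed — far below the real ~25k median — was chosen as the
smallest scale at which per-breed standardized probabilities are estimated
precisely enough for the breed-level association to be recovered without
material attenuation; the 50-per-sex×age-cell breed eligibility rule is
implemented but disabled by default because it presumes the full-scale
cohort.

**What the generator does not emulate:** real breed name lists and
geography, owner-report bias relative to veterinary BCS, multi-wave survey
timing, visit-to-visit correlation structure beyond a shared dog-level
age/breed, and non-normal latent distributions. Passing tests therefore
demonstrate that the *procedures* recover known structure under a
plausible generative model, not that the substantive effect sizes
themselves generalise to any particular real population.

## 7. Problem sizes and reproducibility

Default analysis sizes (14,960 dyads; 27,600 clinic dogs; 1,000 CI draws;
500 in the acceptance script) run in seconds on one CPU; the CI-coverage
simulation uses 200 replicates of 46 × ~200-dog cohorts with 400 draws
each. All randomness flows from explicit seeds (root simulation seed,
visit-selection seed, CI-simulation seed), recorded in the run manifest
together with a hash of the analysis-defining configuration, so a run
directory can be regenerated bit-identically.

## 8. Known limitations

* The owner-BCS response is modelled as numeric in OLS, inheriting the
  original analysis's choice; ordinal regression might be preferable but
  is out of scope.
* The two binomial fits' CI draws are independent; any true cross-fit
  sampling covariance is ignored (it cannot be estimated from separately
  fitted binomials).
* The breed:age interaction is always linear in age, even when the age
  main effect is dummy-coded.
* Stepwise AIC retains truly-null terms with the usual ~16% probability;
  selection consistency is only checked as retention of generating terms.
* At very small per-breed samples, aliased interaction columns are dropped
  per binomial subset, so the two merged fits may rest on slightly
  different column sets; at the default scale this does not occur.
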