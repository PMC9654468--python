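# Methods

This note records the statistical models implemented in `dietval`, the
defaults and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical conventions that matter for reproducing results.

## Questionnaire scoring

Each of the 24 items defines an ordered category ladder mapped to integer
points 1–5; 20 items are scored and partitioned into eight sub-scores
(cereal ×3, fruit/vegetables ×3 including the vegetable-variety item,
take-away ×3, fiber ×2, fat ×2, omega-3 ×2, food choices ×3, food
preparation ×2). Items describing discretionary consumption are
reverse-scored (6 − p), so that in every item more points = better diet
quality. A sub-score is the mean of its items' points; the total is the sum
over the 20 scored items and is therefore bounded in [20, 100] with both
endpoints attainable.

The published instrument's exact proforma is not public; the bundled schema
(`dietval/data/dhq_schema.json`) uses evenly spaced points over each ladder
and is deliberately *data*: substituting the true proforma requires no code
change. The vegetable-variety item scores the count of types clamped to
1–5. Missing answers are rejected by default; an opt-in proration rescales
the total by 20/answered.

Quartiles use linear-interpolation sample percentiles at 25/50/75; a value
tied with a cut point falls in the lower quartile, so a degenerate cohort
(all totals equal) sits entirely in Q1. Q1 is the least guideline-consistent
stratum.

## Food composition

All composition quantities share one linear basis: amounts per 100 g of
food. Day totals are then weighted sums, which makes every derived quantity
additive over records and exactly homogeneous in grams. Composite dishes
carry recipes (component, mass fraction summing to 1) and are deconstructed
recursively with cycle detection; mass is conserved to rounding error, and
energy is conserved whenever the parent's stated density is
mass-consistent with its ingredients.

Conventions:

* nutrient totals, guideline-group serves and discretionary serves are
  accumulated over *deconstructed* foods, and each terminal ingredient
  carries its own discretionary flag (a casserole is not discretionary, its
  confectionery topping is);
* major-food-group gram totals — the input to pattern analysis — use the
  food *as consumed*, without deconstruction, because data-driven patterns
  describe what people report eating, not recipe chemistry;
* a discretionary serve is 600 kJ of discretionary-flagged energy **or**
  10 g of ethanol: alcoholic drinks are counted through their alcohol mass
  only (no double counting through their energy); if alcohol-based serves
  are disabled in configuration, alcoholic drinks fall back to the energy
  rule.

## Usual intake: two-part shrinkage

A single recall day y_id for person i mixes habitual intake with
day-to-day noise. With some participants contributing repeated days, we
model, separately per variable:

**Probability part** (episodic variables only). Person-level consumption
probabilities are shrunk toward the pooled consuming-day fraction p̄ by
beta-binomial empirical Bayes: pᵢ = (cᵢ + m·p̄)/(nᵢ + m), with prior
strength m from the method-of-moments between-person overdispersion of the
observed fractions, floored at 1; with no detectable overdispersion
everyone is pooled. Variables configured "daily" (energy, macronutrients)
take p = 1.

**Amount part.** Positive amounts are Box-Cox transformed, with λ chosen
from the grid {0, ¼, ⅓, ½, 1} by profile log-likelihood (λ=0 is log; the
λ=1 convention is the usual x−1, which is linear, so it behaves as the
identity throughout). Variance components come from the unbalanced one-way
ANOVA method of moments: σ̂²_w = MSW, σ̂²_b = (MSB − MSW)/c with the standard
unbalanced coefficient c, truncated at 0. Estimation requires at least two
participants with two or more positive days; single-recall participants are
shrunk using components identified by the repeat subsample. Person means on
the transformed scale are shrunk by the reliability factor

  tᵢ = μ + (x̄ᵢ − μ) · σ²_b / (σ²_b + σ²_w/nᵢ),

which contracts toward μ, preserves order, and never inflates the
between-person spread. Back-transformation applies a second-order Taylor
correction ½·g⁻¹″(tᵢ)·σ²_b·(1 − shrinkage factor) for the curvature of the
inverse transform over residual person-level uncertainty; results are
floored at 0. Usual intake is pᵢ × amountᵢ.

Numerical choices: within-person variance is floored at 1e-8 (a zero
estimate otherwise raises); week/weekend day types are recorded but
unweighted by default, with an optional 5:2 weighting; a variable with
fewer than two repeat consumers (e.g. a nutrient almost nobody consumed) is
skipped and reported rather than failing the run.

## Psychometrics

Construct validity uses Spearman rank correlations (average ranks on ties,
two-sided p from the t approximation on n−2 df) between each sub-score and
its matched usual-intake variable, computed against the model-based usual
intakes. Internal consistency reports both raw Cronbach's α (variance form)
and standardized α (from the mean off-diagonal correlation, hence
scale-free), over the eight sub-scores by default (item-level mode is
available). Quartile trends are OLS slopes on the quartile index treated as
numeric, the convention the field uses for "p for trend". Two-group
contrasts are gated by Shapiro–Wilk at α=0.05 in each group (groups smaller
than 3 cannot reject normality): Student's t if both look normal, otherwise
the asymptotic rank-sum test with tie correction. Three or more groups use
one-way ANOVA with Welch pairwise follow-ups, Bonferroni-multiplied and
capped at 1. Exact permutation nulls are deliberately not used: at cohort
sizes near 100 the large-sample approximations are standard practice.
Agreement-style analyses (Bland–Altman) are out of scope because a unitless
score and gram-scale intakes share no measurement scale.

## Dietary patterns

Single-day major-food-group gram intakes are standardized and the
correlation matrix eigendecomposed; the trace identity Σλ = p is an
internal check. Components with eigenvalue > 1 are retained (the full scree
is emitted for inspection), varimax-rotated (unnormalized rotation;
communalities are invariant), and each factor's sign is fixed so its
dominant variable loads positively. Percent variance per factor is the
rotated sum of squared loadings over p. Factor scores use the regression
(Thomson) estimator Z·R⁻¹·L, which is mean-zero with variance at most 1 per
factor. Attribution assigns each food group to the factor of its largest
absolute rotated loading when that exceeds 0.2 (strict), ties to the lower
factor index, signs preserved in reports.

Sampling adequacy: KMO and per-variable MSA from the partial correlations
(scaled inverse of R), Bartlett's sphericity χ² = −(n−1−(2p+5)/6)·ln det R
on p(p−1)/2 df. On an exactly diagonal correlation matrix both off-diagonal
sums vanish and the adequacy statistics are reported as 0 (no signal).
Variables are pruned iteratively (worst MSA first) until all MSA ≥ 0.5, the
conventional floor. Note that disjoint block structures — each variable
loading exactly one factor — have *population* MSA near 0.5, so pruning at
the default threshold on modest samples can remove genuinely structured
variables; recovery studies of the extraction itself therefore disable
pruning (`msa_cut=0`), while the pipeline default keeps it.

## Synthetic cohorts

The generator exists so that every pipeline stage can be validated against
known truth. Per participant: a latent diet-quality trait z ~ N(0,1) and
five orthogonal pattern-factor scores f ~ N(0, I). Per food group g, the
person-level log-intake effect mixes trait (weight w_g), factors (one block
loading per group, so the planted loading matrix has orthogonal columns),
and a unique part, scaled to σ_b,g; day amounts add N(0, σ²_w,g) noise and
exponentiate around a base gram level, so positive amounts are log-normal.
Day-level consumption is a probit of the same latent (link 0.75) thresholded
to hit each group's marginal consumption probability — zeros are therefore
*informative*, as in real cohorts where pattern adherence drives both
whether and how much. Participants receive a second (weekend) recall day
with probability p_repeat (default 0.3125, i.e. ~30 of 96). True usual
intakes in the truth table are exact conditional expectations (the shared
day noise between consumption and amount is handled by exponential tilting
of the probit), and all downstream variables are linear maps of true usual
grams.

Questionnaire answers discretize a latent u = a·z + √(1−a²)·ε on
equal-probability thresholds, ordered by post-reversal points. The loading
a per sub-score is *calibrated*: no closed form links a to the
sub-score↔intake correlation through ladders, episodic zeros and the recall
design, so the generator simulates the observable chain (sub-score versus
the two-part-shrinkage usual-intake estimate under the cohort's own recall
design) on an internal fixed-seed calibration sample and bisects a — the
correlation is monotone in a with frozen noise — to the target within 0.01.
Targets beyond the attainable bound raise an error that states the bound.
The planted correlation is thus defined on the quantity the pipeline
estimates; the correlation against the *latent* usual intake is slightly
higher (the recall design attenuates), which is the appropriate convention
for validating an estimation pipeline against its own estimand.

Default conditions: 17 major food groups with five planted factor blocks
(miscellaneous/sugar; special-dietary/alcohol/fats; fruit/fish/substitutes;
milk/meat/−soup; confectionery/cereals/vegetables/beverages), between-person
log-SDs 0.35–0.55 against within-person 0.25–0.35, consumption
probabilities 0.35–0.97, and default targets ρ = {cereal 0.40, fruit/veg
0.45, take-away −0.30, fiber 0.50, fat −0.086, omega-3 0.40, food choices
−0.10, food preparation −0.10}. These were chosen jointly so that every
target is attainable and the factor blocks are recoverable from single-day
grams; they represent a cohort with strong, habitual diet differentiation.

**What passing tests do not show.** Real recall data have larger
within-person than between-person variance for most nutrients, sizable
correlated measurement error between a questionnaire and recalls completed
by the same person, and single-day pattern structure much weaker than
planted here. Recovery under the defaults demonstrates correctness of the
estimators, not that a real cohort of 96 would yield correlations of this
size.

## Pipeline conventions

A valid recall day has ≥1 food record and positive total energy (a
beverage-only day is valid); participants with no valid day are excluded
and listed, and a participant whose second day is invalid continues as a
single-recall participant. Every participant lands in exactly one of the
analysis set or the exclusion table. Outputs are CSV/JSON with fixed float
formatting, so re-running an unchanged configuration is byte-identical.
Pattern extraction degrades gracefully (recorded error) when participants
are fewer than food groups, as in the bundled 6-participant fixture.

## Problem sizes used in the checks

Variance-component recovery uses 1000 participants × 2 days × 20
replicates; construct-validity recovery uses 100 cohorts of 96; pattern
recovery uses 10 cohorts of 500. These sizes put simulation error well
below the tolerances they are checked against while keeping the whole suite
in the order of a minute.

## Known limitations

* The usual-intake model is a transparent stand-in for the covariate-rich
  mixed-model software used in practice: no covariates, no correlation
  between the probability and amount parts beyond what shrinkage induces,
  and no population-distribution percentiles.
* The bundled composition table is a 17-food miniature with one
  representative food per major group; it reproduces the schema, not the
  scale, of national food databases.
* Cronbach's α over eight sub-scores treats sub-scores as components; the
  item-level alternative is provided but unvalidated against any external
  value.
* Factor-count selection beyond the eigenvalue-1 rule (parallel analysis)
  and oblique rotations are out of scope.
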