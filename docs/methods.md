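# Methods

## The scientific setting

Longitudinal ageing surveys observe participants at waves roughly two years
apart.  Frailty is scored on the Clinical Frailty Scale (CFS, 1 = very fit
… 9 = terminally ill) with a classification tree over six
questionnaire-derived items, and collapsed to three analysis states:
*fit* (CFS 1–3), *vulnerable* (CFS 4), *frail* (CFS 5+).  Between waves a
participant may change state, die, or miss a wave and return.  The package
implements the full analysis chain — item derivation, tree scoring, state
collapsing, transition modelling, flow tabulation, weighted utilisation
summaries and sample accounting — together with a synthetic cohort
generator so the chain is testable end to end without restricted survey
microdata.

## Tree scoring

A tree definition is a binary tree whose internal nodes compare one of the
six items (`<`, `<=`, `>=`, `>`, `==`, `in`; ordinals compared by level
rank) and whose leaves carry CFS categories.  The engine is total on the
discretised item domain (BADL help 0–6, IADL help 0–6, conditions 0–28,
five self-rated-health levels, four effort levels, activity yes/no; bounds
configurable), and validation reports unknown items, out-of-domain
thresholds, and categories with empty preimage by exhaustive enumeration of
the domain (56,840 vectors at the defaults).

The shipped `data/default_tree.json` is this package's own
operationalisation of the CFS semantics over the six items (dependency in
personal care → CFS 6–7 by BADL count, IADL dependency → CFS 5, frequent
effort or fair/poor self-rated health → CFS 4, and activity/morbidity/
self-rated health separating CFS 1–3).  It reaches exactly categories 1–7;
the engine itself supports leaves up to CFS 9.  Every correctness claim in
the test suite is made against small fixture trees and an independent
path-walking oracle, so nothing depends on the default tree's particular
splits.  Ordinal labels are matched case-insensitively against common
questionnaire phrasings; ADL counts are counts of items *requiring help*
(the help-vs-difficulty questionnaire distinction is a configuration
concern, not fixed by the engine).

## Transition model

States (fit, vulnerable, frail, died) follow a time-homogeneous
continuous-time Markov chain with generator Q (off-diagonals ≥ 0, rows sum
to 0, died row zero).  The interval law is P(t) = exp(Qt).

**Likelihood.**  Panel records are interval-censored.  For consecutive
non-missing observations (a at t₁, b at t₂) the contribution is
P(t₂−t₁)[a,b].  A death ascertained at t₂ contributes P(t₂−t₁)[a, died],
which sums over all within-interval paths into death — death times are not
observed, only the ascertainment wave.  Missing waves are skipped via the
Markov property (the likelihood is invariant to splitting a record at a
missing wave); subjects are never dropped.  Attrition weights are not used
in the transitions likelihood — they calibrate the cross-sectional
estimates only.

**Structure.**  The default mask allows adjacent-severity moves
(fit↔vulnerable, vulnerable↔frail) and death from every transient state;
direct fit↔frail intensities are excluded by default (standard practice for
ordered severity states; the 2-year *interval* probabilities fit→frail are
still positive via two jumps) but the mask is fully configurable, and
recovery experiments fit whatever structure generated the data.

**Optimisation.**  The likelihood is maximised over log-intensities, so
every iterate is a valid generator.  L-BFGS-B with an analytic gradient
(Fréchet derivatives of the matrix exponential evaluated for all free
intensities at once through the block identity
exp([[A, D],[0, A]]) = [[e^A, L(A,D)],[0, e^A]]), gradient tolerance 1e-8,
log-intensity bounds [−12, 3] (rates 6e-6–20 per year — wide enough for any
biennial design, tight enough to keep the exponential well-conditioned).
Initial values are crude empirical rates (observed interval moves divided
by person-time at risk, clipped to [0.02, 2]).  Panels are aggregated to
counts of (interval length, from, to) before optimisation, so fitting cost
is independent of cohort size.  Allowed moves never observed directly in
the data are flagged (`flagged_intensities_`), not errors.  Transition
matrices clip round-off negatives at 0 and renormalise rows (tolerance
1e-9).

**Calibration to a printed matrix.**  `nearest_generator` takes the
principal matrix logarithm of a row-renormalised interval matrix, divides
by the lag, clips negative off-diagonals, rebalances the diagonal and
zeroes the absorbing row, returning the generator with its worst-entry
reproduction error.  For the shipped reference matrix the log is already a
valid generator and the error (≤ 0.006) comes only from the renormalisation
of printed rounded rows.

**Confidence intervals.**  The CI method is a seeded parametric bootstrap
(percentile 2.5/97.5, default B = 500): panels are re-simulated from the
fitted generator on each subject's *observed* wave grid — conditioning on
the first observed state and preserving the missingness pattern — and
refitted with the point estimate as initial value.  Non-convergent
replicates are dropped and counted; more than 20% dropped is an error.
Coverage is checked by simulation in the test suite (200 datasets of 220
subjects over one interval, B = 120 — sizes chosen to keep the check
single-CPU friendly; the library default B stays 500).

## Synthetic cohorts

`simulate_cohort` emulates the study design the estimator assumes:

- **Baseline**: CFS categories drawn from the published seven-category
  final-wave prevalence (6, 36, 31, 16, 5.5, 4.3, 0.7 percent, renormalised
  from the printed sum of 99.5); the paper prints no baseline-wave state
  composition, so the same vector is the default baseline — a package
  choice, configurable per run.
- **Dynamics**: one multinomial draw per interval from exp(Q·spacing) —
  exactly the interval law the estimator uses, which is sufficient because
  death is interval-censored (no event times are ever consumed).  The
  default Q is the calibrated reference generator.  Wave spacing defaults
  to 2.0 years; per-wave offsets may be supplied for irregular designs.
- **Missingness**: independent per-wave Bernoulli (default 5%), never at
  baseline, missing-at-random, non-absorbing (subjects return).  Death is
  ascertained at every wave and overrides missingness; died rows are
  carried forward for flow accounting.  Whole waves are missing, not
  individual items.
- **Categories and items**: within a state, categories are drawn from the
  baseline vector's conditional distribution (time-homogeneous
  composition); item vectors are drawn uniformly from the tree's preimage
  of the category, so scoring always recovers the generating category.
- **Utilisation**: annual visit/admission counts Poisson with
  category-specific means (negative binomial if a dispersion is
  configured); 13 service flags Bernoulli; care per provider type =
  receipt Bernoulli × gamma hours/day (shape 2) × binomial(31, d/31)
  days/month, so the days mean is exact on [0, 31].  Default means follow
  the published category profiles (GP 2.5→5.9, outpatient 0.7→3.9,
  ED 0.1→0.9, admissions 0.2→1.0, nights 6.6→26.1 with the published CFS7
  dips; services 0.3→2.0; formal-state care peaking at CFS 6).
- **Weights**: subject-level lognormal with mean exactly 1 (σ = 0.5) —
  strictly positive and right-skewed like real attrition weights.

What the generator does *not* emulate: informative (state-dependent)
attrition, covariate effects on intensities (the analysis fits none),
item-level missingness, irregular within-wave interview timing, and
within-subject correlation of utilisation across waves.  Passing recovery
tests therefore show the estimators are correct under the stated design,
not that the design captures every feature of real survey data.

## Weighted summaries

The weighted mean is Σwx/Σw with the design-based linearised variance
n/(n−1)·Σ[wᵢ(xᵢ−x̄_w)]² / (Σw)², normal 95% intervals (z = 1.96).  This is
the ratio-estimator standard error, not the frequency-weight formula; it is
exact under equal weights and checked against a weight-replication oracle.
Summaries are computed only over respondents observed at the wave.
Derived quantities: services count (0–13 true flags), monthly care hours
(hours/day × days/month, summed across providers upstream), and fold
changes as the CFS7/CFS1 ratio of category means — when reproducing printed
in-text ratios these use the printed (rounded) means, as the source does.

## Flows and sample accounting

Flow tables count exact subject transitions between consecutive waves at
category or state level; absent rows count as missing; conservation (flows
out of a wave = members at the wave) and non-decreasing cumulative death
hold by construction and are asserted in tests.  The exclusion-filter
ledger applies pure subject-level predicates in order, recording n removed
and n remaining at each step; because predicates are pure, order changes
the ledger but never the final subject set.
`synthetic_accounting_cohort` realises any printed exclusion arithmetic as
a concrete fixture cohort.

## Experiment sizes

The recovery experiment uses the published design (3,500 subjects × 5
biennial waves, 5% missingness); count aggregation makes the fit itself
take well under a second.  The bootstrap-coverage simulation uses 200
datasets × (1 + 120) fits ≈ 3 minutes on one CPU.  All randomness is
driven by explicit seeds; the acceptance script derives independent
sub-seeds from its single `--seed` via `numpy.random.SeedSequence`.

## Known limitations

- Time-homogeneous intensities: no covariates, no wave effects, no hidden
  misclassification layer.
- Death handling assumes ascertainment by the next wave; an
  exact-death-time likelihood mode is not provided.
- The default tree is an operationalisation, not a transcription of any
  particular published tree; swap in your own definition file for
  study-specific scoring.
- The CI method is percentile bootstrap; no delta-method intervals.
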