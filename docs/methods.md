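# Methods

## Diagnostic rule engine

The engine maps CIS-R depression-section endorsements to ICD-10 F32
categories through a declarative `RuleTable`. The default table follows
the operationalisation used in psychiatric-morbidity survey work: an
episode requires duration ≥ 2 weeks and ≥ 2 of the 3 core symptoms
(depressed mood, loss of interest, fatigue); severity is graded on the
total endorsed-symptom count — mild 4–5, moderate 6–7, severe ≥ 8 with all
three core symptoms. Moderate and severe are collapsed into one reporting
band (`moderate_severe`); the severe grade is carried as a traceability
sub-flag only. Severity is graded on binary endorsements, not 0–4 item
scores: the rule-table contract is count-based, and a score-based variant
would be a different table, not a different engine.

Under the dialysis administration, the appetite-change, weight-change and
functional-impairment items are neither asked nor scored
(`excluded_items`); the engine guarantees that their stored values can
never influence a classification in `as_administered` mode (a property
test enforces this). The sensitivity mode (`impute_present`) re-classifies
every participant as if each excluded item were endorsed; all three
imputed items contribute one unit each to the additional-symptom count.
Because three units are added to every profile, the sensitivity re-run can
only move categories upward — monotonicity is asserted per participant.

With the appetite and weight criteria unavailable, the somatic-syndrome
qualifier is evaluated against the 5 remaining criteria (diurnal
variation, early waking, loss of reactivity, libido loss, observed
retardation/agitation) at a threshold of ≥ 3, configurable. Episode
duration is modelled as a non-negative number of weeks; question
re-routing during administration is an interview concern outside the
scoring contract.

## Screening scales

PHQ-2: two items scored 0–3, positive at total ≥ 3. HAMD-17: the standard
per-item maxima (nine items 0–4, eight items 0–2, maximum 52), positive at
total ≥ 19. Partially missing administrations are never prorated: the
record is excluded from that instrument's summary and the exclusion count
is logged. Proration rules vary across studies; exclusion is conservative
and visible. Concordance with the ICD-10 reference diagnosis reports the
2×2 table, sensitivity/specificity/PPV/NPV and Cohen's κ; any proportion
with a zero denominator is reported as missing, never as 0.

## Covariate coding and missing data

Categorical covariates are reference-coded (k−1 indicators, levels in
schema order). Education's reference is completed schooling — the largest
group — with "no schooling" and "did not complete schooling" kept
distinct. Ethnicity uses four analysis groups (White British, South
Asian, Black, Other). Regression uses complete-case (listwise) deletion;
the design matrix carries an explicit complete-case mask and the pipeline
logs n at every filtering step, since the analysable n is itself
meaningful. Descriptive tables report per-variable denominators.

## Inference

- **Prevalence**: Clopper–Pearson exact intervals (beta quantiles). Exact
  intervals are conservative; a simulation test confirms ≥ 95% empirical
  coverage at p = 0.08, n = 300.
- **Cross-tabulations**: Pearson chi-squared without continuity
  correction when every *expected* cell count is ≥ 5, otherwise Fisher's
  exact test. Keying the switch on expected (not observed) counts is the
  conventional reading of the small-cell rule; it is configurable in
  effect because `min_expected_cell` is exposed on every result. 2×2
  Fisher p-values are the usual hypergeometric two-sided test; r×c tables
  are handled by full enumeration of fixed-margin tables (feasible for
  the small tables the rule routes there; refused above n = 200).
- **Stepwise selection**: backward elimination per block at retention
  threshold p < 0.1. Removal p-values are Wald z-tests, consistent with
  reporting OR / Wald-CI / p triplets; a likelihood-ratio mode
  (`p_value_method="lr"`) is available. Multi-level categoricals enter and
  leave as whole variables, scored by their smallest single-indicator p,
  so a variable with any significant level is kept. Ties are broken by
  removing the variable declared latest; the procedure is fully
  deterministic and the removal order is recorded in the trace.
- **Final model**: ML logistic fit on the union of block-retained
  variables with age and sex always forced in; Wald 95% CIs, model
  chi-squared against the null, McFadden pseudo-R², terms at p ≤ 0.05
  flagged.
- **Separation**: complete or quasi-complete separation (detected via the
  optimizer and standard-error blow-up) raises by default rather than
  reporting unstable odds ratios. A Firth-penalized fit (Jeffreys-prior
  score correction, hand-implemented Newton iterations) is available as
  `separation_policy="firth"`; the reporting pipeline uses that fallback
  by default — small cohorts with many sparse candidate indicators would
  otherwise abort routinely during block stepping — and logs when it
  engages.

## Synthetic cohort generator

The generator emulates a 300-person urban haemodialysis cohort: older
adults (ethnicity-specific mean ages 57–64, SD 14), an ethnically diverse
mix (30% White British, 35% South Asian, 25% Black, 10% Other), heavy
comorbidity burden (hypertension 75%, type 2 diabetes 35% overall with a
South Asian excess at 50% and a Black-group minimum at 22%), a 12-item
threatening-life-events inventory (e.g. death of a parent/child/spouse
12%, major financial crisis 15%) and five discrimination items with higher
endorsement in minority ethnic groups. These marginals are the package's
defaults; each is configurable.

The outcome layer draws the moderate/severe label from a logistic model
over named covariate effects (log odds ratios). The study-conditions
preset uses four effects — type 2 diabetes exp(β) = 5.32, loss of a
spouse/child/parent 3.62, major financial crisis 3.51, university vs
school education 0.18 — and solves the intercept so marginal prevalence is
8%. The intercept solve draws one large covariate sample (n = 200,000,
fixed internal seed, common random numbers) and root-finds the intercept
at which the mean inverse-logit equals the target; this is deterministic,
monotone, and accurate to about 6×10⁻⁴ on the prevalence scale. Among
non-cases, mild episodes are assigned at conditional rate 53/276 ≈ 0.19,
matching a cohort in which mild depression is about twice as common as
moderate/severe.

Symptom profiles are constructed conditional on the label: a core-symptom
count and total within the label's band are drawn, then the endorsed items
are sampled at random, guaranteeing that the rule engine recovers the
label exactly at the default `fidelity = 1` (a lower fidelity substitutes
a random label for profile construction with the complementary
probability, for misclassification studies). Instrument items are drawn
from label-conditional distributions — PHQ-2 items Binomial(3, p) with
p = 0.12/0.45/0.75 for none/mild/moderate-severe; HAMD totals Gaussian
(means 12/18/26, SD 6, clipped to 0–52) spread over the 17 items by a
multivariate-hypergeometric split respecting per-item maxima — calibrated
so screening positivity (~20–30%) far exceeds diagnosed prevalence (8%),
reproducing the screening-overestimation phenomenon as a structural
property. Covariates are generated independently except the explicit
ethnicity couplings above: only marginal structure is asserted about the
emulated population, and inventing further joint structure would be less
transparent than stating its absence.

Default missingness (education 3%, occupation/marital/smoking/alcohol 2%)
yields roughly 90% complete cases at n = 300, so the pipeline's
complete-case accounting is exercised realistically.

**What passing tests do and do not show.** The generator validates the
machinery — coding, selection, estimation — under a known truth; it cannot
validate the substantive claims on real patients. Real interview data have
correlated covariates, informative missingness, interviewer effects and
culturally patterned symptom reporting, none of which are emulated.

## Problem sizes and numerical choices

Parameter-recovery checks refit on one generated cohort of n = 50,000
(complete cases ≈ 48,500), where the recovered odds ratios are unbiased
with relative Monte-Carlo SDs of 3–9% (largest for the education effect,
whose OR of 0.18 leaves only ~200 depressed graduates in the sample).
The exhaustive rule-engine oracle covers all 2⁹ endorsement patterns ×
4 durations × 6 somatic counts in both administration modes; the Fisher
oracle enumerates every 2×2 table with n ≤ 40. Stepwise operating
characteristics use 200 replicates at n = 2,000. Cohen's κ is undefined
when chance agreement is 1 and reported as missing. Logistic fits use
statsmodels' Newton solver (maxiter 200); the Firth fallback iterates to a
score-norm tolerance of 1e-8.

## Known limitations

- The rule constants are the conventional ICD-10/F32 operationalisation;
  study-specific algorithm variants should be supplied as a `RuleTable`.
- The r×c exact test enumerates fixed-margin tables and is exponential in
  table size; it is intended only for the small tables the switching rule
  produces.
- The generator's independence assumptions understate real-world
  confounding between education, occupation, ethnicity and comorbidity.
- Backward stepwise selection at p < 0.1 is implemented as specified for
  fidelity to the emulated workflow; it inherits that workflow's known
  inferential caveats (post-selection inference, order dependence under
  collinearity).
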