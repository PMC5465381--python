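# Methods

## Scope and data model

`kanopa` analyses a wide-format survey in which each of ~105 middle-aged
respondents answers, for each of 52 exercise-app design features, a
functional and a dysfunctional Kano question (five-point scale), plus the
10-item mobile-phone self-efficacy (MPSE) scale and the IPAQ long form.
The pipeline stages are: age inclusion filter → instrument scoring →
stratification → multiple imputation of missing Kano answers →
per-imputation categorization → union-of-winners → demand-supply report →
per-feature multinomial regression.

## Kano categorization

The evaluation matrix maps the 25 ordered answer pairs to six categories
with composition A:3, O:1, M:3, I:9, R:7, Q:2 (functional "Dissatisfied"
against dysfunctional "Satisfied" is *reverse*; the two contradictory
diagonal corners are *questionable*). A feature's sample-level verdict is
decided by:

1. **category strength** `s = 100(n₁ − n₂)/n`, the gap between the largest
   and second-largest *distinct* counts, defined as 0 whenever two or more
   categories share the top count;
2. **total strength** `t = 100(n_A + n_O + n_M)/n`, with the full
   subsample (including R and Q votes) as denominator;
3. the **mixed rule**: if `s < 6` and `t ≥ 60` — strict and inclusive
   respectively, always compared on unrounded percentages — the verdict is
   a mixed set `X(...)`.

The mixed set contains every category holding the top count; only when
the top count is held by a single category are the categories at the
second-largest distinct count added. This asymmetry is deliberate: with a
tied top the runner-up is already more than a full tie below the leaders,
and including it would misstate the contest (e.g. counts A:6, M:5, O:1,
I:6 yield `X(A, I)`, not `X(A, I, M)`). Set ordering is by descending
count, ties broken by the fixed column order A, M, O, I, R, Q.

When the mixed rule does not fire, the single plurality winner is
reported; a tied top count is broken by the positive-priority order
M > O > A > I > R > Q, consistent with the deliberately demand-friendly
("aggressive") reading of positive categories. An R or Q winner is legal
but logged as a warning. Strengths are displayed rounded half-away-from-
zero to integer percent (68.75 → 69); rounded values are never used in
decisions.

All 49 published per-stratum frequency rows shipped in
`kanopa/data/reference_tallies.csv` reproduce exactly under these rules
(strengths after display rounding, verdict strings verbatim), which is
how the tie-handling and threshold semantics above were fixed.

## Instruments

**IPAQ.** Each activity class (domain × intensity) scores MET-weight ×
days/week × minutes/day. Default MET weights: walking 3.3, moderate 4.0,
vigorous 8.0, transport cycling 6.0, vigorous yard work 5.5, moderate
yard work 4.0, indoor chores 3.0 — the long-form protocol values; all
config-overridable. Weekly minutes are truncated at 1260 per intensity
class (walking / moderate / vigorous; cycling and yard work count as
moderate) *before* MET weighting; when a class exceeds the cap every
record in it is scaled proportionally, preserving the domain mix of the
capped remainder (the protocol caps minutes, not MET-minutes). The
categorical level is HIGH if vigorous activity on ≥3 days with ≥1500
MET-min/week total, or ≥7 activity days with ≥3000; MEDIUM if ≥3 days of
≥20-min vigorous activity, or ≥5 days of ≥30-min moderate activity or
walking, or ≥5 activity days with ≥600 MET-min; else LOW. These
disjunctive rules are monotone: added activity never lowers the level.

**MPSE.** Sum of the ten 1–5 items (range 10–50; the sum is
rank-equivalent to the mean for tertiles). The tertile split is by rank
with nominal cuts at n/3 and 2n/3 and *all boundary ties assigned to the
lower group*, making the score→level map deterministic and weakly
monotone; actual group sizes are logged. Cronbach's alpha uses the
classical variance formula with unbiased sample variances throughout.

**Inclusion.** Ages 40–69 inclusive; missing age excludes a respondent
under a distinct logged reason. A respondent enters the Kano analysis
only if ≥50% of their 104 Kano cells are answered; sparser rows are
treated as not having filled the questionnaire rather than imputed
wholesale.

## Missing data

Missingness is expected only in the categorical Kano answers; functional
and dysfunctional items are imputed as separate variables and the
category is always recomputed from answers. For each incomplete variable,
candidate predictors (the fully observed columns) are screened one at a
time with the likelihood-ratio test of the multinomial model of the
target on that candidate, computed as the G statistic of the target ×
candidate contingency table — the two are the same test, since a
saturated multinomial logit on one categorical covariate has the
contingency MLE. Candidates with p < .05 (configurable) survive. Draws
come from the conditional category frequencies within the joint cell of
the (at most two strongest) retained predictors — again the saturated
model's predictive distribution — falling back to the observed marginal
for unseen cells or when nothing survives screening. The two-predictor
cap exists because joint cells go empty quickly at n ≈ 100; it is a
bias/variance choice, not a statistical necessity. Each missing cell
receives m = 3 independent draws (proper imputation; modal assignment
would make m pointless), seeded and bit-reproducible; non-missing cells
are never touched.

Winners are reconciled across imputations by the union of the winning
category sets per feature, ordered by the fixed column order, with a flag
on features whose winners disagreed. In the output tables the union
replaces a run-1 verdict only when it actually adds categories; otherwise
run-1's count-based ordering is kept. Regression estimates are *not*
pooled across imputations (the per-feature models run on the first
imputed dataset); only Kano winners are reconciled.

## Two-factor regression

Per feature, categories are recoded to valued (A, O) / must-be (M) /
indifferent (I, R, Q) and modelled with a maximum-likelihood multinomial
logit on PA level and MPSE level jointly, baseline outcome indifferent,
dummy coding with configurable reference levels (default: medium for
both; the pipeline also emits the low-reference coding so every pairwise
level contrast is reported). Fit is screened with grouped Pearson and
deviance statistics over the covariate patterns
(df = patterns × (J−1) − parameters); a deviance p < .05 excludes the
model from the likelihood-ratio tests, which otherwise drop each
predictor's dummies and refit. Coefficients report b, Wald χ²(1),
two-sided p, OR = exp(b), and 95% Wald CIs. Quasi-/complete separation —
|b| above a configurable bound of 15, or an unusable Hessian — flags the
model and suppresses the Wald quantities for the affected terms instead
of printing astronomically inflated statistics. Reparameterization
invariance of the log-likelihood across reference codings, OR/CI
consistency, and agreement of the maximized likelihood with an
independent numerical optimizer are asserted in the test suite;
parameter recovery (n = 2000, every estimate within 3 SE of truth) and
LR-test type-I calibration (1000 null replicates at n = 300, rejection
rate within [3.5%, 6.5%] at α = .05) establish statistical validity,
since the original respondent-level data needed to reproduce the
published coefficient tables are not available.

## Synthetic data

The generator emulates the study conditions: 105 respondents (default),
ages uniform on 40–69, PA levels drawn with probabilities 22/102, 18/102,
62/102 (the observed subsample mix), MPSE profiles as a shared
respondent factor plus item noise sized to give high internal consistency
(alpha ≈ .9), and 5% MCAR missingness confined to the Kano answers
("small proportions of missing values"; a MAR hook is deliberately
absent by default). IPAQ records are built from level-typical activity
templates with jitter and verified against the scoring rules by rejection
sampling, because the categorical rules are disjunctive and not
invertible. Kano answers are generated by inverse lookup of the
evaluation matrix — draw a true category from the respondent's propensity
vector, then a uniformly random matrix cell of that category — so every
pair classifies back to its recorded truth. Default propensities are
indifferent-dominated with low-PA mass shifted toward must-be/
one-dimensional and high-MPSE mass toward one-dimensional, mirroring the
qualitative pattern of the study; they are inputs, not estimates.

What passing tests on this generator do *not* show: real answer pairs
need not be uniform within a category's matrix cells, real missingness
need not be MCAR, and real PA/MPSE effects need not be additive on the
propensity scale. The generator validates machinery, not substantive
conclusions.

## Numerical and design choices

- Thresholds 6%/60%, α = .05, m = 3, MET table, truncation cap,
  separation bound and seed all live in `RunConfig` with the study
  settings as defaults; the run log records what was actually used.
- Strength comparisons are exact rational arithmetic in effect (counts /
  n in double precision; the closest decision margin in the shipped data
  is 0.25 percentage points, far above representation error).
- The demand-supply report includes a feature iff at least one stratum's
  winning set contains a positive category; a positive winner tied with
  indifferent carries a boolean `tied_with_indifferent` column. The
  headline mean prevalence is the arithmetic mean over reported features
  with available prevalence, with the denominator printed alongside.
- CSV outputs use a fixed column order and `\n` line endings; two runs
  with identical inputs, configuration and seed are byte-identical (the
  run log contains no timestamps).
- Problem sizes in the test suite (n = 300–2000 for simulations, 1000 LR
  replicates, n = 105 for the end-to-end scenario) are chosen to make the
  statistical assertions sharp at interactive runtimes.

## Known limitations

- The exact tertile cut handling of the original survey is unknowable
  from the published tables; the ties-to-lower rule here is one
  deterministic resolution and can produce group imbalances when scores
  are coarse.
- High-PA subsample results and the complete 52-row per-stratum tables
  exist only in unavailable supplements; reproduction claims are limited
  to the 49 published rows.
- Separation in the per-feature models is flagged, not penalized; a
  Firth-type correction is out of scope.
- No multiple-testing correction across the 52 feature models, matching
  the original reporting convention.
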