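# Methods

This note documents the modeling choices behind `upfsim`: what each stage
assumes, which parameters matter, what the synthetic population does and
does not emulate, and where the design was genuinely open.

## Scope and data model

The pipeline consumes two flat tables emulating a Day-1 24-hour dietary
recall extract: an item-level food table (participant id, 8-digit food
code, description text, energy, sodium, added sugar, fiber) and a
participant table (demographics, SNAP status, poverty-income ratio,
10-item adult food-security raw score, education, household size, and the
complex-survey design fields weight/stratum/PSU). Native survey transport
formats (XPT/SAS), multi-day recall averaging, and nonresponse modeling
are out of scope. Only Day-1 totals enter the analysis; the adult age
filter (18+) is applied upstream of the tables.

Socioeconomic categories follow the standard SNAP-eligibility cutpoints:
PIR < 1.30 low income, 1.30–1.85 near poverty, > 1.85 higher income. Both
boundary values map to the middle band because the source ranges are
written inclusive-style. Food security: raw score 0 high, 1–2 marginal,
3–5 low, 6–10 very low; the binary food-insecurity indicator is score ≥ 3.

## NOVA keyword classification

No operational keyword list for NOVA assignment of FNDDS-style
descriptions is published, so the shipped rule table is a curated artifact
built from the canonical NOVA exemplars (sodas, candy, chips, chicken
nuggets, hot dogs, commercially prepared breads, ready-to-heat frozen
meals → group 4; table sugar, oils, salt, honey → group 2; brined/canned
goods, cheese, bakery bread, smoked/cured items → group 3; raw fruit,
plain milk, eggs, grains, plain meats → group 1) plus obvious synonyms.
Decisions that matter:

- **Whole-word matching.** Patterns match only as contiguous whole-word
  sequences of the normalized (uppercased, punctuation-collapsed)
  description, so `HAM` cannot fire inside `GRAHAM CRACKERS`.
- **Tie-breaking** is priority, then longer matched pattern, then higher
  NOVA group. The last step is deliberate: misclassifying an
  ultra-processed item as minimally processed shrinks the UPF pool and
  biases every scenario delta toward null, so ambiguity resolves toward
  "more processed".
- **No silent default.** Descriptions matching no rule are UNCLASSIFIED,
  and aggregation refuses to run while any remain — vocabulary gaps must
  surface, not vanish into group 1.
- The rule table is a plain CSV; its content hash is stamped into every
  run so classified outputs are traceable to the exact vocabulary used.

A labeled 50-description vocabulary ships with the package; it was built
jointly with the rule table (classification reproduces every label), and
the synthetic generator draws item descriptions from it, which makes
classifier round-trip agreement a measurable property of every generated
population (≥ 99% required by the tests; in practice 100%).

## Substitution engine

One substitution profile is applied to the UPF aggregate rather than per
food category: the replacement is isocaloric and carries, per unit energy,
`m_sodium = 0.5`, `m_sugar = 0.2`, `m_fiber = 1.5` times the UPF nutrient
density. Replacing fraction *f* of UPF energy is algebraically identical
to replacing fraction *f* of every UPF item, which is why the aggregate
formula and the item-level oracle used in the tests agree exactly, and why
deltas are exactly linear in *f* (the graded scenarios A/B/C = 25/50/100%
differ only by scale). Energy is conserved identically; reductions can
never drive a total negative because each is bounded by the UPF pool.
Participants with zero UPF intake pass through unchanged and stay in every
denominator. Deltas are reported reduction-positive (sodium/sugar cuts and
fiber gains are all positive numbers).

Whether substitution should act on observed Day-1 totals or on
usual-intake draws is not specified by any source; `upfsim` applies it to
observed totals and treats the usual-intake stage as a parallel
uncertainty layer. This is an interpretation, flagged here.

## Usual-intake Monte Carlo

Forward simulation only — not an NCI/ISU-style measurement-error
deconvolution. Per participant and nutrient, `n_draws` (default 10,000)
values are drawn with a within-person coefficient of variation of 0.20
(the "20% within-person variation factor" read as a CV; an SD-fraction or
±20% band reading would be alternatives, and the truncated-normal family
is available by config). The default lognormal is moment-matched in
closed form — σ² = ln(1 + cv²), μ = ln(x) − σ²/2 — so draws average to the
observed value and are strictly positive. Draws are independent across
nutrients (no between-nutrient correlation is asserted anywhere).
Zero observed intake yields a degenerate point mass at zero, documented
rather than raised.

Per-participant substreams derive from (seed, participant id) via hashed
SeedSequence spawning: subsetting a population never changes a remaining
participant's draws, and summaries are reproducible to full precision.

## Health impacts and the coefficient-scale choice

Impacts are linear: ΔSBP = 0.0025 mm Hg/mg × Δsodium; T2D and CVD risk
changes are percent *relative* risk reductions (no baseline-risk,
life-table or event-count model is layered underneath, because none is
specified by the source material).

**The central ambiguity.** The narrative statement of the sugar and fiber
slopes ("0.8% per 10 g added sugar", "0.9% per 10 g fiber") is
inconsistent with the printed results they accompany: a 30.7 g/d sugar cut
is reported as a 0.25% T2D risk reduction — consistent only with
0.008 %/g, one tenth of the stated 0.08 %/g — while a 1.13 g/d fiber gain
is reported as a 1.01% CVD reduction — consistent only with 0.9 %/g, ten
times the stated 0.09 %/g. The discrepancies run in opposite directions
(×1/10 and ×10), so no single rescaling reconciles both. `EffectCoefficients` therefore requires an explicit `scale_mode`:

- `as_reproduced` (the configs' default): 0.008 %/g sugar, 0.9 %/g fiber —
  the values that reproduce the printed results;
- `as_stated`: 0.08 %/g and 0.09 %/g — the narrative text taken literally.

Sodium is internally consistent and identical in both modes. Every result
object and report header records the mode; neither is chosen silently.

**Uncertainty.** Each Monte Carlo replicate draws slopes from
Normal(β, 0.10·β) truncated at zero and multiplies by a nutrient delta
draw; 2.5/97.5 percentiles form the interval. The 0.10 relative SD is a
calibration chosen to bracket plausible meta-analytic uncertainty (at a
256.7 mg sodium delta it gives a half-width of ≈ 1.96·0.10·0.64 ≈ 0.13
mm Hg); it is a package parameter, not a published fact, and the printed
intervals are treated as an order-of-magnitude plausibility band only.

## Survey estimation

Weighted means and proportions use Taylor linearization over stratum/PSU
score totals with df = PSUs − strata and t-based intervals; estimates are
invariant to weight rescaling, and an SRS-style SE is reported alongside
for comparability with analyses that ignore the design. Lonely-PSU strata
raise by default, naming the stratum; certainty-unit treatment is an
explicit opt-in. Replicate-weight (BRR/jackknife) variance and
covariate-adjusted regression modeling are out of scope — covariate
context is provided as stratified summary tables instead, since no
estimator for absorbing covariates into a deterministic substitution
microsimulation is specified anywhere.

## Synthetic population

The generator emulates the *group-level* statistics of the study
population — it is a calibration target-matcher, not a survey emulator:

- **Totals.** Lognormal marginals moment-matched to each group's mean/SD
  for energy, sodium, added sugar and fiber, coupled through a
  common-factor Gaussian copula (energy-nutrient correlation 0.5 by
  default — no between-nutrient covariance is published, so a mild
  positive dependence is an honest, configurable assumption). UPF energy
  share is logit-normal, moment-matched by Gauss-Hermite quadrature and a
  numeric root-solve; infeasible (mean, SD) targets raise naming the field.
- **UPF pools.** The mean UPF-attributable sodium/sugar/fiber amounts are
  set by inverting the full-replacement group results under the
  substitution multipliers (SNAP: 513.4 mg, 38.375 g, 2.26 g; non-SNAP:
  588.2 mg, 39.25 g, 2.50 g). Per participant the pool scales with their
  UPF energy share. These pools are *implied by printed results*, not
  measured facts; true UPF-vs-non-UPF density contrasts are unpublished.
- **Items.** Totals split into 8–20 items (UPF and non-UPF strata
  separately) with Dirichlet weights shared across nutrients, so item sums
  reproduce the drawn totals exactly; descriptions are sampled from the
  labeled vocabulary consistent with each item's intended group.
- **Demographics** sample the published category probabilities (sex,
  race/ethnicity, education, PIR band, food-security level); continuous
  PIR and raw scores are drawn uniformly within their band. Ages are
  normal around the published median with IQR-matched spread, clipped to
  18–85.
- **Design fields.** 15 strata × 2 PSUs assigned cyclically (guaranteeing
  estimable variance), lognormal weights. Real multistage cluster
  correlation, cycle pooling and weight construction are *not* emulated —
  passing tests show the estimators are correct and the calibration
  recovers its targets, not that design effects match any real survey.
- Everything is driven by one seed; identical configs are byte-identical.
  Every generation emits an audit (realized vs target moments, classifier
  round-trip rate, config hash).

Group sizes default to 767 SNAP / 5563 non-SNAP. (The source's prose
mentions a conflicting nonparticipant count; the tabulated unweighted n is
used, and sizes are config, not constants.)

## Numerical and reproducibility choices

- One global seed fans out to labeled substreams (generator groups, per-
  participant usual intake, impact simulation) via SeedSequence, so
  subset analyses and re-runs are stable by construction.
- Percentiles use NumPy's default linear interpolation; draw summaries are
  computed in memory-flat per-participant chunks.
- CSV round trips use repr-style floats with round-trip parsing, keeping
  numeric fields bit-exact.
- Default problem sizes used by the test suite: the full configured
  population (6330 participants, ~88k items) is generated once per run
  for calibration-recovery and ordering checks, with Monte Carlo draw
  counts reduced where draws do not affect the checked quantity; the full
  default fit (6330 × 10,000 draws) completes in well under a minute.

## Known limitations

- Keyword NOVA classification approximates, and cannot settle, genuinely
  ambiguous processing assignments; accuracy on real FNDDS vocabularies
  depends entirely on the rule table supplied.
- The substitution profile (50% sodium cut, 80% sugar cut, 50% fiber
  boost) is an optimistic stylization of minimally processed
  replacements; behavioral compensation (out-of-program purchases,
  cross-price elasticities) is not modeled.
- Risk projections are scalar relative reductions under linear
  no-threshold dose-response; no absolute-risk baseline, no joint
  nutrient-outcome correlation, no life-course accumulation.
- The synthetic population matches published marginals, not real joint
  structure; conclusions about estimator behavior on real survey data are
  limited accordingly.
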