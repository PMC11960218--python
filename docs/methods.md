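# Methods

This note documents the models and procedures implemented in `timeuse`,
the choices made where the design was genuinely open, and what the synthetic
cohort does and does not establish about real data.

## The measurement problem

A child's day is partitioned into sleep, sedentary time, light physical
activity (LPA) and moderate-to-vigorous physical activity (MVPA). Two
instruments estimate this partition: a wrist accelerometer worn continuously
(with a paper log of bed times, get-up times and removals), and an
interviewer-administered 24-h recall at ≥5-min resolution with an energy
cost (MET) per activity. The analysis asks two questions: *how far apart are
the two measurements per behaviour* (agreement statistics), and *does the
disagreement depend on who the child is* (compositional interaction models
over characteristics: sex, age, puberty stage, parental education, BMI
z-score, VO₂max, academic score).

## Accelerometry processing

Per sample, the signal vector magnitude is SVM = |‖a‖ − 1 g|. Epochs are
1 minute; the epoch value is **mean per-sample SVM × 60** (g·min). The
field convention "summed over 1-min epochs" is sampling-rate dependent; the
mean-based contract gives identical epoch values at any Hz, so one set of
cut-points serves every configured rate. Cut-point defaults (5.25 and
14.25 g·min) convert published children's wrist thresholds of 7 and 19 g·s
per 1-s epoch into this convention; they correspond to the MET bands <1.5 /
1.5–2.99 / ≥3, with the MVPA edge inclusive. The cut-points are
configuration, not constants: the synthetic generator reads the same
`CutPoints` object as the classifier, so ground truth and classification
stay consistent whatever values a user supplies.

Labelling precedence follows the instrument protocol: the logged sleep
window first (a removal logged inside the window is ignored — sleep wins),
logged removals second, then minutes without signal outside any log are
auto-labelled non-wear (a `strict_nonwear` mode raises instead, for
workflows that trust the log alone; manual visual correction of logs is out
of scope). Minutes are half-open [m, m+1); days run midnight to midnight;
a sleep window crossing midnight belongs to the day containing the bed time.

"Sports" removals of d minutes are reallocated 0.4 d to MVPA, 0.4 d to LPA
and 0.2 d to sedentary time — children's observed activity mix during
organised sport — as fractional minutes in the daily totals, not as
per-minute relabelling: the replacement concerns the aggregate, and
fractional minutes keep it exact. A day is valid with ≤360 min non-wear
**and** ≥600 min waking wear (both inclusive); a participant is valid with
≥4 valid days including ≥1 weekend day. Remaining non-wear is closed out by
linearly rescaling the four behaviours to 1440 min.

## Recall compilation

Sleep is a distinct diary entry, identified by label rather than MET, so
quiet wakeful rest (MET < 1.5) stays sedentary. Waking segments are binned
lower-inclusive at 1.5 and upper-inclusive at 3.0 METs. A diary tiles the
day by construction, so its composition sums to 1440 exactly. Recall days
with sleep < 300 min (strict) are excluded as implausible.

## Matching and averaging

A recall day enters only if the same child has a valid device day on the
same date. Device days are closed to 1440 *before* averaging (the non-wear
adjustment is part of day-level processing; the alternative order is not
distinguishable from published descriptions and differs negligibly at the
observed ~24 min/day of non-wear). Matched days are averaged per child and
method — averaging preserves closure — and children enter the models with
equal weight regardless of how many days they contributed; the day count is
kept on each record for sensitivity weighting.

## Agreement statistics

ICC(2,1) — two-way random effects, absolute agreement, single measure — is
computed from the two-way ANOVA mean squares with n children × 2 methods:
ICC = (MSR − MSE)/(MSR + MSE + (2/n)(MSC − MSE)), with the McGraw–Wong 95%
CI (Satterthwaite df) and F = MSR/MSE; point estimates are labelled poor /
moderate / good / excellent at 0.5 / 0.75 / 0.9. Bland–Altman uses
self − device differences with limits bias ± 1.96·SD (sample SD; the 1.96
multiplier is fixed rather than t-based, matching the conventional plot).
MAPE treats self-report as forecast and the device as actual; pairs with a
zero device value (possible for MVPA) are excluded with a warning and
counted.

## Compositional model

Compositions are expressed in isometric log-ratio (ILR) coordinates. The
sequential binary partition is not dictated by the analysis and defaults to
{sleep | SED, LPA, MVPA}, {SED | LPA, MVPA}, {LPA | MVPA} — sleep versus
waking, then sedentary versus active, then light versus vigorous. The
omnibus test is invariant to this choice up to variance-component
estimation (a basis change is a rotation; the method-contrast block depends
on the residual term only): empirically the χ² agrees across partitions to
~10⁻³ relative, and the property suite asserts 10⁻². Zero parts (rare after
averaging) are handled by multiplicative replacement with a 1-min floor.

Each child contributes 6 stacked rows (2 methods × 3 ILR coordinates). The
fixed effects are the full ILR × method × characteristic crossing; the
random effects are intercepts for wave, school-within-wave and
child-within-school plus child-level random effects indexed by ILR
coordinate (one defensible reading of "random slopes at the log-ratio
level": each child has their own level on each coordinate, shared across
methods). Estimation is maximum likelihood, not REML, so Wald blocks are
comparable across models with different fixed effects. On an outright fit
failure the random structure is simplified down a declared ladder — drop
the ILR random effects, then the wave intercept, then the school intercept
— and each step is recorded on the result. A variance component estimated
on its boundary can leave the default optimizer at a point with a singular
Hessian; the fitter retries with Powell's method (which lands at an
invertible point) before simplifying the structure.

The omnibus statistic is a Wald χ² on all fixed-effect terms containing
both the method factor and the characteristic: 3·(L−1) df for an L-level
categorical characteristic, 3 df for a continuous one. Continuous
characteristics are standardized (estimates reported at −1 SD / mean /
+1 SD) except age, kept on its raw scale with display levels 9.5 / 10 /
10.5 years. Model-based compositions use fixed effects only (random effects
at zero), back-transformed to min/day; they close to 1440 by construction.
One model is fitted per characteristic, unadjusted for the others.

Pattern taxonomy: with Δd and Δs the between-level differences of a
behaviour under device and self-report, a behaviour is **inverting** when
the differences point in opposite directions and both exceed the tolerance,
**isomorphic** when |Δs − Δd| ≤ tolerance (or both differences are within
tolerance of zero), **converging** when |Δs| < |Δd| − tolerance and
**diverging** when |Δs| > |Δd| + tolerance. The tolerance defaults to
5 min/day, matching whole-minute display rounding.

## Synthetic cohort

The generator emulates the study conditions the pipeline targets: 120
children (67% girls) aged 10.0 (SD 0.3), puberty 65/20/15% pre/early/mid,
parental education 7/36/57% low/mid/high, zBMI 0.17 (1.20), VO₂max 40.1
(6.6), academic score 126 (9) with 14% missing (the academic model runs on
the reduced sample); 12 schools over 2 waves; 7 measurement days per child
scattered over the school year with an expected 2/7 weekend fraction;
non-wear 24 (45) min/day truncated to [0, 300], 30% of it logged as
"sports". The base true composition is 588/488/279/85 min (which sums to
1440 exactly), with sex-specific means 595/459/280/106 (boys) and
585/502/278/75 (girls).

Day-to-day and between-child variation is a symmetric Dirichlet
perturbation around the level mean, parameterised by an approximate
relative SD (concentration c = 1/σ² − 1, so σ = 0 reproduces the mean
exactly). The within-person day-to-day spread of children's compositions is
not well pinned down in the literature; the defaults (person 0.07, day
0.05 — roughly 49 and 35 min SD on the sleep share) are free parameters
chosen as plausible, not estimates.

The signal model is deliberately stylised: each wear minute draws a target
epoch SVM uniformly inside its behaviour's configured band (bands validated
to lie strictly inside the cut-point bands, so ground truth is never
ambiguous), realised as white noise rescaled so the minute's mean SVM hits
the target exactly, carried on the vertical axis around 1 g. The
classifier only ever sees epoch SVM, so finer physiological realism
(gait, posture, orientation) would be untestable here — and is explicitly a
non-goal. Non-wear appears as absent samples by default, or as a flat 1-g
gravity signal to exercise log-only non-wear handling.

The recall bias model operationalises the known failure modes of
child self-report: (a) block-of-time rounding — diary boundaries snap to a
recall block (default 15 min); (b) a desirability shift of LPA into MVPA;
(c) homogenisation of interrupted quiet time — LPA shifted into sedentary
time; (d) a stretched sleep window — sedentary time absorbed into sleep —
plus absorption of night awakenings into sleep. Mechanism (c) and the
sleep-window stretch are needed because a log-based device pipeline also
counts in-window awakenings as sleep, so awakening absorption alone cannot
produce a self-report sleep excess. Defaults (+34 MVPA, +49 SED from LPA,
+37 sleep from SED) reproduce, in expectation before non-wear closure, the
reporting biases observed with this instrument pairing: self − device
≈ +37 sleep, +12 sedentary, −83 LPA, +34 MVPA min/day. Shifts that would
exhaust a behaviour are clamped at a 5-min floor with a logged warning.

All randomness descends from one seed through `numpy.random.SeedSequence`
substreams per child and per day, so any single day's signal can be
regenerated in isolation (the pipeline regenerates raw signal on demand
rather than storing it).

**What passing tests show — and don't.** With zero bias and zero noise the
full chain (raw → composition; diary → composition) reproduces ground truth
to within 1 min per behaviour, and planted method × characteristic effects
are recovered within a few min/day at n = 500. This validates the
*machinery*: transformations, model, tests, back-transforms. It does not
validate the signal model against real accelerometer output, the bias model
against real recall behaviour, or the cut-points against calorimetry —
those require field data.

## Numerical and scale choices

* Rounding of integer schedules uses largest-remainder apportionment, which
  preserves exact 1440 totals everywhere.
* The type-I calibration utility simulates stacked data directly on the ILR
  scale under the declared random structure and fits the real model; at 120
  children the Wald test runs slightly hot (ML variance estimates carry no
  small-sample correction), measured at 0.07 at the 200-replicate scale
  used in the test suite. It relaxes the lbfgs stopping tolerances
  (`factr=1e10, pgtol=1e-4`) and warm-starts successive replicates; the
  Wald χ² is insensitive to this (agreement with tight fits to ~3
  decimals).
* Test problem sizes (1–10 Hz signal, 20–500 children) are chosen so the
  whole suite runs in minutes on one core; epoch values are rate-invariant
  by construction, so low-rate runs exercise the same classification logic
  as 50 Hz.
* Determinism: identical configuration + seed gives byte-identical pipeline
  outputs; every output file carries a 16-hex-digit hash of the full
  configuration.

## Known limitations

* Device sleep is taken from the logged window; algorithmic sleep detection
  (and hence device-side awakening handling) is out of scope, as is parsing
  proprietary device binaries.
* The printed limits-of-agreement bounds in some published summaries of
  this design are internally inconsistent (sleep and LPA intervals appear
  swapped against the reported SDs); this package recomputes all limits
  from the data rather than reproducing any printed interval.
* One model per characteristic: no mutual adjustment, no multiple-testing
  correction across the seven characteristics.
* The pattern taxonomy compares the two extreme display levels only; a
  non-monotone middle level would not be flagged.
* MET values arrive in the diary file; curating an activity → MET
  catalogue is out of scope.
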