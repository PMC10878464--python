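# Methods

This note documents the models, operational definitions, numerical choices
and limitations behind `palscore`. Everything stated as a quantity is
computed by the test suite or the examples; nothing here is an empirical
claim beyond what the code reproduces.

## Event model and time base

A scenario is a list of instantaneous action events and a per-compression
stream, all timed in seconds from scenario start (t = 0), with a scenario
configuration (patient weight, default 10 kg — an arbitrary but typical
value, the checklist's dose target scales with it; duration, default 600 s;
required reversible causes; scoring thresholds). Two anchors are
first-class: scenario start (used for reported times-to-task) and
*recognition of the pulseless state*, defined as the earliest `pulse_check`
event with `pulse_result=absent` (used for checklist windows). All window
comparisons are inclusive ("within 60 s" means elapsed ≤ 60.0); events
exactly at the scenario duration are in scope, later ones are validation
errors. Unknown action kinds parse but are flagged as warnings, so extended
logs degrade gracefully.

Serialization is JSON (complete) and CSV. The CSV dialect's five columns
(`team_id, group, t_seconds, action, attributes`) cannot carry compressions
or configuration, so the dialect adds `compression` pseudo-action rows and
a `# record={...}` header comment; this keeps one CSV file a lossless,
round-trippable record.

## Deviation checklist

Fifteen binary items, each 1 when the task is omitted, late or incorrect;
the total is the deviation count (0 best, 15 worst). Items whose anchor is
recognition score as deviations when the pulseless state is never
recognized — the task chain never started, which the instrument treats as
a performance failure, not missing data. The same convention applies to
the second-adrenaline items when no first dose was ever given.

Operationalizations chosen where a human video rater would judge
holistically (all thresholds configurable and echoed in report metadata):

* **15:2 ratio (item 3).** The merged compression/ventilation timeline is
  split into alternating runs; every compression run followed by a
  ventilation run is a *completed cycle*. The item is correct iff ≥ 80% of
  completed cycles have 13–17 compressions followed by exactly 2
  ventilations. Trailing compressions with no subsequent ventilation are
  not a completed cycle; a log with no completed cycles deviates.
* **"While compressions are being performed" (items 9, 11).** The
  administration instant must fall inside a compression episode (see
  below). The saline flush must follow the administration within 30 s.
* **Dose tolerance.** Strictly less than 10% relative deviation from
  0.01 mg/kg; the dilution must equal 0.1 mg/ml; route IV or IO.
* **Compressor switches (item 5).** ≥ 2 `switch_compressor` events between
  the first compression and scenario end ("switched more than once" read
  literally).
* **Second-adrenaline windows.** Call window [180, 300] s and
  administration deadline ≤ 300 s after the first administration, both
  closed ("between 3 and 5 min" read inclusively).
* **Other medications (item 15).** Any `administer_medication` whose
  `med_name` is not in the configured cause-directed allow-list deviates;
  cause-directed treatments are exempt by construction.

## CPR metrics

Compressions whose inter-compression gap never exceeds the pause threshold
(default 2.0 s) form an episode running from its first to its last
compression. Mean rate is 60·n / (total episode time), i.e. over performed
CPR only, so pausing degrades the no-flow fraction rather than the measured
rate. The no-flow fraction is 1 − (episode time inside the resuscitation
period) / (period length); the period runs from recognition to scenario end
by default, with `first_compression` and `scenario_start` selectable
because mannequin software vendors do not state their denominator.
Complete recoil means a release residual ≤ 0.5 cm (configurable). The
quality bands are rate 100–120/min, depth 5–6 cm (the clinically coherent
reading of the recommended 50–60 mm), recoil in > 50% of compressions, and
no-flow < 20%. Active and no-flow time always sum exactly to the period
(conservation, tested), and the interval arithmetic agrees with a 10 ms
grid discretization within 1%.

## Performance rubric

The validated asystole instrument's item wording is not public, so the
engine is config-driven (predicates: action presence, anchored time
windows, attribute equality, dose tolerance, boolean combinators; full and
partial credit per item) and ships a *provisional* seven-item rubric
totalling 13: prompt pulse check, timely CPR, bag-mask ventilation,
vascular access, adrenaline given, correct adrenaline dose (six 2-point
items with 1-point partial credit for late/mere performance) and a 1-point
rhythm-management item (pulseless state identified and no shock). The real
instrument can be loaded from YAML/JSON once transcribed. Because the
synthetic generator always performs ventilation and vascular access and
rarely errs on dose, simulated cohorts saturate near the rubric maximum;
the rubric discriminates on real or hand-built logs, not on the default
synthetic cohort, and no calibration target is attached to it.

## Statistics

* **Fisher exact, r×2.** Full enumeration of all tables with the observed
  margins; two-sided p sums the multivariate hypergeometric probabilities
  of tables whose point probability is ≤ the observed one (relative guard
  1e-7 against representation ties; the sums themselves use exact integer
  arithmetic). Degenerate margins give p = 1, flagged in the method tag. An
  enumeration guard rejects N > 500.
* **Difference of proportions.** Reported in percentage points, oriented
  aid minus no-aid; CI by Wald (default) or Newcombe hybrid score — the
  method is always named in the output because "binomial method" alone is
  ambiguous. Point estimates, not CIs, are acceptance-tested.
* **Wilcoxon rank-sum.** Exact enumeration when the combined sample is
  ≤ 25 without ties, tie-corrected normal approximation otherwise; the
  method tag records the path.
* **Hodges–Lehmann.** Estimate = median of all m·n pairwise differences
  (y − x, aid minus no-aid). CI inverts the exact Mann–Whitney null
  distribution (classic counting recursion, cached): with ordered
  differences D₍₁₎…D₍ₘₙ₎ the 95% interval is [D₍ₖ₊₁₎, D₍ₘₙ₋ₖ₎] where k is
  the largest integer with P(U ≤ k) ≤ 0.025; a normal approximation of k
  is used beyond 2500 pairs. Small-sample coverage is checked by
  simulation in the tests.
* **Lin CCC.** Population (1/n) moments; undefined (error) when both
  samples are the same constant. The bootstrap CI is percentile-based,
  2000 case resamples by default, fully seeded; resamples where the
  statistic is undefined are dropped, more than 10% failures is an error.
* **Quantiles.** Medians/IQRs use the SAS empirical-distribution-with-
  averaging rule (`averaged_inverted_cdf`), matching the analysis software
  that produced the reference tables; e.g. {6,6,7,7,7,8,8} → IQR (6, 8).

## Synthetic cohort generator

The generator emulates the reference study conditions: 27 teams, 14
without and 13 with the pocket-card cognitive aid. Per team it draws 15
Bernoulli conformance indicators at the group's observed per-item
proportions (independent by default; an optional latent team-competence
factor with loading λ induces positive inter-item correlation through a
Gaussian copula — default λ = 0 because the true inter-item correlation is
unknowable from published marginals).

Task times are log-normal on the elapsed scale from the appropriate anchor,
with medians and sigmas fitted from the reference time-to-task medians and
IQRs (σ = ln(q3/q1)/(2·0.6745)) where those are reported, and plausible
fills otherwise (board positioning, adrenaline calls; values in
`TASK_TIME_DEFAULTS`). A draw is conditioned inside the item's checklist
window when the indicator is conformant and beyond it otherwise;
non-conformant optional tasks are omitted with probability 0.5. The
call-for-help median parameter is calibrated to 200 s so that the marginal
median of *emitted* call times (conformant early callers included) matches
the reference target. The compression stream is emitted in cycles (15:2
when the ratio item is conformant, 10:2 otherwise) with per-team rate,
depth, recoil fraction and a no-flow target drawn from the reference
distributions; cycle pauses are sized to approximate the no-flow target
but never shrink below 2.5 s, which biases very low no-flow targets
upward slightly.

The module's central contract is **generator–scorer consistency**: the
emitted log, scored by the checklist, reproduces the drawn indicators
exactly. Construction is feasibility-aware (e.g. the first adrenaline is
capped at 290 s when a conformant second dose must still fit; the first
adrenaline call is kept below the second-call window) and verified by
re-scoring, with bounded retries of the time draws only — indicators are
never redrawn, so item frequencies are untouched. Calibration is tested:
with 500 teams per stratum the per-item frequencies match the reference
proportions within 3 percentage points and the emitted time-to-task
medians match the reference medians within 15%.

What the generator does *not* emulate: patient physiology, team dynamics,
correlation between task times and conformance beyond the window
conditioning, and rater behaviour beyond independent per-item flips.
Passing pipeline tests on synthetic cohorts therefore demonstrates the
scoring and statistical machinery, not the realism of any particular
simulated team.

## Problem sizes

The default test suite simulates cohorts of 27 teams and pools of up to
1,000 random team logs; the reproduction script runs 200 cohort
replicates. These sizes give stable modes/medians while keeping the whole
suite and the script each under a minute of compute on one core.

## Known limitations

* The checklist's video-rater judgements (ratio quality, flush timing) are
  operationalized with thresholds a rater never needed to state; all are
  configurable and reported in metadata, but other operationalizations are
  defensible.
* The shipped rubric is an approximation; rubric totals from it are not
  comparable to published totals from the validated instrument.
* The exact "binomial method" behind published proportion-difference CIs
  is not stated; the package names its method in every output rather than
  guessing, and only point estimates are reproduced.
* Exact Fisher enumeration is exponential in rows; fine for r ≤ 4, N ≤ 100
  as used here, guarded at N = 500.
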