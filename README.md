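# palscore

Guideline-adherence scoring and stratified analysis for **simulated
pediatric cardiac arrest** scenarios.

Pediatric cardiac arrest is rare, its management is time-critical, and
deviations from pediatric advanced life support (PALS) guidelines are
associated with worse outcomes. Simulation studies measure adherence by
video-reviewing teams of clinicians running a standardized nonshockable
arrest scenario and scoring each team on structured checklists. `palscore`
is a toolkit for researchers and simulation educators running such studies:
it turns timestamped scenario event logs into checklist scores, CPR quality
metrics and a complete two-group statistical report, and it ships a
calibrated synthetic cohort generator so every stage can be exercised and
tested without access to (typically unpublished) study data.

## What it computes

**15-item deviation checklist** (`palscore.cdev`). Each item encodes one
recommended task for a nonshockable pediatric arrest; a team scores 1 per
item that is omitted, late or incorrect, so the total runs from 0 (perfect
adherence) to 15. Timed items are anchored at *recognition of the pulseless
state* (first pulse check finding no pulse). Examples: CPR within 30 s of
recognition; CPR board within 60 s; 15:2 compression:ventilation ratio;
first adrenaline at 0.01 mg/kg (strict <10% tolerance), 0.1 mg/ml
(1:10,000) dilution, IV/IO, flushed, during active compressions, within
180 s; no shock in a nonshockable rhythm.

**Performance rubric** (`palscore.rubric`). A config-driven engine for
clinical-performance-tool-style instruments (predicates over the event log,
full/partial credit). The shipped seven-item asystole rubric totals 0–13
(higher is better) and is an explicitly provisional approximation of the
validated instrument, replaceable from YAML/JSON.

**CPR quality** (`palscore.cpr`). From the per-compression stream:
mean rate over performed CPR, mean depth, % of compressions with complete
chest recoil, and the **no-flow fraction** — the share of the resuscitation
period without compressions — each flagged against the AHA bands
(100–120/min, 5–6 cm, recoil >50%, no-flow <20%).

**Statistics** (`palscore.stats`). The small-cohort toolkit used in such
studies: exact Fisher tests for r×2 tables by full enumeration with the
point-probability two-sided rule; differences of proportions with binomial
CIs; Wilcoxon rank-sum; the Hodges–Lehmann shift estimate
(median of all pairwise differences) with CI by inversion of the exact
Mann–Whitney distribution; Lin's concordance correlation coefficient
`CCC = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²)` with a seeded 2000-resample
bootstrap CI; medians/IQRs under the SAS quantile rule.

**Synthetic cohorts** (`palscore.cohort`). Seeded generation of a 27-team
cohort stratified by pocket-card use (14/13), drawing per-item conformance
indicators at the reference proportions and per-task times from log-normal
distributions fitted to the reference medians/IQRs, then emitting event
logs that *score back exactly to the drawn indicators* — the generator's
central, tested contract.

**Pipeline** (`palscore.pipeline`, CLI `palscore`). `run_study` produces a
stratified report: per-item frequencies with group differences and Fisher
p-values, median/IQR comparisons with Hodges–Lehmann CIs and rank-sum
p-values, CPR band frequencies, optional dual-rater agreement, and full run
metadata; rendered to lossless JSON, CSV or markdown.

## Worked example

```sh
python examples/04_simulate_and_report.py
```

```
cohort deviation median: 7 (IQR 6-8) of 15   [n=27]
performance rubric median: 13 (IQR 12-13) of 13
most frequent deviations:
   92.6%  CPR board positioned within 60 s from recognition of pulsele
   92.6%  Help called within 60 s from recognition of pulseless state
  100.0%  First adrenaline called within 30 s from recognition of puls
aid vs no-aid deviation shift: 0 (95% CI -2 to 1), p = 0.406
inter-rater CCC: 0.709 (95% CI 0.476-0.829)
full report written to report_out/report.md
```

The first line is the cohort's median deviation count (7 of 15 tasks
deviant for the typical team); the deviation percentages name the tasks
most often failed; the shift line is the Hodges–Lehmann estimate of the
aid-minus-no-aid difference in deviation totals with its exact-inversion
CI and rank-sum p-value; the CCC line quantifies agreement between two
simulated video raters. `examples/01–03` show single-team scoring, CPR
metrics and the statistical toolkit in isolation, and the same workflow is
available from the shell:

```sh
palscore simulate cohort_dir --seed 11
palscore report cohort_dir --out-dir report --format markdown
```

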