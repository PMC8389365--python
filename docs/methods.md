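# Methods

## Score computation

The lab-MELD score is computed on the mg/dL scale:

```
MELD = round(10 · (0.957 ln Cr + 0.378 ln Bili + 1.12 ln INR + 0.643))
```

Inputs arrive in the laboratory's SI units (bilirubin and creatinine in
µmol/L, sodium in mmol/L) and are converted with the divisors 88.4
(creatinine) and 17.1 (bilirubin); the creatinine factor is pinned by the
regulatory equivalence 353.6 µmol/L = 4.0 mg/dL used for the dialysis
override. Each component is floored at 1.0 (INR included), creatinine is
capped at 4.0 mg/dL, and the final score is clamped to [6, 40]. When the
stated dialysis status meets the official criteria — at least two
intermittent sessions, or ≥ 24 h of CVVHD, within the prior week —
creatinine is set to the cap regardless of the measured value; albumin
dialysis never qualifies. Rounding is half-up throughout (allocation
practice). MELD-Na adds `1.32·(137−Na) − 0.033·MELD·(137−Na)` with sodium
clamped to [125, 137] mmol/L, only when the initial MELD is at least 11; the
adjustment is non-negative and capped at 40, so MELD-Na ∈ [MELD, 40]. The
weights, clamps, bounds and the MELD-Na threshold sit in
`ScoreCoefficients`, so a regulatory variant is a configuration change. The
lab-MELD is the default reported score; MELD-Na is always computed alongside
when sodium is available, since which of the two an allocation body consumes
is a policy question, not a laboratory one.

## Verification rules

Rules run in a fixed sequence — order integrity, preanalytics, INR
resolution, dialysis plausibility, anticoagulation, delta check — and a
verdict's reason codes keep that order, so the first code names the earliest
failing stage. Blocking codes (wrong or missing material, underfilled or
clotted citrate, misidentification, transport/entrance violations, split
orders, pediatric routing, anticoagulation impact, an unresolvable INR)
yield INVALID with no score. Dialysis-status issues, delta-check failures
and a resolved-but-undeterminable INR escalate to NEEDS_CONSULTATION; a
resolved undeterminable INR is routed to consultation rather than released
because the substituted value requires physician sign-off. `apply_correction`
turns a dialysis consultation into CORRECTED_VALID once the sender confirms
a status; the plausibility heuristic is not re-applied to a human-confirmed
status, but a confirmed status that itself fails the official interval
criteria keeps the case in consultation.

Thresholds the source workflow names without quantifying are explicit,
configurable defaults chosen from common laboratory practice:

| parameter | default | rationale |
|---|---|---|
| co-draw tolerance | 0.5 h | "sent in at the same time" for one order |
| preanalytical window | 4 h | INR stability of citrate blood |
| late-entrance window | 24 h | order-to-arrival plausibility |
| citrate underfill | fill ratio < 0.90 | citrate:blood mixing ratio convention |
| PELD age | < 12 years at draw, calendar arithmetic | validation range of MELD |
| dialysis implausibility | stated RRT with creatinine < 100 µmol/L | RRT patients carry elevated creatinine; an unremarkable value flags an order-creation mistake. The check deliberately uses only the current value: a history-based trajectory hook exists but is not part of the default heuristic |
| anticoagulation impact | INR > 1.5 with VKA/DOAC stated; or INR > 1.2 × the latest non-anticoagulated baseline while every comparable synthesis marker (albumin, fibrinogen, cholinesterase) is within ±20% | the stable-marker condition separates undeclared anticoagulation from true synthesis failure |
| delta checks | creatinine 100%, bilirubin 150%, INR 75% relative change vs the most recent prior within 7 days | conventional delta-check bands for these analytes |
| INR timeout | 315 s | instrument clot-detection limit |
| INR policy | `last_determinable` (also: `table_max` 9.0, `block`) | the policy the allocation auditors accepted; the conversion-table maximum is the stricter alternative |

Timestamps are ISO 8601, timezone-naive, single-site clock. Heparin is
non-blocking unless the baseline comparison fires; the rare massive heparin
overdose that suppresses the prothrombin-time reaction itself surfaces only
through the delta/anticoagulation heuristics, not through a thrombin-time
model.

## Synthetic cohorts and error injection

The simulator emulates a six-year tertiary-care MELD workload: log-normal
bilirubin (median ≈ 32 µmol/L) and creatinine (median ≈ 86 µmol/L), a
shifted log-normal INR (median ≈ 1.3), dialysis prevalence 7.7% with
renal-replacement patients drawing elevated creatinine so their stated
status is congruous with the laboratory picture, an anticoagulation mix of
488 heparin, 33 VKA, 2 fondaparinux and 1 DOAC per 7,270 requests, and
geometric repeat requests averaging ≈ 4.9 per patient (≈ 1,500 patients per
7,270 requests). Every patient starts with one pre-cohort validated result
two days before their first request — transplant-evaluation patients have
prior laboratory results on file — which gives the delta check and the
anticoagulation baseline something to compare against from the start.
Repeat results jitter multiplicatively around the patient's profile values
(±15% for bilirubin/creatinine, ±8% for INR), which keeps clean requests
inside every delta and baseline band by construction.

Default per-category injection probabilities encode the observed category
counts of that workload divided by 7,270: the seven preanalytical categories
(56, 7, 7, 5, 5, 3, 2 = 85), 4 missing dialysis statuses, 24 anticoagulation
impacts, 8 dialysis-interval violations, 26 implausible dialysis statements
(including the stated-negative corrections), 1 albumin dialysis, 42
undeterminable INRs, and 3 delta-check events — 193 in total, the 2.7%
flagged fraction. The per-category split of the non-preanalytical remainder
is an allocation consistent with the published totals, not an estimate; only
the overall fraction is calibrated. At most one category is injected per
request (primary-cause bookkeeping); multi-error requests sit behind a flag
and are excluded from rate-recovery tests. Each injection minimally mutates
a clean request so the targeted rule fires *first*; a large injected
excursion may legitimately trip a downstream check as a secondary code
(e.g. a VKA-inflated INR also fails the INR delta band).

What the simulator does **not** emulate: sex-stratified analyte differences
(Table-style p-values for the real cohort's joint distribution are out of
reach of independent log-normal marginals), assay-level method effects,
seasonal workload structure, and correlated multi-analyte failures. Passing
tests therefore demonstrate the correctness and calibration of the rule
engine, not the epidemiology of any real cohort.

## Numerical and design notes

* Half-up integer rounding everywhere a score or percentage is printed;
  percentages to one decimal.
* The verification pipeline (`run_pipeline`) processes requests in
  chronological order and appends only *released* (VALID) results to the
  working history, mirroring routine operation; it operates on copies, so
  repeated runs are byte-identical. A consequence worth knowing: when a long
  run of a patient's requests fails verification, the delta check can lose
  its within-window comparator and a delta injection may go unflagged. At
  the default 2.7% error load this is negligible; at artificially inflated
  rates it shows up as a small, expected recovery deficit.
* `chi_square_2x2` delegates to the Pearson chi-squared test without
  continuity correction (the correction is a flag), df = 1.
* Degenerate inputs fail loudly: non-positive concentrations, zero-margin
  tables, empty cohorts and mismatched verdict/request lists all raise.
* Cohort summaries count unresolved consultations as unreported: no score
  leaves the laboratory without a resolution.

## Problem sizes

The acceptance computation simulates 20 cohorts of 7,270 requests
(145,400 validations, well under a minute on one CPU); the property suites
use 10,000 random panels for score-oracle equivalence and cohorts of
500–3,000 requests for purity and rate recovery.

## Known limitations

PELD is routed (requests for patients under 12 are blocked with
`PELD_REQUIRED`) but never computed; match-MELD / standard-exception scores
and any allocation-body transmission interface are out of scope. The
anticoagulation heuristic cannot exclude drug intake with minor INR changes
— the same limitation the manual validation it models has.
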