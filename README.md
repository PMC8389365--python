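# meldqa — quality-assured lab-MELD diagnostics

The Model for End-stage Liver Disease (MELD) score predicts three-month
mortality in end-stage liver disease and decides the priority of patients on
the liver-transplant waiting list. It is computed from three laboratory
analytes on the mg/dL scale,

```
MELD    = round(10 · (0.957 ln Cr + 0.378 ln Bili + 1.12 ln INR + 0.643))
MELD-Na = round(MELD + 1.32 · (137 − Na) − 0.033 · MELD · (137 − Na))   (MELD ≥ 11)
```

with every component floored at 1.0, creatinine capped at 4.0 mg/dL
(353.6 µmol/L), the final score clamped to [6, 40], and sodium clamped to
[125, 137] mmol/L. Patients under renal replacement therapy — at least two
dialysis sessions, or ≥ 24 h of continuous veno-venous hemodialysis, within
the prior week — have their creatinine overridden to 4.0 mg/dL.

Because an inflated score can move a patient up the allocation list,
transplant laboratories screen every MELD request before a score leaves the
laboratory. `meldqa` implements that screen as a rule engine with
machine-readable reason codes:

* **order integrity** — serum and citrate tube ordered and drawn together in
  one laboratory order; dialysis status stated;
* **preanalytics** — transport time, late laboratory entrance, underfilled or
  clotted citrate (both falsify the INR), patient misidentification,
  pediatric requests routed to the PELD pathway;
* **dialysis plausibility** — stated status against the official criteria and
  against the creatinine picture; albumin dialysis is not renal replacement;
* **anticoagulation** — vitamin-K antagonists and direct oral anticoagulants
  inflate the INR; an unexplained INR rise with stable liver synthesis
  markers (albumin, fibrinogen, cholinesterase) suggests undeclared intake;
* **coagulation measurability** — in advanced liver failure no clot may form
  within the instrument timeout (315 s); the undeterminable INR is resolved
  by policy (last determinable INR, conversion-table maximum, or block);
* **delta checks** — improbable changes versus the patient's prior results.

Each request ends VALID (score released), CORRECTED_VALID (released after a
sender-confirmed dialysis correction), NEEDS_CONSULTATION, or INVALID
(blocked). A synthetic cohort simulator with calibrated per-category error
injection makes the whole pipeline testable end-to-end without patient data.

Intended users: clinical-chemistry and transplant-laboratory software teams,
and anyone studying autoverification rules for allocation-relevant scores.

## Worked example

Score one panel (bilirubin 34.2 µmol/L = 2.0 mg/dL, creatinine
132.6 µmol/L = 1.5 mg/dL, INR 1.3, sodium 131 mmol/L):

```
$ meldqa score --bilirubin 34.2 --creatinine 132.6 --inr 1.3 --sodium 131
{
 "score": 16,
 "meld_na": 21,
 "bilirubin_mg_dl": 2.0,
 "creatinine_mg_dl": 1.5,
 "inr": 1.3,
 "dialysis_override_applied": false,
 "clamps_applied": []
}
```

The lab-MELD is 16 (10·(0.957 ln 1.5 + 0.378 ln 2 + 1.12 ln 1.3 + 0.643) =
15.87, rounded half-up); with sodium 131 the MELD-Na rises to 21.

Simulate a cohort, validate it and summarize the dispositions:

```
$ meldqa simulate --n-requests 2000 --seed 42 --out cohort.csv --truth-out truth.json
$ meldqa summarize cohort.csv
{
 "n_requests": 2000,
 "n_valid": 1941,
 "n_invalid": 59,
 "valid_pct": 97.1,
 "flagged_pct": 3.0,
 "unreported_pct": 3.0,
 "reason_counts": {
  "MATERIAL_ERROR": 21,
  "DIALYSIS_IMPLAUSIBLE": 13,
  "INR_UNDETERMINABLE": 9,
  "ANTICOAGULATION_INR_IMPACT": 6,
  "DELTA_CHECK_FAIL": 5,
  ...
 }
}
```

59 of 2,000 simulated requests (3.0%) failed verification under the default
injection rates; the remaining 97.1% released a validated score.
`unreported_pct` includes consultation cases that were never resolved — in
library use, `apply_correction` turns a confirmed dialysis consultation into
a CORRECTED_VALID release with the old and new status on record.

The same workflow is available in Python:

```python
from meldqa import SimulationConfig, simulate_cohort, run_pipeline, summarize

bundle = simulate_cohort(SimulationConfig(n_requests=2000, seed=42))
verdicts = run_pipeline(bundle)
print(summarize(verdicts, bundle.requests).flagged_pct)   # 3.0
```

Every threshold of the rule engine (transport window, citrate fill ratio,
delta-check bands, INR policy, score coefficients …) lives in a YAML config;
see `meldqa.config.VerificationConfig` and the `--config` option of every
CLI verb.

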