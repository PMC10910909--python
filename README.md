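# ehrprep

Quantify how data-preparation choices in primary-care electronic health
records (EHR) change the discrimination and calibration of a Cox
cardiovascular risk model.

A synthetic EHR generator with known ground truth emulates the data-quality
mechanisms of routinely collected records — left-truncated registration,
risk-dependent (MNAR) measurement of blood pressure and cholesterol, and
imperfect dual-channel outcome recording through diagnosis and medication
codes. A pipeline then builds run-in cohorts, applies coded outcome
definitions, handles missing baseline values, fits a five-predictor
proportional-hazards model and validates it under a repeated 70/30
derivation/validation split design in which the derivation arm varies and the
validation arm always uses the reference preparation.

## Layout

| module | role |
| --- | --- |
| `ehrprep.synthetic_ehr` | longitudinal coded-event generator (diagnoses, prescriptions, measurements) with separate ground truth |
| `ehrprep.cohort_builder` | run-in period, time-zero definition, eligibility, baseline aggregation, follow-up |
| `ehrprep.outcome_engine` | five coded operationalizations of "first-ever major adverse cardiovascular event" |
| `ehrprep.missing_data` | chained-equation multiple imputation, fixed population-mean imputation, complete-case analysis, elastic-net auxiliary ranking |
| `ehrprep.survival_model` | Cox model (Efron ties, Breslow baseline) with absolute 10-year risk transform |
| `ehrprep.performance` | Harrell's c-index, calibration-in-the-large, recalibration slope, decile calibration curve, percentile intervals |
| `ehrprep.experiment_engine` | the nine dataset variants, repeated ID-split orchestration, summary tables |
| `ehrprep.io` / `ehrprep.cli` | long-format CSV persistence and the `ehrprep` command line |

## Command line

```bash
# write a synthetic population (events.csv, patients.csv, ground_truth.csv)
ehrprep simulate --seed 1 --n-patients 20000 --out-dir scratch/pop

# run the full nine-variant experiment and write metric / summary CSVs
ehrprep run --seed 1 --out-dir scratch/results --n-repeats 50

# pretty-print a previous run
ehrprep report --out-dir scratch/results
```

A YAML config can override any generator field, the cohort settings, the
imputation settings and the variant list:

```yaml
generator:
  n_patients: 20000
  seed: 1
  diagnosis_sensitivity: 0.444
n_repeats: 50
imputation: {m: 5}
variants:
  - {label: reference}
  - {label: outcome ICPC_only, outcome: ICPC_only}
```

## Conventions

* Time is integer days; day 0 is the start of the data window; registration
  windows are half-open; one year is 365 days.
* Calibration intercept = logit(Kaplan-Meier observed risk at 10 years) −
  logit(mean predicted risk); positive values mean the model underestimates
  risk.
* Calibration slope = coefficient of the frozen linear predictor in a
  proportional-hazards recalibration fit on the validation arm.
* Event proportions are reported as Kaplan-Meier risks at the 10-year
  horizon, so they are comparable under censoring.
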