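# miscbias

Quantifies misclassification bias when the case status of a rare surgical
procedure is assigned from administrative data by three competing methods:

1. **code** — procedure-code flags taken at face value;
2. **categorical** — a multinomial prediction model's probability,
   thresholded at the Youden-optimal operating point;
3. **bootstrap imputation (BI)** — repeated cohort resampling in which each
   record's status is imputed by comparing a uniform draw with its predicted
   probability, with statistics averaged over replicates.

The pipeline simulates a hospitalization cohort (3-level true status:
incontinent diversion / continent diversion / none, plus ~30 covariates and
error-prone code flags), builds and internally validates the prediction
model, produces the three assignments, measures 30 association statistics
(prevalence, 3 continuous mean differences, 26 binary log odds ratios) under
each, and compares methods by the standardized mean squared error
SMSE = (β − β_T)² / |β_T| using ANOVA on log SMSE with Tukey's
studentized-range test.

## Layout

| module | contents |
| --- | --- |
| `miscbias.cohort` | synthetic cohort generator (`CohortSpec`, `generate_cohort`, `assign_codes`) |
| `miscbias.accuracy` | 2×2 operating characteristics (`ContingencyTable`, `compute_accuracy`) |
| `miscbias.model` | df budget, FP1 transforms, ranked forward selection, prediction, bootstrap optimism-corrected c-statistic / ICI |
| `miscbias.assignment` | code / threshold / bootstrap-imputation assignment |
| `miscbias.bias` | statistic battery, SMSE, ANOVA + Tukey comparison |
| `miscbias.pipeline` | `RunConfig`, `run_study`, report bundle |
| `miscbias.cli` | `miscbias` command-line interface |

## CLI

Each stage reads/writes files so it can be run and inspected independently:

```bash
miscbias run-all  --profile test --seed 1 -o out/      # full study bundle
miscbias simulate --profile test --seed 1 -o out/
miscbias fit      --cohort out/cohort.csv -o out/model.json
miscbias validate --cohort out/cohort.csv --model out/model.json -o out/validation.json
miscbias assign   --cohort out/cohort.csv --model out/model.json -o out/
miscbias bias     --cohort out/cohort.csv --model out/model.json -o out/
miscbias report   -d out/
```

`--profile paper` runs the full-scale protocol (428,697 rows, 1000
bootstraps); `--profile test` is the reduced profile (no-procedure class at
50,000 rows, case counts preserved, 200 bootstraps). A YAML config can
override either:

```yaml
profile: test
seed: 7
n_none: 20000
n_boot_validation: 100
n_boot_imputation: 100
```

The report bundle contains the cohort CSV, model JSON, validation report,
Table-3-style accuracy blocks for all four classifiers, tidy statistic and
SMSE tables, the method-comparison JSON, and a run log with realized counts.
Outputs are byte-identical for an identical config and seed.

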