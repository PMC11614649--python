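# poppk

Population-pharmacokinetic modelling and Monte Carlo dose optimisation
for sparse therapeutic-drug-monitoring (TDM) data, built around a
one-compartment oral quetiapine model with allometric weight scaling
and binary drug–drug-interaction (DDI) covariates for fluvoxamine and
duloxetine.

The package provides the full pipeline:

| Module | Purpose |
| --- | --- |
| `poppk.dataset` | NONMEM-style event CSVs (ID/TIME/AMT/DV/EVID/WT/FLU/DUL) — read, write, validate |
| `poppk.structural` | closed-form one-compartment first-order-absorption kinetics: single dose, superposition, steady state |
| `poppk.model` | fixed effects, covariate structure (allometric / power / linear), log-normal IIV on CL/F, combined proportional + additive residual error |
| `poppk.estimation` | FOCE-with-interaction estimation, standard errors, stepwise covariate search (ΔOFV 3.84 in / 6.63 out) |
| `poppk.bootstrap` | subject-resampling bootstrap: medians, 5th–95th percentile intervals, bias (%) |
| `poppk.diagnostics` | PRED/IPRED/iWRES tables, FO weighted residuals, visual predictive check |
| `poppk.simulation` | probability of target attainment (100–500 ng/mL window) over a weight × dose × DDI grid; dose recommendations |
| `poppk.cohort` | synthetic sparse-TDM cohort generator (96 subjects, ~1.6 samples each, configurable) |
| `poppk.cli` | `poppk generate / fit / bootstrap / diagnose / simulate / recommend` |

Variance components (`omega2_cl`, `sigma2_prop`, `sigma2_add`) follow
the NONMEM OMEGA/SIGMA convention (variances); set `params_are_sd=True`
to interpret them as standard deviations.

## Command-line pipeline

```sh
poppk generate --out data.csv                        # synthetic cohort (defaults)
poppk fit --data data.csv --model model.yaml --out fit.json
poppk bootstrap --data data.csv --model model.yaml --reps 1000 --seed 1 --out boot.json
poppk diagnose --data data.csv --fit fit.json --out-prefix diag
poppk simulate --model model.yaml --seed 1 --out pta.csv
poppk recommend --pta pta.csv --out recommendations.csv
```

`model.yaml` is a serialised `PopulationModel`
(`PopulationModel.to_yaml`); the default published quetiapine model is
available as `poppk.default_quetiapine_model()`:
CL/F = 118·(WT/70)^0.75·(1−0.536·FLU)·(1−0.537·DUL) L/h,
V/F = 2460·(WT/70) L, Ka fixed at 1.46/h.

The dosing simulation's regimen policy (dosing interval, evaluated
steady-state metric `trough`/`cavg`/`cmax`, residual error on/off) is
explicit and swappable via `SimulationDesign`, since it materially
changes the attainment probabilities.

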