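# linklcm

Probabilistic record linkage via a loglinear latent-class model with
conditional-dependence diagnostics.

The classical Fellegi–Sunter model treats agreement of identifier fields as
independent given the latent match status of a record pair. `linklcm`
reparameterizes that model as a loglinear model over agreement patterns and
relaxes the independence assumption with pairwise within-class interaction
terms. It implements the full iterative workflow:

1. fit the conditional-independence (CI) model to an agreement-pattern
   frequency table;
2. compute observed pairwise agreement correlations;
3. compute the correlations implied by the fitted model's expected counts;
4. inspect the correlation residuals (observed − expected) — residuals with
   absolute value above ≈0.05 flag conditionally dependent field pairs;
5. for the worst pair, fit four interaction structures (match class only,
   nonmatch class only, both classes with distinct coefficients, both with a
   shared coefficient) and keep the BIC winner; repeat 2–5;
6. score and classify record pairs with the final model (log2 likelihood
   ratios, posterior match probabilities, or prevalence-ranked counts).

## Library overview

| module        | contents |
| ------------- | -------- |
| `linklcm.data` | record comparison, blocking, agreement-pattern tables, CSV I/O |
| `linklcm.model` | cell means, pattern probabilities, λ ↔ (π, m, u) mappings, match scores, G², BIC |
| `linklcm.estimation` | `fit_ml` (quasi-Newton, multi-start), `fit_em` (independent EM cross-check), delta-method standard errors |
| `linklcm.diagnostics` | observed/expected correlations, residuals, flagging, residual plots |
| `linklcm.stepwise` | four-structure comparison and the full iterative procedure |
| `linklcm.scoring` | posteriors, match scores, classification rules |
| `linklcm.synthetic` | scenario-based generators and parameter-recovery studies |

```python
import numpy as np
from linklcm import FitOptions, run_stepwise
from linklcm.data import read_table_csv

table = read_table_csv("table.csv")
trace = run_stepwise(table, FitOptions(seed=17))
fit = trace.chosen
print(fit.classical.pi, fit.deviance, fit.bic)
```

## CLI

```sh
# raw records -> agreement-pattern table (blocked de-duplication)
linklcm build --input clients.csv --block last_name,first_name \
    --fields yob,ssn,dob_day,telephone,zip,sex,dob_month --out table.csv

# fit a model, diagnose residuals, run the full stepwise procedure
linklcm fit --table table.csv --seed 17 --out fit.json
linklcm diagnose --table table.csv --fit fit.json --plot residuals.png --out residuals.csv
linklcm stepwise --table table.csv --seed 17 --report trace.json --plots-dir figs/

# score and classify
linklcm score --table table.csv --fit fit.json --rule posterior:0.5 --out scored.csv

# draw synthetic data from a scenario YAML
linklcm simulate --scenario scenario.yaml --out sim.csv
```

Pre-computed pair-level agreement data (one 0/1 row per record pair,
optionally weighted by a `count` column) loads with
`--input-kind agreements`; aggregated pattern tables with
`--input-kind table`.

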