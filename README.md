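# hhineq

Survey-weighted analysis of socio-economic inequality in a binary household
outcome (a 7-day "no household hunger" indicator), built as a reusable Python
package:

* **`hhineq.survey_core`** — validated survey table model, outcome
  harmonization across the two source coding conventions, weighted fractional
  (midpoint) ranks with tie-group averaging, weighted SES quintiles, and
  weighted prevalence tables with effective-sample-size logit confidence
  intervals.
* **`hhineq.wreg`** — probability-weighted logistic (IRLS) and
  linear-probability regression with robust sandwich variance, automatic
  perfect-prediction/collinearity screening, odds-ratio tables with a/b/c
  significance marks, average marginal effects, and the diagnostic suite
  (Hosmer–Lemeshow, weighted ROC AUC, VIF, link test).
* **`hhineq.cindex`** — standard, Erreygers and Wagstaff concentration
  indices with convenient-regression robust standard errors and a seeded
  household bootstrap, plus pro-rich / pro-poor interpretation labels.
* **`hhineq.decomp`** — regression-based decomposition of the index into
  per-factor contributions, percent shares and an unexplained residual;
  SES-specification sensitivity (categorical vs ordinal) with a joint Wald
  test and weighted McFadden pseudo-R².
* **`hhineq.synthetic_survey`** — seeded generator of survey tables with a
  latent wealth score, quintile-graded covariates, heterogeneous weights and
  a logistic outcome whose intercept is calibrated by bisection to a target
  prevalence; shipped per-round default configurations (`wave1`…`wave5`,
  `nfnss`).
* **`hhineq.pipeline_cli`** — a config-driven end-to-end pipeline
  (simulate/load → describe → regress → index → decompose → diagnose) with
  byte-stable text artifacts.

Note on the emulated sources: the published Wave-1 hunger headline (26.47%)
is not the exact complement of the published Wave-1 no-hunger proportion
(77.69%); this package always computes complements consistently from the
no-hunger proportion.

## CLI

```sh
# write a synthetic survey round as CSV
hhineq simulate --wave wave1 --n 5652 --seed 1 --out wave1.csv

# small deterministic 200-row fixture
hhineq fixture --out fixture.csv

# full analysis from a config (or default simulated wave 1)
hhineq analyze --config config.yaml --seed 1 --out results/ \
    --model lpm --index erreygers

# decomposition table only
hhineq decompose --seed 1 --out decomposition.csv

# re-render a previously written analysis directory
hhineq report --dir results/
```

A config file (YAML or JSON) either simulates or loads data:

```yaml
simulate: {wave: wave1, n: 5652}   # or: input: {path: survey.csv}
formula: "outcome_no_hunger ~ employment + race + C(ses_quintile) + dwelling
  + electricity + piped_water + education + sex + household_size + age"
model: lpm          # or logit_ame
index: erreygers    # or standard / wagstaff
bootstrap: 0        # B > 0 switches the index SE to a seeded bootstrap
```

`analyze` writes prevalence (overall / by quintile / by province),
regression, index and decomposition CSVs plus `summary.json` (diagnostics,
provenance with seed and config hash) and a plain-text report. Runs are
byte-identical under a fixed seed.

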