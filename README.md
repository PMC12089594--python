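# vaxstab

Hierarchical Bayesian stability modelling and shelf-life estimation for
multivalent biologic products (e.g. a 9-valent vaccine assayed per molecular
type in vials and pre-filled syringes).

The package provides:

* **`vaxstab.core_io`** — domain types (`StabilityRecord`, `StabilityDataset`)
  and lossless CSV I/O for long-format stability tables, plus time-split
  partitioning for train/test validation.
* **`vaxstab.synthetic_data`** — a seeded generator for cohorts with the
  statistical structure the analysis assumes: 30 batches (17 syringe,
  13 vial), 9 molecular types, storage at 5/25/37 °C, temperature-indexed
  degradation slopes (optionally tied by Arrhenius kinetics), an optional
  saturating taper of the time trend, and dominant batch-independent assay
  noise. The default training design yields exactly 2160 measurements.
* **`vaxstab.hier_model`** — the hierarchical Bayesian model: normal
  likelihood, linear time trend, batch-within-type layers for intercepts and
  per-temperature slopes, an additive container offset (vial reference), and
  a shared residual variance. Estimated by a pure Gibbs sampler (all full
  conditionals conjugate; translation moves keep level means mixing well),
  with posterior predictive / mean-profile intervals, shelf-life estimation
  (largest month at which the one-sided lower 95 % bound stays at or above
  the specification limit), posterior summaries, and a closed-form conjugate
  oracle used to verify the sampler in tests. An optional
  Arrhenius-constrained variant (Metropolis-within-Gibbs on activation
  energy) supports extrapolation to unseen temperatures.
* **`vaxstab.comparators`** — the two baselines of the simulation benchmark:
  per-(batch, type) OLS with temperature-specific slopes and exact t
  prediction intervals, and a maximum-likelihood mixed-effects model
  (time × temperature fixed effects, container, random intercept + slope per
  batch) with plug-in normal intervals.
* **`vaxstab.evaluation`** — empirical coverage and per-type MSE metrics,
  time-split validation, the scenario-grid simulation study (coverage at the
  95 % nominal level on 5 °C hold-out data), interval-width/data-requirement
  curves, and prior-sensitivity scans.
* **`vaxstab.cli`** — a `vaxstab` command with `simulate`, `fit`, `predict`,
  `shelflife`, `timesplit`, `benchmark` and `sensitivity` subcommands.

> **Model note.** The layer equations implemented here are one concrete
> choice among the hierarchies matching this design (hierarchically centred
> normal layers, temperature-indexed slope families, shared residual
> variance, non-informative priors); defaults for the synthetic generator
> are package choices, not measured values, and every one is overridable
> via configuration.

## CLI

Every subcommand takes `--seed`, `--config` (YAML/JSON), `--out` (output
directory) and `--log-level`, and writes a `manifest.json` next to its
outputs recording the command, resolved configuration, seed, package version
and timestamps. Logs go to stderr; results only to files.

```sh
# 2160-row default training cohort
vaxstab simulate --seed 1 --out runs/sim

# fit the hierarchical model, persist draws + posterior summary
vaxstab fit --data runs/sim/stability.csv --seed 1 --out runs/fit

# intervals at target coordinates (batch_id "new-batch" = fresh batch)
vaxstab predict --draws runs/fit --targets targets.csv --out runs/pred

# shelf life against a specification limit
vaxstab shelflife --draws runs/fit --spec-limit 80 --out runs/shelf

# 0-6 month train / >6 month test validation with all three models
vaxstab timesplit --data runs/sim/stability.csv --out runs/ts

# simulation benchmark (scenario grid from the config file)
vaxstab benchmark --config bench.yaml --seed 1 --out runs/bench
```

Example config (`bench.yaml`):

```yaml
scenarios:
  - {setting: full, n_batches_train: 5, train_window_months: 6, n_replicates: 20}
generator:
  residual_sd: 4.0
mcmc:
  n_iterations: 1500
  burn_in: 500
  n_chains: 1
```

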