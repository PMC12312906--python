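# locolearn

Dual-context state-space analysis of locomotor skill learning on a virtual
obstacle-negotiation task. The package provides:

- **core_model** — the trial-by-trial forward model of foot clearance:
  dead-zone error against a per-height success range, an
  interference-weighted state update `x' = x + B·e·c`, and the motor
  output. Two readings of the output equation are available: the literal
  inner product (`DOT`) and per-context selection (`SELECT`).
- **synthetic_cohort** — generators for complete synthetic study datasets
  (two groups, baseline / acquisition / no-feedback / retention phases,
  192 acquisition obstacles in six 32-obstacle bouts) with ground-truth
  parameter tables for recovery testing.
- **inference** — hierarchical Bayesian estimation (three levels:
  Student-t observation noise, sigmoid-Normal participant effects,
  group-level location/scale hyper-parameters with a shared Student-t
  degrees of freedom) by adaptive Metropolis-within-Gibbs MCMC, with
  split and rank-normalized R-hat diagnostics and WAIC model comparison
  (FULL vs B-only vs shared-B variants).
- **bayes_tests** — probability of direction on sigmoid-transformed group
  differences (trim-then-count recipe, conventional untrimmed variant via
  a flag) and ROPE testing on standardized effect sizes.
- **metrics** — behavioral performance error, online improvement,
  overnight retention, model-based end-of-practice error, and OLS
  association regressions with group interactions.
- **io_cli** — validated CSV trial tables, netCDF/CSV posterior
  persistence, and a CLI chaining the stages into a reproducible
  pipeline.

Baseline foot-clearance levels are not available from the source study;
the generator defaults (LOW 0.15 ± 0.04 m, HIGH 0.10 ± 0.04 m above the
obstacle top) are documented stand-ins.

## CLI

```bash
# generate a synthetic cohort
locolearn cohort --seed 1 --out-dir runs/demo

# fit the hierarchical model (reduced MCMC shown; defaults are
# 3 chains x 20,000 iterations, 10,000 burn-in, thinning 10)
locolearn fit --data runs/demo/trials.csv --model full --output-variant select \
    --chains 3 --iter 4000 --burnin 2000 --thin 4 --seed 1 \
    --out runs/demo/posterior.nc

# convergence diagnostics, hypothesis tests, model comparison, metrics
locolearn diagnose runs/demo/posterior.nc
locolearn test --posterior runs/demo/posterior.nc --param B --rope -0.1 0.1
locolearn compare --data runs/demo/trials.csv --fit full=runs/demo/posterior.nc
locolearn metrics --data runs/demo/trials.csv --posterior runs/demo/posterior.nc \
    --out-summaries runs/demo/summaries.csv

# or the whole pipeline in one reproducible run
locolearn run --seed 1 --out-dir runs/full
```

Forward simulation of a single participant:

```bash
locolearn simulate --params params.json --schedule schedule.csv --seed 1 --out trials.csv
```

where `params.json` holds `B`, `q`, `x1_low`, `x1_high` (optionally
`tau`, `k`, `nu`, `noise`, `variant`) and `schedule.csv` has a
`height_class` column of `LOW`/`HIGH` values.

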