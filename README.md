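# jointbhm

Joint Bayesian hierarchical modelling of mixed continuous/binary
repeated-measures outcomes, with three self-contained MCMC samplers and a
predictive model-comparison stack.

The model couples a normal sub-model for a continuous severity score with a
latent-probit sub-model (unit residual variance) for a binary health status,
measured repeatedly within patients. Patient-level random effects for the
two responses share one joint covariance matrix, which carries the
cross-response correlation. Everything runs on synthetic data emulating a
balanced 16-patient × 2-leg × 2-side × 4-occasion design (256 rows).

## Components

| module                  | contents |
|-------------------------|----------|
| `jointbhm.synthetic`    | balanced design generator, seeded simulator (latent-probit), predictor z-scoring |
| `jointbhm.model`        | `ModelSpec` (null / random-intercept / full structures), likelihoods, priors, unnormalized posterior, analytic gradients on an unconstrained scale (log σ², log-Cholesky Σᵤ), adaptive Gauss–Hermite marginal likelihood |
| `jointbhm.priors`       | normal/flat β; inverse-gamma, half-t, half-Cauchy, truncated-normal σ priors; inverse-Wishart and LKJ+scales Σᵤ priors; presets `mlwin_like`, `mcmcglmm_like`, `brms_like` |
| `jointbhm.samplers`     | blockwise random-walk Metropolis(-Hastings), Gibbs with latent-normal probit augmentation, fixed-trajectory HMC with leapfrog, dual-averaging step size and diagonal mass adaptation |
| `jointbhm.diagnostics`  | rank-normalized split R̂, Bulk/Tail-ESS (Geyer truncation), summary tables with threshold flags |
| `jointbhm.criteria`     | conditional pointwise log-likelihood, WAIC, PSIS-LOO (own generalized-Pareto fit), DIC, ICOMP (C1 complexity), patient-stratified K-fold CV |
| `jointbhm.checks`       | prior/posterior predictive checks, HPD intervals, prior-sensitivity harness |
| `jointbhm.cli` / `io`   | `jointbhm` command-line pipeline, long-format CSV I/O, YAML configs, run manifests |

All samplers are single-threaded and bit-reproducible given a seed.

## CLI

```bash
# simulate the default 256-row design
jointbhm simulate --seed 1 --out data.csv

# fit the full model with HMC (config optional; see below)
jointbhm fit data.csv --sampler hmc --out fit_full --seed 1

# compare stored fits (rows = models; DIC, ICOMP, WAIC, LOO_IC, K-fold)
jointbhm compare fit_null fit_full data.csv --out table.csv

# other stages
jointbhm kfold data.csv --k 10 --out kfold.json
jointbhm ppc fit_full data.csv --out ppc.csv
jointbhm prior-ppc data.csv --out prior_ppc.csv
jointbhm sensitivity data.csv --out sens.csv
```

A config file is a single YAML/JSON mapping with sections
`{data, model, priors, sampler, run}`, e.g.

```yaml
model:
  structure: full          # null | random_intercept | full
  prior: brms_like         # or a detailed prior mapping
run:
  n_chains: 4
  n_iterations: 3000       # total per chain, burn-in included
  burn_in: 1000
  thinning: 1
  seed: 1
```

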