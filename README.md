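# speedirt

Joint two-dimensional item response modelling for *speeded* tests — tests
whose time limit keeps most respondents from reaching the last items, so
observed scores mix ability with working speed.

Two Rasch-type channels share a correlated bivariate latent trait per person:

- a **completion factor** (θ₀), measured through attempt indicators derived
  from the not-reached-item pattern, with item difficulties constrained to be
  affine in item position (β₀ₖ = τ₀ + (k − K)·τ₁), and
- a **mathematics/ability trait** (θ₁), measured through correctness of the
  recorded answers with free item difficulties.

Latent means are fixed at 0 for identification; optional person covariates
(gender dummy, condition dummy, their interaction — Models 1–4) shift the
latent means through regression coefficients, so group gaps can be compared
on the latent scale against observed-score gaps (Cohen's d).

## Layout

| module | contents |
|---|---|
| `speedirt.data_io` | CSV reading, missingness-indicator coding (attempted / first-not-reached / structurally missing, skips scored as attempted), covariate dummies, descriptives (sum scores, Cohen's d, Cronbach's α, per-item curves) |
| `speedirt.model_core` | item response function, constrained completion difficulties, both channel log-likelihoods, latent regression means, full prior density |
| `speedirt.sampler` | multi-chain Metropolis-within-Gibbs (conjugate Wishart update for the latent covariance, conjugate normal update for coefficients, adaptive random walks elsewhere), escalating burn-in on non-convergence, strict seed contract |
| `speedirt.diagnostics` | classic Gelman–Rubin R̂, initial-positive-sequence ESS, MCSE, shortest-interval HPDI, latent correlation, three-rule convergence verdict (R̂ > 1.05, MCSE > 0.05, ESS < 400), trace/density plots |
| `speedirt.synthetic_data` | generative counterpart: sequential stopping process + correctness + optional skips, scenario presets, parameter-recovery and power experiments |
| `speedirt.pipeline` / `speedirt.cli` | manifest-driven end-to-end runs and the `speedirt` command line |

## CLI

```bash
# synthetic cohort (defaults: N=794, K=25, 78% women)
speedirt simulate --out runs/sim --seed 1

# derive completion indicators
speedirt code --responses runs/sim/sim_responses.csv --out runs/sim/indicators.csv

# observed-score descriptives
speedirt descriptives --responses runs/sim/sim_responses.csv \
    --covariates runs/sim/sim_covariates.csv --out runs/desc

# fit one model (1=no covariates, 2=gender, 3=condition, 4=full)
speedirt fit --model 2 --responses runs/sim/sim_responses.csv \
    --covariates runs/sim/sim_covariates.csv --seed 1 --out runs/fit2

# full pipeline from a manifest (see RunManifest fields)
speedirt report --manifest manifest.yaml

# parameter recovery experiment
speedirt recover --replicates 5 --model 1 --seed 1 --out runs/recovery
```

`fit` accepts a YAML config with `mcmc:` (iteration scheme; defaults are
3 chains × 25,000 adaptation + 25,000 burn-in, 60,000 retained draws total),
`prior:` (all hyperprior switches) and `rules:` (verdict thresholds).
Response files are delimited text with a header of item ids in
administration order and cells in {0, 1, missing-token}; the missing token
defaults to `NA` and is never inferred.

## Python API sketch

```python
from speedirt import (SimulationScenario, generate_dataset, code_missingness,
                      MCMCConfig, fit_model)

data = generate_dataset(SimulationScenario(N=794, K=25, seed=1))
ind = code_missingness(data.responses)
cfg = MCMCConfig(n_chains=3, n_adapt=2000, n_burnin=2000, n_posterior_total=6000, seed=1)
report = fit_model(data.responses, ind, data.covariates, model_id=1, cfg=cfg)
print(report.verdict, report.latent_corr["mean"])
print(report.table.loc["cov_completion_ability"])
```

Throughout the package the latent vector is ordered
`(completion θ0, ability θ1)`; coefficient pairs are `(ability, completion)`
to match the conventional subscripts 1 and 2.
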