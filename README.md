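# rangesqueeze

Bayesian hierarchical analysis of vascular-plant **elevation range sizes**
versus **temperature variability** across and within mountain gradients.

Two classic predictions collide here. Stevens' hypothesis says climatically
variable places select for broad thermal tolerances, hence *larger* ranges.
The *temperature range squeeze* says the opposite: under a thermal
tolerance window `[t_lower, t_upper]` and lapse rate `L` (°C / 100 m), a
temperature oscillation of amplitude ΔT leaves a suitable elevation span of
only

    span = max(0, t_upper − t_lower − ΔT) / L × 100   [m]

so more variability means *smaller* ranges. `rangesqueeze` provides the
full machinery to test these predictions on species elevation-range tables:

* **Preprocessing** — range-size computation, QC filters (inverted or
  impossible elevations, > 25 % singletons, sampling gaps > 500 m),
  gradient standardization to a common length with range truncation,
  edge exclusion zones, and the ln-transform with the 10 m singleton floor.
* **Climate covariates** — 100 m elevation-band climate summaries (zonal
  means of DTR, TS, MAT, AP), per-mountain means over standardized
  domains, millennial temperature variability ΔMAT₀₋₁₉₈₀ (max − min of a
  30-year-mean series, 0–1980 AD), and species-midpoint climate assignment.
* **Models** — a global hierarchical model (species log ranges around
  mountain means that respond linearly to a mountain-level covariate, with
  interaction and island/continental variants) and a local model
  (mountain-specific slopes on midpoint covariates, shared residual
  variance), both with BUGS-convention flat priors, sampled by a blocked
  conjugate Gibbs sampler (3 chains × 50,000 iterations, 20,000 burn-in by
  default, extended until ESS ≥ 3000).
* **Evaluation** — WAIC and PSIS-LOO model comparison, P(β < 0), 95 %
  credible intervals, site-level Bayesian R², split-chain R̂, ESS,
  posterior predictive checks, and per-mountain slope classification.
* **Synthetic worlds** — a generator with the exact generative structure
  the models assume (island mountains with lower diurnal temperature
  range, tunable singleton fraction, paleo series), so the whole pipeline
  is testable end-to-end with no downloads.

See `docs/methods.md` for the model definitions, priors, design choices
and limitations.

## Worked example

Simulate a 14-mountain world whose ranges are driven by diurnal
temperature range (slope −0.15 per °C), run the full global analysis, and
compare which covariate best predicts mean range size:

```python
from rangesqueeze import (
    MCMCConfig, RunConfig, SyntheticWorldConfig, TrueParameters,
    run_global_analysis,
)

cfg = RunConfig(
    world=SyntheticWorldConfig(
        n_mountains=14, span_range=(2600, 5500),
        n_species_per_mountain=50, singleton_fraction=0.1, seed=17,
    ),
    true_params=TrueParameters(
        alpha_V=8.0, beta_V=-0.15, sigma2_site=0.02, sigma2_RS=0.36,
    ),
    mcmc=MCMCConfig(n_chains=3, n_iter=12_000, burn_in=3_000, seed=5),
)
bundle = run_global_analysis(cfg)
print(bundle["comparison"].table[["model", "waic", "p_waic", "elpd_loo"]])
s = bundle["slopes"]["dtr"]
print(f"DTR slope {s.mean:.3f} (95% CI {s.ci_lower:.3f}..{s.ci_upper:.3f}), "
      f"P(beta<0) = {s.prob_negative:.3f}, R2 = {s.r2:.2f}")
```

Output:

```
  model         waic     p_waic    elpd_loo
0   dtr  1572.940343   8.577489 -786.510209
1  dmat  1577.241622  12.315552 -788.656990
2    ts  1577.338948  12.579074 -788.706302
DTR slope -0.129 (95% CI -0.206..-0.053), P(beta<0) = 0.998, R2 = 0.76
```

The planted driver (DTR) attains the lowest WAIC and highest LOO elpd;
its slope posterior covers the generating value −0.15 with essentially
all mass below zero — the squeeze signature. The same bundle
carries per-mountain posterior mean ranges with SDs (`site_table`),
R̂/ESS diagnostics, and attrition logs showing which mountains the
standardization dropped.

The local (within-mountain) analysis and the 3 × 3 × 2 standardization
sensitivity grid run the same way via `run_local_analysis` and
`run_sensitivity_grid`, or from the shell:

```bash
rangesqueeze simulate --seed 4 --out-dir world/
rangesqueeze fit-global --covariate dtr --covariate ts --seed 4
rangesqueeze fit-local --seed 4
rangesqueeze sensitivity --covariate dtr --seed 4
```

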