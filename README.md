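# mvjoint

Bayesian joint modelling of **multivariate longitudinal** and **survival**
data with skew-normal errors.

Cohort studies of childhood growth and disease — for example prospective
type-1-diabetes cohorts that measure height and weight repeatedly while
following children for diagnosis — produce two linked kinds of data:
correlated repeated measures that are often skewed, and a censored
time-to-event outcome whose risk depends on the growth trajectories
themselves.  Modelling the pieces separately biases both; `mvjoint` fits
them jointly.

## Model

For K outcomes (k = 1..K), subject i, visit j at age t_ij:

    y_ijk = x_ij' β_k + z_ij' b_ik + ε_ijk                (growth curves)
    ε_ij | w_ij ~ N( Δ (w_ij − √(2/π) 1), Σ_K ),  w_ij ~ N(0,1) I(w>0)
    b_i ~ N(0, Σ_b)
    λ(t | b_i, x_i) = λ₀(t) exp( Υ' b_i + α' x_i )        (hazard)

The errors are Sahu-type skew normal: a shared half-normal latent w_ij per
visit times per-outcome skewness coefficients Δ = diag(δ₁,…,δ_K), centred
so E[ε] = 0; δ = 0 recovers the ordinary multivariate-normal joint model
("Model N" vs "Model SN").  The association vector Υ on the random
intercepts/slopes links growth to risk.  The baseline hazard uses the
counting-process approximation (gamma-distributed masses on the observed
event times), making every survival update conjugate or a cheap
Metropolis step.  Inference is a Gibbs/M-H sampler with multi-chain
Gelman–Rubin diagnostics and conditional DIC for variant comparison.

## Worked example

```python
from mvjoint import (MCMCConfig, recovery_design, simulate_dataset,
                     run_mcmc, summarize, gelman_rubin, hazard_ratios)

# correctly specified skew-normal design: 200 children, 10 visits,
# skewness (-1.5, -0.8), hazard loadings (-0.2, 1.0, 0.4, 0.3)
design = recovery_design(n_subjects=200, n_visits=10)
long_ds, surv_ds, truth = simulate_dataset(design, seed=42)

cfg = MCMCConfig(n_chains=3, n_iterations=4000, burn_in=1000, thin=5, seed=1)
draws = run_mcmc(long_ds, surv_ds, config=cfg, model_variant="sn")

summ = summarize(draws)
print(summ.loc[["beta01", "beta11", "delta1", "delta2"]].round(3))
print("R-hat delta1:", round(gelman_rubin(draws, "delta1").R, 3))
```

Output from this exact run:

```
               PM     SD  ci_low  ci_high
parameter
beta01     59.127  0.185  58.755   59.492
beta11     10.639  0.241  10.162   11.096
delta1     -1.619  0.132  -1.849   -1.344
delta2     -1.117  0.127  -1.336   -0.827
R-hat delta1: 1.012
```

The posterior means recover the true values (β₀₁ = 59, β₁₁ = 11,
δ = (−1.5, −0.8)) to within a couple of posterior SDs, and the
Gelman–Rubin ratio near 1 indicates the three chains have mixed.
`hazard_ratios(summ, ["upsilon2"])` turns the height-slope association
into a hazard ratio with its 95% credible interval.

The same pipeline is available from the shell:

```bash
mvjoint simulate --design recovery --n-subjects 200 --seed 42 --out data/
mvjoint fit --long data/dataset_long.csv --surv data/dataset_surv.csv \
            --model sn --seed 1 --out fit/
mvjoint diagnose --draws fit/draws.csv --out diag/
mvjoint simstudy --n-datasets 10 --models sn,n --seed 7 --out study/
```

`mvjoint simstudy` runs the bias/MSE study: simulate gamma-error (skewed,
misspecified) datasets, fit both variants, and tabulate percent bias and
percent MSE per parameter.  The desk-scale default (10 datasets of 150
subjects) finishes in minutes; `--paper-scale` switches to the full-size
study (50 datasets of 500 subjects, three chains of 30,000 iterations),
which runs for hours.

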