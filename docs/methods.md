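# Methods

## Model

`mvjoint` fits a multivariate joint (MVJ) model linking K longitudinal
outcomes to a time-to-event process through shared random effects.

**Longitudinal sub-model.** For subject i, outcome k and visit j at age
t_ij,

    y_ijk = x_ij' beta_k + z_ij' b_ik + eps_ijk,

with fixed-effect rows x_ij (by default `(1, Age, Age^2, Gender)`) and
random-effect rows z_ij (`(1, Age)`), so each subject carries a random
intercept and slope per outcome.  The stacked random-effect vector
b_i = (b_i01, b_i11, ..., b_i0K, b_i1K)' is N(0, Sigma_b).  Errors follow a
Sahu-type skew normal: with a standard half-normal latent w_ij *shared
across outcomes at each visit*,

    eps_ij | w_ij ~ N( delta * (w_ij - sqrt(2/pi)), Sigma_K ),

where delta = (delta_1, ..., delta_K) are skewness coefficients and Sigma_K
is the within-visit error covariance.  The -sqrt(2/pi)*delta shift makes
the marginal error mean exactly zero, so beta keeps its usual
interpretation; delta_k = 0 for all k recovers the multivariate-normal
mixed model ("Model N").  The shared latent means the skew components of
the K outcomes at one visit are comonotone; the Gaussian part carries
arbitrary cross-outcome correlation through Sigma_K.

**Survival sub-model.** The hazard for subject i is

    lambda(t | b_i, x_i) = lambda_0(t) exp( upsilon' b_i + alpha' x_i ),

with baseline covariates x_i (three country indicators against a reference
country, gender, HLA risk genotype, first-degree-relative status) and
association loadings upsilon on the random effects — the linkage that makes
inference joint.  The baseline hazard is handled by the counting-process
(Clayton) approximation: nonnegative masses dLambda_g on the grid of
observed event times, each subject contributing independent Poisson terms
dN_i(g) with intensity 1{T_i >= g} exp(eta_i) dLambda_g.  Ties share a grid
point (Breslow convention).

**Priors.** Independent normals for beta, gamma = (upsilon, alpha) and
delta with mean 0 and variance 100 (a stated precision of 0.01 is read in
the BUGS convention; a variance-convention switch exists in
`PriorSpec.default`), inverse-Wishart IW(0.01 I, dim) for Sigma_K and
Sigma_b, and Gamma(0.01, 0.01) for each baseline-hazard increment.  These
are weakly informative at the scales of the growth application.

## Sampler

A Gibbs sweep with Metropolis-Hastings steps, one iteration being

1. w: truncated-normal full conditionals (positive support), sampled by
   inverse CDF;
2. delta: normal full conditional (the mean is linear in delta given w);
3. beta: conjugate normal (GLS-type) full conditional;
4. b: per-subject independence M-H.  The proposal is the exact normal
   conditional implied by the longitudinal likelihood and the N(0, Sigma_b)
   prior, *tilted* by the survival score: the proposal mean adds
   s_i(b) P_i^{-1} upsilon with s_i(b) = rho_i - exp(eta_i) Lambda_0(T_i),
   i.e. a per-subject Laplace-style linearisation of the survival factor.
   The M-H correction accounts for the state-dependent tilt, so the
   invariant law is exact; with upsilon = 0 the tilt vanishes and the step
   is an exact Gibbs draw (acceptance 1).  The untilted proposal, while
   valid, mixes very poorly along the b-gamma ridge: the survival
   information lags one step behind and the chain makes long excursions
   into inflated-|upsilon| regions.  We verified against an independent
   BUGS-family implementation (JAGS) of the identical model that those
   regions do carry posterior mass at small n; the tilt shortens the
   excursions without changing the target.
5. Sigma_K, Sigma_b: conjugate inverse-Wishart draws (non-PD numerical
   draws are retried with jitter and logged);
6. hazard increments: conjugate gamma draws
   Gamma(0.01 + d_g, 0.01 + sum_{at risk} exp(eta_i));
7. gamma: component-wise Gaussian random-walk M-H on the counting-process
   likelihood times the prior, with Robbins-Monro scale adaptation toward
   0.30 acceptance during burn-in only (scales frozen afterwards, so the
   post-burn-in chain is a fixed Markov kernel).

Chains draw from independent substreams of the master seed
(`default_rng([seed, chain])`); identical configuration and seed reproduce
retained draws bit for bit.  The normal variant pins delta = 0 and skips
steps 1-2 entirely.  Update order is configurable and immaterial to the
stationary law.

Initialisation (`overdispersed`, the default) starts each chain from a
per-outcome OLS fit with chain-dependent offsets of +/-2 (and +/-4) in
natural units on beta, +/-1 on delta, +/-0.5 on gamma, and covariance
scale factors {0.5, 1, 2}.  Offsets are expressed in natural rather than
prior units because the weakly informative priors (SD 10) would start the
random-walk gamma block tens of SDs from the posterior, where it stalls.
`prior` and `fixed` strategies are also available.

## Diagnostics, DIC and summaries

Posterior summaries are the pooled post-burn-in mean, SD and (2.5%, 97.5%)
quantiles.  Convergence uses the original Gelman-Rubin variance ratio: for
C chains of length m, W = mean within-chain variance, B = m * variance of
chain means, V = ((m-1)/m) W + B/m, R = V/W; the dynamic (prefix-indexed)
sequences behind the three-curve diagnostic plot are available from
`gelman_rubin(..., sequences=True)`.

DIC uses the deviance *conditional* on the latent layers,
D = -2 [log f(Y | beta, b, w, delta, Sigma_K) + log f(N | b, gamma,
dLambda)], the focus a BUGS-style sampler induces.  The per-draw deviance
is accumulated during sampling; D(theta-bar) is evaluated at componentwise
posterior means, including the stored means of b, w and the hazard
increments, with elementwise-averaged covariance matrices PD-projected by
eigenvalue flooring when numerically indefinite.  pD = Dbar - D(theta-bar),
DIC = Dbar + pD.  Which deviance a DIC should integrate is genuinely open;
the conditional joint deviance is the default and the only one shipped.

Hazard ratios are exp-transformed posterior means with exp-transformed
equal-tail CI bounds, rounded to two decimals in reports.  The
Kaplan-Meier display wraps the lifelines product-limit estimator.

## Synthetic-data generator

The generator emulates a prospective birth-cohort growth study: scheduled
visits every 3 months to age 4 and every 6 months to age 12 (32 visits);
two growth outcomes with quadratic age trends; gender Bernoulli(0.5),
country uniform over four levels (expanded to three indicators), HLA and
FDR Bernoulli(0.5); random effects N(0, I_4); event times exponential with
subject-specific rate lambda_0 exp(upsilon'b + alpha'x) (constant baseline
lambda_0 = 0.1); exponential censoring; and longitudinal records truncated
at the observed time.  Default true values: beta_height = (59, 11, -0.3,
0.1), beta_weight = (6, 2, -0.5, -0.5), upsilon = (-0.2, 1, 0.4, 0.3),
alpha = (0.7, 0.8, -0.3, -0.4, 0.3, 0.4).

Error models: gamma errors (height Gamma(1, 0.5), weight Gamma(2, 0.8),
shape-rate convention with a shape-scale switch) — deliberately
misspecified, positive-mean and right-skewed, the stress design whose
signature is upward intercept bias; centred skew-normal errors (the
correctly specified design used for recovery checks, default skew
(-1.5, -0.8)); and plain normal errors.  Gamma errors are *not*
mean-centred: the intercept shift is an intended feature of the stress
design.  Censoring defaults to rate 0.1 (mean 10 years); the literal
mean-0.1 reading, which censors essentially everyone before the first
visit, is available as `censoring_literal_mean=True` for completeness.

What the generator does not emulate: real visit compliance and missingness,
measurement rounding, cohort heterogeneity beyond the listed covariates,
or dependence between censoring and the outcome.  Passing recovery tests
therefore demonstrates internal consistency of model + sampler under the
stated generating mechanisms, not robustness to the full messiness of
cohort data.

## Simulation-study harness and problem sizes

`run_sim_study` simulates replicates, fits the requested variants, and
tabulates percent bias (100 (EST - TP)/|TP|) and percent MSE
(100 MSE/|TP|), the latter non-negative by construction.  Replicate seeds
are `seed + 1 + r`, and finished replicates are checkpointed to JSON so a
partial run resumes.

Two scales are built in.  The desk scale — 10 replicates, 150 subjects, 10
visits, 3 chains x 4,000 iterations (burn-in 1,000, thin 5) — is the
package default; a full study completes in minutes on one CPU and is what
the test suite and the acceptance script exercise.  The full scale — 50
replicates, 500 subjects, 32 visits, 3 chains x 30,000 (burn-in 10,000,
thin 20; 1,000 retained per chain) — is available via
`paper_scale_design()` / `paper_scale_config()` and the CLI flag
`--paper-scale`; it runs for hours and is intended for manual studies.

At desk scale the qualitative conclusions are stable (positive intercept
bias under gamma errors in both variants; the skew-normal variant's DIC
below the normal variant's in nearly all replicates; positive skewness
estimates on right-skewed errors), while the numerical bias magnitudes
differ from a full-size study — smaller n and fewer visits inflate both
bias and MSE, particularly for the hazard loadings.

## Numerical choices and known limitations

- Truncated-normal sampling uses the inverse-CDF method with the uniform
  clipped to [1e-300, 1 - 1e-16]; far-tail conditionals lose some relative
  precision but remain in (0, inf).
- The hazard-loading posterior is genuinely diffuse and heavy-tailed when
  events are few relative to the number of hazard parameters: the latent
  b can quasi-separate events from censored subjects, and late grid points
  with near-empty risk sets give the corresponding increments a heavy
  right tail.  This is a property of the model/prior, reproduced
  independently by JAGS on the same data, not a sampler artefact; expect
  wide upsilon intervals below a few hundred events.
- Fitting requires visit times aligned across outcomes within subject
  (the shared per-visit latent is otherwise undefined); the data container
  accepts unaligned series for storage and description.
- Subjects with follow-up shorter than the first scheduled visit carry no
  longitudinal rows; their random effects are informed by the prior and
  the survival factor only.
- Outcomes are not standardised internally; `standardize_outcomes` offers
  optional z-scoring because raw- versus standardised-scale modelling is
  application-dependent.
- No support for interval censoring, time-varying survival covariates,
  competing risks, or missing-data mechanisms.
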