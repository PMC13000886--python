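# basketbhm

Covariate-adjusted Bayesian hierarchical analysis of randomized controlled
**basket trials** — master-protocol trials that test one therapy across
several disease subtypes ("subtrials") sharing a molecular target.

Subtrials are individually small, so estimating a subtrial-specific
treatment effect θ_k from one subtrial alone is noisy.  Two remedies are
combined here:

1. **Borrowing information across subtrials.**  The effects are modelled
   as exchangeable, θ_k | μ_θ, σ_θ ~ N(μ_θ, σ_θ²), with μ_θ ~ N(0, 100)
   and a half-t prior σ_θ ~ HT(σ_HT, d).  The posterior shrinks each θ_k
   toward the population mean, with strength governed by the heterogeneity
   scale σ_θ (larger σ_HT ⇒ less borrowing).
2. **Covariate adjustment (ANCOVA) inside the data model.**  With a
   continuous outcome Y_ik, treatment indicator T_ik and cluster-centered
   baseline covariates X_ik, three data models are supported:

   | label   | mean model                                             |
   |---------|--------------------------------------------------------|
   | BHM     | α_k + θ_k T_ik                                         |
   | adjBHM  | α_k + θ_k T_ik + β_k X_ik                              |
   | intBHM  | α_k + θ_k T_ik + β_k X_ik + γ_k T_ik X_ik              |

   all with shared outcome variance σ_y² ~ InvGamma(2, 20) and N(0, 100)
   priors on α_k, β_k, γ_k.  The posterior is sampled by a blocked Gibbs
   sampler (the half-t prior is handled by its inverse-gamma scale
   mixture, keeping every update conjugate); a Bernoulli/logistic variant
   uses Metropolis-within-Gibbs.

The package also implements the frequentist comparators (stratified
AN(C)OVA per subtrial, linear mixed models with random intercept and
random treatment slope), synthetic basket-trial generators, and the full
simulation-study machinery: bias / SD / RMSE / RMSE reduction / rejection
rate, family-wise error and disjunctive power, each with its Monte Carlo
standard error, over paired replicates so that between-method comparisons
account for the shared simulated data.

## Worked example

```python
from basketbhm import (
    ScenarioConfig, generate_scenario, center_covariates,
    BhmSpec, McmcConfig, fit_bhm, summarize_posterior, decide_rejection,
)

# a basket trial with 4 subtrials (sizes 80:120:160:200), effects (0,0,1,1),
# one predictive covariate: Y = 1 + theta_k T - 2X + 4TX + noise
cfg = ScenarioConfig("S1", total_n=560, allocation_fraction=0.75, seed=1)
data = center_covariates(generate_scenario(cfg))

draws = fit_bhm(data, BhmSpec(data_model="ANCOVA2"), McmcConfig(seed=3))
est = summarize_posterior(draws)
for k in range(est.K):
    print(f"subtrial {k+1}: {est.estimate[k]:+.3f} "
          f"[{est.lower[k]:+.3f}, {est.upper[k]:+.3f}] "
          f"reject H0: {decide_rejection(est)[k]}")
```

prints

```
subtrial 1: +0.305 [-0.211, +0.821] reject H0: False
subtrial 2: -0.076 [-0.524, +0.372] reject H0: False
subtrial 3: +1.162 [+0.777, +1.547] reject H0: True
subtrial 4: +0.984 [+0.647, +1.320] reject H0: True
```

Posterior means with 95% credible intervals symmetric about the mean for
this single simulated trial; the true effects are (0, 0, 1, 1), so both
null subtrials are retained and both effective subtrials detected here.
The simulation machinery quantifies how often that happens.  A simulation
cell over many such replicates:

```python
from basketbhm import McmcConfig, run_cell

reports = run_cell("S1", 560, 0.75, ["BHM", "intBHM"], B=100,
                   base_seed=0, mcmc=McmcConfig(), reference_method="BHM")
print(reports["intBHM"].format_table())
```

reports, per subtrial, the bias/SD/RMSE of the posterior-mean estimator,
its percent RMSE reduction relative to the unadjusted model, and the
rejection rate of the interval test — each with its Monte Carlo standard
error in parentheses.

A command-line interface mirrors the library:

```bash
basketbhm simulate --scenario S1 --total-n 560 --seed 1 --out trial.csv
basketbhm fit --data trial.csv --method intBHM --seed 3
basketbhm study --scenario S2 --total-n 112 --method sANOVA -B 50 --out-dir out/
basketbhm case-study --config majic.yml
```

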