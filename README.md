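# copulameta

Bayesian bivariate random-effects meta-analysis of two correlated binomial
outcomes — a surrogate endpoint and a final outcome observed in the same
two-arm randomized trials — with three choices of within-study likelihood:

* **BRMA** — the standard normal approximation on the log odds-ratio scale
  with known within-study variances and correlation ρ_w;
* **BRMA-IB** — exact, independent binomial likelihoods per arm and outcome
  (logit link), avoiding the normal approximation but ignoring within-study
  association;
* **BRMA-BC** — a joint per-arm likelihood: a bivariate pmf with binomial
  margins coupled by a Gaussian copula with per-arm dependence parameters
  ρ_A, ρ_B, accounting for within-study association on the original
  binomial scale.

All three share the between-study model

```
(δ₁ᵢ, δ₂ᵢ)ᵀ ~ N( (d₁, d₂)ᵀ, [[τ₁², τ₁τ₂ρ_b], [τ₁τ₂ρ_b, τ₂²]] )
d₁,₂ ~ N(0, 10²)   τ₁,₂ ~ U(0, 5)   ρ_b = tanh(z), z ~ N(0, 1)
```

where ρ_b — the between-studies correlation of the true treatment effects —
is the quantity used to validate study-level surrogacy.  The copula CDF is
evaluated in closed form via Owen's T-function; the discrete joint pmf is
the four-corner rectangle difference of the copula at neighbouring binomial
CDF values.  The package also ships the bootstrap estimators of
within-study association from binary IPD (Pearson correlation of bootstrap
log ORs; two-stage copula MLE per arm), a double-bootstrap prior builder
from cohort summaries, the bottom-up IPD scenario simulator, and a
replication harness reporting bias / coverage / RMSE.  Posterior
computation uses a built-in slice-sampling-within-Gibbs engine (validated
against JAGS in the test suite), with rank-normalised split R-hat and ESS
diagnostics via arviz.

Audience: biostatisticians evaluating surrogate endpoints from aggregate
trial data, and methodologists studying how within-study association and
extreme event proportions distort between-study correlation estimates.

## Worked example

The packaged dataset contains 10 randomized trials in chronic myeloid
leukemia: complete cytogenetic response (CCyR) at 12 months as candidate
surrogate, and the number of patients event-free at 24 months as final
outcome.

```python
from copulameta import load_cml, fit_brma_ib, McmcConfig

fit = fit_brma_ib(load_cml(), cfg=McmcConfig(chains=4, warmup_iters=1000,
                                             sampling_iters=2000, seed=1))
print(fit.table.loc[["d1", "d2", "tau1", "tau2", "rho_b"]].round(3))
```

prints

```
        mean  median   q2.5  q97.5   rhat       ess
d1     0.469   0.470  0.087  0.874  1.012   401.231
d2     0.164   0.160 -0.239  0.583  1.002   831.700
tau1   0.464   0.432  0.151  0.963  1.001   563.312
tau2   0.365   0.321  0.016  1.009  1.002   731.329
rho_b  0.230   0.334 -0.874  0.963  1.005  1365.225
```

d₁ and d₂ are the pooled log odds ratios on the surrogate and final
outcome (both favour the newer regimens), τ₁ and τ₂ the between-study SDs,
and ρ_b the surrogacy correlation.  Its 95% credible interval spans nearly
all of (−1, 1): these ten trials cannot establish CCyR at 12 months as a
study-level surrogate for 24-month event-free survival — largely because
treatment effects on the final outcome are weak and imprecise.

The `examples/` directory walks through each capability: the case study
above, the copula model with a double-bootstrap dependence prior, the
bootstrap association estimators on simulated IPD, and a miniature
simulation study comparing all three models.  A `copulameta` command-line
tool exposes the same pipeline (`fit`, `bootstrap`, `prior`, `simulate`,
`evaluate` subcommands).

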