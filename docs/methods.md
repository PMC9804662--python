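# Methods

`copulameta` performs Bayesian bivariate random-effects meta-analysis of two
correlated binomial outcomes — typically a surrogate endpoint (outcome 1)
and a final clinical outcome (outcome 2) observed in the control arm A and
treatment arm B of each randomized study.  The scientific target is the
between-studies correlation ρ_b of the true treatment effects, the quantity
used to judge study-level surrogacy, together with the pooled effects
(d₁, d₂) and heterogeneity SDs (τ₁, τ₂).

## The three models

All three models share the between-study layer

    (δ₁ᵢ, δ₂ᵢ)ᵀ ~ N( (d₁, d₂)ᵀ, [[τ₁², τ₁τ₂ρ_b], [τ₁τ₂ρ_b, τ₂²]] )

with priors d₁,₂ ~ N(0, 10²), τ₁,₂ ~ U(0, 5), ρ_b = tanh(z), z ~ N(0, 1),
and per-study baselines μ₁ᵢ, μ₂ᵢ ~ N(0, 10²) where they appear.  They
differ in the within-study layer:

* **BRMA** — the classical normal approximation.  Counts are transformed to
  log odds ratios Y₁ᵢ, Y₂ᵢ with variances σ²₁ᵢ, σ²₂ᵢ from the reciprocal
  2×2 cells; (Y₁ᵢ, Y₂ᵢ) is bivariate normal around (δ₁ᵢ, δ₂ᵢ) with known
  within-study correlation ρ_wᵢ.  When a cell of an outcome's 2×2 table is
  zero (or a count equals its denominator) 0.5 is added to all four cells
  of that outcome's table (Haldane–Anscombe); an always-add switch exists
  for sensitivity runs.
* **BRMA-IB** — exact, independent binomial likelihoods
  r_jᵢ ~ Bin(N, logit⁻¹(·)) per arm and outcome.  No continuity correction
  is needed and no normality is assumed, but the within-study association
  between the two outcomes (measured on the same patients) is ignored.
* **BRMA-BC** — the within-study layer models each arm's two counts
  *jointly*: a bivariate pmf with binomial margins coupled by a Gaussian
  copula with per-arm dependence parameters ρ_Aᵢ, ρ_Bᵢ.  The joint pmf is
  the four-corner rectangle difference of the copula CDF at neighbouring
  binomial-CDF values (the discrete-margin Sklar construction).

## Copula numerics

The Gaussian copula CDF is evaluated in closed form through Owen's
T-function,

    C(u₁,u₂;ρ) = (u₁+u₂)/2 − T(x₁, a₁) − T(x₂, a₂) − δ(u₁,u₂),

with x_j = Φ⁻¹(u_j), a₁ = (x₂/x₁ − ρ)/√(1−ρ²) (a₂ symmetrically) and
δ = ½ exactly when one argument lies below ½ and the other at or above ½
(the "at or above" convention resolves the tie at exactly ½).  Owen's T
itself is delegated to the vetted scipy routine; the assembly above is this
package's and is cross-checked in the tests against scipy's independent
bivariate-normal quadrature (agreement ≤ 1e−6; in practice ~1e−14).
Numerical choices:

* CDF endpoints are handled analytically: binomial F(−1) ≡ 0 and F(n) ≡ 1,
  and copula arguments of 0 and 1 short-circuit so Φ⁻¹ is never evaluated
  at an endpoint.  Arguments of exactly ½ (x = 0) use the closed forms
  C(½,½;ρ) = ¼ + arcsin(ρ)/2π and C(½,v;ρ) = v/2 − T(Φ⁻¹(v), −ρ/√(1−ρ²)).
* The public CDF clamps results into the Fréchet–Hoeffding bounds
  max(0, u₁+u₂−1) ≤ C ≤ min(u₁,u₂) (removing ~1e−15 floating noise); the
  likelihood hot path uses a lean formula-only variant (endpoint clipping
  at 1e−15, verified to agree with the careful path to ~1e−14).
* The rectangle rule can go negative by cancellation; the pmf is clamped at
  a floor of 1e−12 so log-likelihoods stay finite.  Normalisation tests run
  pre-clamp.  |ρ| is capped at 1 − 1e−6 inside likelihoods so the Owen's-T
  slopes stay finite.
* Correlated Bernoulli sampling dichotomises a latent standard bivariate
  normal at the upper tail: outcome j is 1 when Z_j > Φ⁻¹(1−p_j).

A point worth stating explicitly: the law of a *sum* of n copula-correlated
Bernoulli pairs is **not** the copula-coupled bivariate binomial with the
same dependence parameter (the two coincide only at n = 1; at n = 2 the
maximum pmf difference is already ~0.01).  This is why aggregate-level
dependence parameters are re-estimated from bootstrap count pairs rather
than carried over from the individual level, and the tests assert exactly
this distinction.

## Posterior computation

No probabilistic-programming backend is assumed: the engine is a
package-authored univariate slice sampler (stepping-out + shrinkage)
composed into a Gibbs sweep — the sampler family JAGS uses for
non-conjugate nodes.  Slice sampling needs no step-size tuning and has no
Metropolis rejection pathologies, which matters for these heavy-tailed,
weakly identified posteriors (10 studies, a correlation parameter whose
credible interval spans most of (−1, 1)).  Two structural choices make it
fast and reliable:

* **BRMA is marginalised.**  The within-study layer is linear-Gaussian, so
  the per-study latents integrate out exactly: Y_i ~ N(d, S_i + T).  Only
  the five between-study parameters are sampled; study-specific effects are
  recovered afterwards by the exact conjugate conditional
  δ_i | y_i, θ ~ N(d + T C⁻¹(y_i − d), T − T C⁻¹ T), C = S_i + T.  This is
  a Rao–Blackwellisation, not an approximation.
* **The binomial models use non-centred latents with batched updates.**
  δ_i = d + L u_i with u_i ~ N(0, I₂) and L the Cholesky factor of the
  between-study covariance.  Given the global parameters, the per-study
  blocks (μ₁ᵢ, μ₂ᵢ, u₁ᵢ, u₂ᵢ) are conditionally independent across
  studies, so one vectorised likelihood call drives thirty simultaneous
  slice updates.  The binomial CDFs in the copula likelihood are evaluated
  through the regularised incomplete beta function with the corner
  parameters precomputed per dataset.

Chains are independent replicates from dispersed starts; summaries report
rank-normalised split R-hat and bulk ESS (via arviz) for every parameter,
with a convergence warning attached above the 1.01 threshold.  Defaults
mirror common practice for these models: 4 chains, 1000 warm-up + 2000
retained sweeps each.  The engine is validated in the test suite against an
independent JAGS fit of the same likelihood and priors on the packaged CML
data (all five between-study parameters agree within MC error) and against
closed-form conjugate posteriors.

The copula model's posterior is sensitive to initialisation, so
`init_bc_from_ib` starts every chain from the independent-binomial
posterior means (latents included) with per-chain jitter; fitting BRMA-IB
first and handing its solution to BRMA-BC is the recommended and default
pipeline route.

Dependence inputs to BRMA-BC come in three modes: per-study plug-ins
(bootstrap estimates), one shared value, or empirical prior draws.  In the
prior mode the draws are summarised as a normal prior on the Fisher-z scale
(mean and SD of atanh of the draws) on a single shared parameter per arm —
smooth, sampler-friendly, and respecting the (−1, 1) support after tanh;
the same mechanism serves BRMA when only prior draws of ρ_w exist.

## Within-study association estimation

With binary IPD available, two bootstrap estimators populate the models
(3000 resamples by default, patients resampled with replacement within each
arm — implemented as multinomial resampling of the arm's 2×2 cells):

* ρ_w: both outcomes' log ORs are computed on every resample (continuity
  correction applied per resample when a cell is zero) and ρ_w is the
  Pearson correlation of the pairs.
* ρ_A, ρ_B: each arm's resampled count pairs (r₁*, r₂*) feed a two-stage
  (inference-functions-for-margins) MLE — binomial margins first
  (p̂_j = Σr_j / nK), then the copula dependence parameter by bounded
  one-dimensional likelihood maximisation on (−1+1e−6, 1−1e−6) with
  multi-start at {−0.5, 0, 0.5}; convergence is the optimiser's success
  status with a finite objective.  Degenerate inputs (an outcome constant
  in the IPD, or a margin with p̂ of 0 or 1) raise; the default degenerate
  policy redraws the bootstrap, with redraw counts recorded.

When no IPD exist anywhere, `double_bootstrap_prior` converts a published
cohort summary (n, surrogate response rate, final-outcome rate conditional
on response status) into an empirical prior: the 2×2 pseudo-IPD table is
reconstructed with largest-remainder rounding, an outer bootstrap resamples
it (default 1000 outer draws), and the inner estimator (ρ_arm, or the
correlation of the two outcomes' bootstrap log odds for the ρ_w analogue)
is applied to each outer draw.  The outer/inner sizes are this package's
choices; no canonical values exist.  Real cohort rates for the CML example
are not published in usable form, so the examples use a synthetic cohort,
which is labelled as such.

## The simulation harness

`simulate_study` builds each study bottom-up: arm sizes ~ N(m, 5) rounded
(independently per arm, minimum 2); baseline logits (μ₁ᵢ, μ₂ᵢ) bivariate
normal with means (η₁, η₂), SDs 0.1 and correlation 0.8; effects from the
between-study law at the default truth d₁=0.4, d₂=0.2, τ₁=τ₂=0.5, ρ_b=0.8;
event probabilities by inverse logit; and per-arm correlated binary IPD
from the Gaussian-copula Bernoulli construction with the same latent
dependence in both arms.  η = 0 gives an average event proportion of 0.5,
η = 3 gives 0.95.  The scenario grid crosses proportions {0.5, 0.95} ×
mean arm sizes {400, 150} × dependence {low, moderate, high} — 12 named
scenarios.

The latent dependence values behind low/moderate/high are this package's
calibration (the aggregate-level anchors are what matters): a one-time
pilot search chose latent ρ ∈ {0.22, 0.585, 0.895} so that the median
bootstrap ρ_w at proportion 0.5 / arm size 400 lands at the anchors
0.14 / 0.40 / 0.71 (the calibrated run reproduces 0.14–0.15 / 0.40 / 0.71,
with the per-arm copula dependence medians essentially coinciding).  The
closed-form seed for that search: for Bernoulli(½) margins the phi
coefficient is (2/π)·arcsin(ρ), so ρ ≈ sin(πφ/2) at the target φ.

Two resimulation policies mirror the degenerate cases a bootstrap cannot
handle.  Each study is redrawn until every arm × outcome series contains
both a 0 and a 1 (binding essentially only at proportion 0.95 with small
arms; at balanced proportions the tests confirm the effect law is
untouched).  And a study whose dependence optimiser fails to converge is
resimulated from its own child random stream — per-study `SeedSequence`
spawning means resimulating one study never perturbs the others — with
counts recorded.

What the generator does *not* emulate: real trials' unequal randomisation,
outcome-specific denominators (supported by the data reader and the log-OR
and independent-binomial models, but not generated), non-copula dependence
structures, and time-to-event censoring.  Passing recovery tests therefore
show correctness of the machinery under the stated generative law, not
robustness to these real-data features.

## Evaluation

`run_replications` simulates R replications of a scenario, estimates the
associations each requested model needs, fits the models (the copula model
initialised from an independent-binomial pre-fit at half budget), and
records posterior summaries beside the generating truth; failures are
collected and the harness aborts if any model fails on more than 5% of
replications.  `performance` reports, per estimand and model, the bias of
the posterior medians, the coverage of the equal-tailed 95% credible
intervals, and the RMSE of the medians — each with a Monte-Carlo standard
error so reduced-replication runs read honestly.  Replications with R-hat
above threshold are retained but flagged; a switch excludes them.

Problem sizes in the shipped tests and acceptance script are desk-scale by
design: 30–50 replications per scenario (with MC standard errors reported),
2-chain fits at reduced sweep counts for the replication studies, and the
full 4-chain budget for the single CML case-study fit.  The harness itself
runs any replication count; the scaled settings are the package's choice of
a defensible desk-scale experiment, with the directional findings tested as
sign tests rather than magnitudes.

## Data-format decisions

Some trials report the two outcomes on different denominators (in the CML
table, e.g. a response outcome on the randomised cohort and event-free
survival on a molecular subset).  The log-OR and independent-binomial
models honour each outcome's own denominator.  The copula model's joint
per-arm likelihood requires a single denominator per arm; such studies are
reduced to the smaller per-arm denominator with the other outcome's count
rescaled proportionally (rounded), preserving the observed event rate — a
warning is emitted per study, and a strict mode errors instead.  Capping
counts at the smaller denominator (the obvious alternative) saturates
several real studies at r = n, which forces the corresponding event
probability to 1 and destroys identification of that study's treatment
effect; proportional rescaling avoids this while using the same evidence.

## Known limitations

* The copula model is ~5–10× slower per sweep than the independent-binomial
  model and needs the BRMA-IB initialisation to mix well from cold starts.
* Aggregate-level dependence plug-ins are treated as known in the per-study
  mode; their bootstrap uncertainty is propagated only through the shared
  Fisher-z prior mode.
* Only the bivariate case, the Gaussian copula and binomial margins are
  implemented; between-study copulas, vine extensions and count margins are
  out of scope.
* The between-study prior z ~ N(0, 1) shrinks extreme correlations toward
  0; with few studies the posterior median of ρ_b sits noticeably below a
  generating value of 0.8 under all models (visible in the recovery tests
  as averages near 0.75–0.8).
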