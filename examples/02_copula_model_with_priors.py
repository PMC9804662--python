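"""Fit the copula model with an informative dependence prior built from a
cohort summary by double bootstrap.

No IPD exist for the CML trials, so the within-study dependence parameters
of the copula model cannot be estimated directly.  A (synthetic, for
illustration) observational cohort reporting the surrogate response rate
and the final-outcome rate conditional on response stands in: pseudo-IPD
are reconstructed from its 2x2 table and a double bootstrap turns them into
an empirical prior for the per-arm dependence.
"""

import warnings

import numpy as np

from copulameta import (McmcConfig, CohortSummary, WithinDependence,
                        fit_brma_bc, fit_brma_ib, init_bc_from_ib, load_cml)
from copulameta.association import BootstrapConfig, double_bootstrap_prior

# synthetic cohort: 300 patients, 65% achieve the surrogate response;
# event-free rates 88% for responders vs 55% for non-responders
cohort = CohortSummary(n=300, p_surrogate=0.65,
                       p_final_given_resp=0.88, p_final_given_nonresp=0.55)
draws = double_bootstrap_prior(cohort, outer_reps=120,
                               cfg=BootstrapConfig(n_boot=500, seed=7),
                               target="rho_arm")
print(f"dependence prior from cohort: median {np.median(draws):.3f}, "
      f"95% interval ({np.quantile(draws, .025):.3f}, "
      f"{np.quantile(draws, .975):.3f})")

data = load_cml()
dep = WithinDependence("prior_samples", rho_A=draws, rho_B=draws)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    ib = fit_brma_ib(data, cfg=McmcConfig(chains=2, warmup_iters=300,
                                          sampling_iters=600, seed=2))
    inits = init_bc_from_ib(ib, dep, chains=2, seed=2)
    bc = fit_brma_bc(data, dep, cfg=McmcConfig(chains=2, warmup_iters=300,
                                               sampling_iters=600, seed=3),
                     inits=inits)

print("\nindependent-binomial vs copula model (posterior medians):")
for p in ("d1", "d2", "tau1", "tau2", "rho_b"):
    print(f"  {p:6s}  ib {ib.median(p):6.3f}   bc {bc.median(p):6.3f}")
print(f"  posterior median of the arm-A dependence: {bc.median('rho_A'):.3f}")
print(
    "\nThe copula model spends part of the observed co-movement of the two\n"
    "outcomes on within-study association, so its rho_b differs from the\n"
    "independent-binomial fit, which attributes everything to the\n"
    "between-study level."
)
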