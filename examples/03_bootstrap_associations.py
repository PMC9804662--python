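"""Estimate within-study association from binary IPD by bootstrap.

Simulates one study's IPD with known latent dependence, then estimates the
two association quantities the models consume: the correlation rho_w of the
bootstrap log ORs (for the log-OR-scale model) and the per-arm copula
dependence rho_A, rho_B by two-stage maximum likelihood on bootstrap count
pairs (for the copula model).
"""

import numpy as np

from copulameta import BinaryIpdStudy, sample_bernoulli_pair
from copulameta.association import (BootstrapConfig, bootstrap_rho_arm,
                                    bootstrap_rho_w)

rng = np.random.default_rng(42)
n = 400
latent = 0.585  # calibrated "moderate": bootstrap rho_w lands near 0.40
xA = sample_bernoulli_pair(0.5, 0.55, latent, n, rng)
xB = sample_bernoulli_pair(0.6, 0.6, latent, n, rng)
ipd = BinaryIpdStudy("sim", np.repeat(["A", "B"], n),
                     np.concatenate([xA[:, 0], xB[:, 0]]),
                     np.concatenate([xA[:, 1], xB[:, 1]]))

cfg = BootstrapConfig(n_boot=3000, seed=1)
rw = bootstrap_rho_w(ipd, cfg)
fA, _ = bootstrap_rho_arm(xA[:, 0], xA[:, 1], cfg)
fB, _ = bootstrap_rho_arm(xB[:, 0], xB[:, 1], cfg)

print(f"latent (IPD-level) dependence used to simulate: {latent}")
print(f"bootstrap rho_w  (log-OR correlation):    {rw.estimate:.3f}")
print(f"two-stage rho_A  (converged={fA.converged}):       {fA.rho:.3f}")
print(f"two-stage rho_B  (converged={fB.converged}):       {fB.rho:.3f}")
print(
    "\nThe aggregate-level estimates sit near 0.4, well below the latent\n"
    "0.585: dependence does not transfer unchanged from the individual to\n"
    "the aggregate level, which is exactly why these estimators exist."
)
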