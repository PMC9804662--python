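"""A miniature simulation study comparing the three models.

Generates replications of the base scenario (30 studies, mean arm size 400,
balanced proportions, moderate within-study dependence; truth d1=0.4,
d2=0.2, tau1=tau2=0.5, rho_b=0.8), fits all three models to each
replication and reports bias / coverage / RMSE of the rho_b estimates.
Five replications keep the runtime to a few minutes; the harness scales to
any count.
"""

from copulameta import McmcConfig
from copulameta.association import BootstrapConfig
from copulameta.evaluate import performance, run_replications
from copulameta.simulate import ScenarioConfig

cfg = ScenarioConfig(name="p05_n400_moderate")
results = run_replications(
    cfg, models=("brma", "brma-ib", "brma-bc"), R=5, seed=11,
    mcmc=McmcConfig(chains=2, warmup_iters=150, sampling_iters=300),
    boot=BootstrapConfig(n_boot=1000))

print(f"{len(results)} fits ({len(results) // 3} replications x 3 models), "
      f"truth rho_b = {cfg.rho_b_true}\n")
for row in performance(results, "rho_b"):
    print(f"  {row.model:8s} bias {row.bias:+.3f} (mcse {row.bias_mcse:.3f})  "
          f"coverage {row.coverage:.2f}  rmse {row.rmse:.3f}")
print(
    "\nAll three centre near the truth here; at five replications the MC\n"
    "standard errors dominate fine distinctions.  The systematic effects —\n"
    "the upward pull on rho_b of ignoring within-study association\n"
    "(brma-ib), strongest for small studies and high dependence — emerge\n"
    "at larger replication counts (see the acceptance tests)."
)
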