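"""The three meta-analytic models: transformation, likelihoods, fits."""

import subprocess
import warnings

import numpy as np
import pytest
from scipy.stats import kstest

from copulameta import (LogORStudy, McmcConfig, Priors, StudyCounts,
                        WithinDependence, fit_brma, fit_brma_bc, fit_brma_ib,
                        init_bc_from_ib, log_or_transform, sample_prior)
from copulameta.models import _BcTarget, _BrmaTarget, _IbTarget

QUICK = McmcConfig(chains=2, warmup_iters=200, sampling_iters=400, seed=7)


class TestLogOrTransform:
    def test_printed_counts_example(self, cml):
        # first CML row: CCyR 171/252 control vs 175/250 treatment
        s = log_or_transform(cml[0])
        want_y = np.log(175 / 75) - np.log(171 / 81)
        want_v = 1 / 175 + 1 / 75 + 1 / 171 + 1 / 81
        assert s.y1 == pytest.approx(want_y, abs=1e-10)
        assert s.y1 == pytest.approx(0.1001, abs=5e-4)
        assert s.v1 == pytest.approx(want_v, abs=1e-10)
        assert s.v1 == pytest.approx(0.0372, abs=5e-4)

    def test_identical_arms_give_null_effect(self):
        c = StudyCounts("x", 100, 100, 50, 50, 50, 50)
        s = log_or_transform(c)
        assert s.y1 == 0.0 and s.y2 == 0.0

    def test_zero_cell_corrected_to_finite(self):
        c = StudyCounts("x", 40, 40, 10, 12, 0, 11)
        s = log_or_transform(c)
        assert np.isfinite(s.y1) and np.isfinite(s.v1)
        # all four cells of outcome 1 shifted by 0.5
        want = np.log(0.5 / 40.5) - np.log(10.5 / 30.5)
        assert s.y1 == pytest.approx(want, abs=1e-12)
        # outcome 2 untouched
        assert s.y2 == pytest.approx(np.log(11 / 29) - np.log(12 / 28), abs=1e-12)

    def test_outcome_specific_denominators_used(self):
        c = StudyCounts("x", 60, 70, 42, 50, 59, 55, n2_A=80, n2_B=90)
        s = log_or_transform(c)
        assert s.y2 == pytest.approx(np.log(55 / 35) - np.log(50 / 30), abs=1e-12)


class TestBrma:
    def test_requires_three_studies_and_rho_w(self):
        d = [LogORStudy("a", 0.1, 0.2, 0.05, 0.05, 0.3)] * 2
        with pytest.raises(ValueError, match="3 studies"):
            fit_brma(d, cfg=QUICK)
        d = [LogORStudy(str(i), 0.1, 0.2, 0.05, 0.05) for i in range(4)]
        with pytest.raises(ValueError, match="rho_w"):
            fit_brma(d, cfg=QUICK)

    def test_fixed_effect_limit_concentrates_at_common_effect(self):
        d = [LogORStudy(str(i), 0.5, 0.25, 0.004, 0.004, 0.4) for i in range(8)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = fit_brma(d, cfg=QUICK)
        assert s.median("d1") == pytest.approx(0.5, abs=0.06)
        assert s.median("d2") == pytest.approx(0.25, abs=0.06)
        assert s.median("tau1") < 0.25

    def test_recovers_generating_between_study_parameters(self, rng):
        truth = dict(d1=0.4, d2=0.2, t1=0.5, t2=0.5, rb=0.8)
        L = np.array([[truth["t1"], 0],
                      [truth["t2"] * truth["rb"],
                       truth["t2"] * np.sqrt(1 - truth["rb"] ** 2)]])
        data = []
        v = 0.01
        for i in range(40):
            delta = np.array([truth["d1"], truth["d2"]]) + L @ rng.standard_normal(2)
            y = delta + np.sqrt(v) * rng.standard_normal(2)
            data.append(LogORStudy(str(i), y[0], y[1], v, v, 0.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = fit_brma(data, cfg=McmcConfig(chains=2, warmup_iters=300,
                                              sampling_iters=800, seed=13))
        for name, want in [("d1", 0.4), ("d2", 0.2), ("tau1", 0.5),
                           ("tau2", 0.5), ("rho_b", 0.8)]:
            sd = (s.table.loc[name, "q97.5"] - s.table.loc[name, "q2.5"]) / 3.92
            assert abs(s.median(name) - want) < 3 * sd + 0.02, name

    def test_latent_effects_shrink_towards_pooled_mean(self):
        d = [LogORStudy(str(i), y, y / 2, 0.04, 0.04, 0.3)
             for i, y in enumerate([-0.2, 0.1, 0.4, 0.7, 1.0])]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = fit_brma(d, cfg=QUICK)
        # the most extreme study's latent mean lies between its observation
        # and the pooled mean
        assert s.mean("d1") < s.mean("delta1[4]") < 1.0


class TestBrmaIb:
    def test_null_data_centres_effects_at_zero(self, rng):
        n = 400
        data = [StudyCounts(str(i), n, n,
                            int(rng.binomial(n, 0.5)), int(rng.binomial(n, 0.5)),
                            int(rng.binomial(n, 0.5)), int(rng.binomial(n, 0.5)))
                for i in range(6)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = fit_brma_ib(data, cfg=QUICK)
        assert abs(s.median("d1")) < 0.2
        assert abs(s.median("d2")) < 0.2

    def test_matches_independent_jags_oracle(self, cml):
        """Cross-check the full CML fit against JAGS (same likelihood,
        priors and data; an entirely independent sampler)."""
        rscript = r"""
library(rjags)
d <- read.csv(commandArgs(trailingOnly=TRUE)[1])
model <- "
model {
  for (i in 1:S) {
    r1A[i] ~ dbin(p1A[i], n1A[i]); r2A[i] ~ dbin(p2A[i], n2A[i])
    r1B[i] ~ dbin(p1B[i], n1B[i]); r2B[i] ~ dbin(p2B[i], n2B[i])
    logit(p1A[i]) <- mu1[i]; logit(p2A[i]) <- mu2[i]
    logit(p1B[i]) <- mu1[i] + delta[i,1]; logit(p2B[i]) <- mu2[i] + delta[i,2]
    mu1[i] ~ dnorm(0, 0.01); mu2[i] ~ dnorm(0, 0.01)
    delta[i,1:2] ~ dmnorm(dvec[1:2], Om[1:2,1:2])
  }
  dvec[1] ~ dnorm(0, 0.01); dvec[2] ~ dnorm(0, 0.01)
  tau1 ~ dunif(0, 5); tau2 ~ dunif(0, 5)
  z ~ dnorm(0, 1); rho_b <- tanh(z)
  Sig[1,1] <- tau1^2; Sig[2,2] <- tau2^2
  Sig[1,2] <- tau1*tau2*rho_b; Sig[2,1] <- Sig[1,2]
  Om[1:2,1:2] <- inverse(Sig[1:2,1:2])
}
"
data <- list(S=nrow(d), n1A=d$n_A, r1A=d$r1_A, n1B=d$n_B, r1B=d$r1_B,
             n2A=d$n2_A, r2A=d$r2_A, n2B=d$n2_B, r2B=d$r2_B)
set.seed(1)
jm <- jags.model(textConnection(model), data=data, n.chains=3, n.adapt=1000,
                 quiet=TRUE)
update(jm, 3000)
s <- coda.samples(jm, c("dvec","tau1","tau2","rho_b"), n.iter=8000, thin=2)
m <- as.matrix(s)
cat(apply(m, 2, median), "\n")
cat(colMeans(m), "\n")
"""
        import tempfile, os
        from copulameta.io import write_counts
        with tempfile.TemporaryDirectory() as td:
            write_counts(cml, os.path.join(td, "cml.csv"))
            rf = os.path.join(td, "fit.R")
            with open(rf, "w") as f:
                f.write(rscript)
            out = subprocess.run(["Rscript", rf, os.path.join(td, "cml.csv")],
                                 capture_output=True, text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        lines = [l for l in out.stdout.strip().splitlines() if l.strip()]
        j_med = dict(zip(["d1", "d2", "rho_b", "tau1", "tau2"],
                         map(float, lines[-2].split())))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = fit_brma_ib(cml, cfg=McmcConfig(chains=2, warmup_iters=500,
                                                sampling_iters=1200, seed=3))
        for p, tol in [("d1", 0.06), ("d2", 0.06), ("tau1", 0.08),
                       ("tau2", 0.08), ("rho_b", 0.15)]:
            assert s.median(p) == pytest.approx(j_med[p], abs=tol), p


class TestBrmaBc:
    def test_zero_dependence_likelihood_equals_independent_binomials(self, small_counts):
        ib = _IbTarget(small_counts, Priors())
        bc = _BcTarget(small_counts, WithinDependence("shared_fixed", [0.0], [0.0]),
                       Priors())
        rng = np.random.default_rng(3)
        for _ in range(5):
            g = np.array([rng.normal(0.4, 0.1), rng.normal(0.2, 0.1),
                          rng.uniform(0.1, 1), rng.uniform(0.1, 1),
                          rng.normal(0, 0.5)])
            # latents kept in the data-supported region: the equivalence is
            # exact there, while deep in the tails the pmf floor (applied
            # only on the joint-likelihood side) takes over
            mu1 = np.log(ib.r1A / (ib.n1A - ib.r1A))
            mu2 = np.log(ib.r2A / (ib.n2A - ib.r2A))
            loc = np.stack([mu1 + rng.normal(0, 0.05, ib.n_studies),
                            mu2 + rng.normal(0, 0.05, ib.n_studies),
                            rng.normal(0, 0.1, ib.n_studies),
                            rng.normal(0, 0.1, ib.n_studies)])
            np.testing.assert_allclose(ib.study_loglik(g, loc),
                                       bc.study_loglik(g, loc), atol=1e-8)

    def test_study_order_invariance_of_likelihood(self, small_counts):
        dep = WithinDependence("per_study_fixed",
                               rho_A=np.linspace(0.1, 0.5, 5),
                               rho_B=np.linspace(0.2, 0.4, 5))
        bc = _BcTarget(small_counts, dep, Priors())
        perm = np.array([3, 1, 4, 0, 2])
        dep_p = WithinDependence("per_study_fixed", rho_A=dep.rho_A[perm],
                                 rho_B=dep.rho_B[perm])
        bc_p = _BcTarget([small_counts[i] for i in perm], dep_p, Priors())
        g = np.array([0.2, 0.1, 0.4, 0.3, 0.1])
        loc = np.random.default_rng(0).normal(0, 0.3, (4, 5))
        np.testing.assert_allclose(bc_p.study_loglik(g, loc[:, perm]),
                                   bc.study_loglik(g, loc)[perm], atol=1e-12)

    def test_dependence_validation(self, small_counts):
        with pytest.raises(ValueError):
            WithinDependence("per_study_fixed", rho_A=[1.0] * 5, rho_B=[0.2] * 5)
        with pytest.raises(ValueError):
            WithinDependence("prior_samples", rho_A=[0.1] * 5, rho_B=[0.2] * 5)
        dep = WithinDependence("per_study_fixed", rho_A=[0.1] * 3, rho_B=[0.2] * 3)
        with pytest.raises(ValueError, match="per study"):
            fit_brma_bc(small_counts, dep, cfg=QUICK)

    def test_prior_samples_mode_reports_dependence_posterior(self, small_counts):
        rng = np.random.default_rng(5)
        dep = WithinDependence("prior_samples",
                               rho_A=np.tanh(rng.normal(0.35, 0.08, 300)),
                               rho_B=np.tanh(rng.normal(0.3, 0.08, 300)))
        cfg = McmcConfig(chains=2, warmup_iters=100, sampling_iters=200, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = fit_brma_bc(small_counts, dep, cfg=cfg)
        # dependence stays near its informative prior (counts are weakly
        # informative about it)
        assert s.median("rho_A") == pytest.approx(np.tanh(0.35), abs=0.15)
        assert "rho_B" in s.table.index

    def test_strict_mode_rejects_unequal_denominators(self, cml):
        dep = WithinDependence("shared_fixed", [0.3], [0.3])
        with pytest.raises(ValueError, match="strict"):
            fit_brma_bc(cml, dep, cfg=QUICK, strict_denominators=True)


class TestInitFromIb:
    def test_identity_before_jitter_and_zero_jitter(self, small_counts):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ib = fit_brma_ib(small_counts,
                             cfg=McmcConfig(chains=2, warmup_iters=100,
                                            sampling_iters=200, seed=1))
        inits = init_bc_from_ib(ib, chains=3, jitter=0.0)
        g0, loc0 = inits[0]
        assert g0[0] == pytest.approx(ib.mean("d1"), abs=1e-12)
        assert g0[4] == pytest.approx(np.mean(ib.draws["z"]), abs=1e-12)
        assert loc0[0, 2] == pytest.approx(ib.mean("mu1[2]"), abs=1e-12)
        for g, loc in inits[1:]:
            np.testing.assert_array_equal(g, g0)
            np.testing.assert_array_equal(loc, loc0)
        jit = init_bc_from_ib(ib, chains=2, jitter=0.05, seed=4)
        assert not np.array_equal(jit[0][0], jit[1][0])


def test_prior_predictive_rho_b_matches_tanh_normal():
    """With no data the posterior of rho_b must reproduce its prior,
    tanh(z) with z standard normal (KS test on thinned draws)."""
    s = sample_prior(cfg=McmcConfig(chains=2, warmup_iters=200,
                                    sampling_iters=2000, seed=21))
    z = np.arctanh(s.draws["rho_b"].reshape(-1))[::5]
    assert len(z) >= 790
    assert kstest(z, "norm").pvalue > 0.01
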