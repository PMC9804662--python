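"""The three Bayesian bivariate meta-analysis models.

All three share the between-study layer

    (delta_1i, delta_2i) ~ N((d1, d2), [[tau1^2, tau1*tau2*rho_b],
                                        [tau1*tau2*rho_b, tau2^2]])

with priors d_j ~ N(0, 10^2), tau_j ~ U(0, 5) and rho_b = tanh(z),
z ~ N(0, 1), and differ only in the within-study likelihood:

* ``fit_brma`` — normal approximation on the log-odds-ratio scale with the
  within-study covariance (variances and correlation ``rho_w``) treated as
  known.  The per-study latent effects are integrated out analytically
  (marginally ``Y_i ~ N(d, S_i + T)``), so only the five between-study
  parameters are sampled; latents are recovered afterwards by exact
  conjugate conditional draws.
* ``fit_brma_ib`` — exact, independent binomial likelihoods per arm and
  outcome with a logit link and per-study baselines ``mu_ji ~ N(0, 10^2)``.
  No within-study association.
* ``fit_brma_bc`` — per-arm *joint* likelihood for the two event counts: a
  bivariate pmf with binomial margins glued by a normal copula with per-arm
  dependence parameters ``rho_Ai``, ``rho_Bi`` (known plug-ins, a shared
  value, or an informative Fisher-z prior matched to bootstrap draws).

The binomial-likelihood models keep the per-study latent treatment effects
in non-centred form, ``delta_i = d + L u_i`` with ``u_i ~ N(0, I)`` and
``L`` the Cholesky factor of the between-study covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import betainc, expit, gammaln

from .copula import RHO_EPS, PMF_FLOOR, _copula_cdf_formula
from .data import LogORStudy, StudyCounts, WithinDependence
from .sampler import (HierarchicalTarget, McmcConfig, PosteriorSummary,
                      run_mcmc, summarize_posterior)

__all__ = ["Priors", "log_or_transform", "fit_brma", "fit_brma_ib",
           "fit_brma_bc", "init_bc_from_ib", "sample_prior",
           "summarize_posterior"]


@dataclass(frozen=True)
class Priors:
    """Between-study prior settings (defaults are the vague priors used
    throughout: ``d, mu ~ N(0, 10^2)``, ``tau ~ U(0, 5)``, ``z ~ N(0, 1)``)."""

    d_sd: float = 10.0
    mu_sd: float = 10.0
    tau_upper: float = 5.0
    z_sd: float = 1.0


def _fisher_z_prior(draws: np.ndarray) -> tuple[float, float]:
    """Normal prior on the Fisher-z scale matched to empirical draws of a
    correlation: mean and SD of atanh(draws)."""
    z = np.arctanh(np.clip(np.asarray(draws, dtype=float), -1 + RHO_EPS, 1 - RHO_EPS))
    return float(z.mean()), float(max(z.std(ddof=1), 1e-3))


# ---------------------------------------------------------------------------
# log-OR transformation

def log_or_transform(counts: StudyCounts, correction: float = 0.5,
                     always_correct: bool = False) -> LogORStudy:
    """Transform arm-level counts to log odds ratios with variances.

    For each outcome the 2x2 table is (events, non-events) x (arm B, arm A)
    on that outcome's own denominators.  When a cell of an outcome's table
    is zero (or the count equals its denominator), ``correction`` is added
    to all four cells of that outcome's table (Haldane-Anscombe); set
    ``always_correct`` to apply it unconditionally.  ``rho_w`` is left unset.
    """
    out = []
    for (rB, nB, rA, nA) in [(counts.r1_B, counts.n_B, counts.r1_A, counts.n_A),
                             (counts.r2_B, counts.n2_B, counts.r2_A, counts.n2_A)]:
        cells = np.array([rB, nB - rB, rA, nA - rA], dtype=float)
        if always_correct or np.any(cells == 0):
            cells = cells + correction
        y = np.log(cells[0] / cells[1]) - np.log(cells[2] / cells[3])
        v = np.sum(1.0 / cells)
        out.append((float(y), float(v)))
    (y1, v1), (y2, v2) = out
    return LogORStudy(study_id=counts.study_id, y1=y1, y2=y2, v1=v1, v2=v2)


# ---------------------------------------------------------------------------
# BRMA: marginalised normal-normal model on the log-OR scale

class _BrmaTarget(HierarchicalTarget):
    local_names: list[str] = []

    def __init__(self, data: list[LogORStudy], priors: Priors,
                 rho_w_prior: tuple[float, float] | None = None):
        self.y1 = np.array([s.y1 for s in data])
        self.y2 = np.array([s.y2 for s in data])
        self.v1 = np.array([s.v1 for s in data])
        self.v2 = np.array([s.v2 for s in data])
        self.rho_w_prior = rho_w_prior
        if rho_w_prior is None:
            rw = np.array([0.0 if s.rho_w is None else s.rho_w for s in data])
            self.s12 = rw * np.sqrt(self.v1 * self.v2)
        self.pr = priors
        self.n_studies = len(data)
        self.global_names = ["d1", "d2", "tau1", "tau2", "z"]
        if rho_w_prior is not None:
            self.global_names = self.global_names + ["z_w"]
        self.global_widths = np.array([0.3, 0.3, 0.3, 0.3, 0.5] +
                                      ([0.3] if rho_w_prior is not None else []))

    def log_prior_global(self, g):
        d1, d2, t1, t2, z = g[:5]
        if not (0.0 < t1 < self.pr.tau_upper and 0.0 < t2 < self.pr.tau_upper):
            return -np.inf
        lp = -0.5 * (d1 * d1 + d2 * d2) / self.pr.d_sd ** 2 \
            - 0.5 * (z / self.pr.z_sd) ** 2
        if self.rho_w_prior is not None:
            m, s = self.rho_w_prior
            lp += -0.5 * ((g[5] - m) / s) ** 2
        return lp

    def study_loglik(self, g, loc, idx=None):
        d1, d2, t1, t2, z = g[:5]
        rb = np.tanh(z)
        sl = slice(None) if idx is None else idx
        v1, v2 = self.v1[sl], self.v2[sl]
        if self.rho_w_prior is not None:
            rw = np.tanh(g[5])
            s12 = rw * np.sqrt(v1 * v2)
        else:
            s12 = self.s12[sl]
        c11 = v1 + t1 * t1
        c22 = v2 + t2 * t2
        c12 = s12 + t1 * t2 * rb
        det = c11 * c22 - c12 * c12
        e1 = self.y1[sl] - d1
        e2 = self.y2[sl] - d2
        quad = (c22 * e1 * e1 - 2.0 * c12 * e1 * e2 + c11 * e2 * e2) / det
        return -np.log(2.0 * np.pi) - 0.5 * np.log(det) - 0.5 * quad

    def initial(self, rng):
        g = np.array([rng.normal(0, 0.3), rng.normal(0, 0.3),
                      rng.uniform(0.1, 1.0), rng.uniform(0.1, 1.0),
                      rng.normal(0, 0.5)])
        if self.rho_w_prior is not None:
            m, s = self.rho_w_prior
            g = np.append(g, rng.normal(m, max(s, 0.05)))
        return g, np.zeros((0, self.n_studies))


def _brma_latent_draws(target: _BrmaTarget, g_draws: np.ndarray,
                       seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact conjugate draws of the per-study true effects given the
    between-study draws: delta_i | y_i, theta ~ N(d + T C^-1 (y - d),
    T - T C^-1 T) with C = S_i + T."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5EED)))
    C, D, _ = g_draws.shape
    S = target.n_studies
    d1, d2 = g_draws[..., 0], g_draws[..., 1]
    t1, t2, z = g_draws[..., 2], g_draws[..., 3], g_draws[..., 4]
    rb = np.tanh(z)
    if target.rho_w_prior is not None:
        rw = np.tanh(g_draws[..., 5])
        s12 = rw[..., None] * np.sqrt(target.v1 * target.v2)
    else:
        s12 = np.broadcast_to(target.s12, (C, D, S))
    T11 = (t1 * t1)[..., None]
    T22 = (t2 * t2)[..., None]
    T12 = (t1 * t2 * rb)[..., None]
    C11 = target.v1 + T11
    C22 = target.v2 + T22
    C12 = s12 + T12
    det = C11 * C22 - C12 * C12
    # K = T C^{-1}
    K11 = (T11 * C22 - T12 * C12) / det
    K12 = (T12 * C11 - T11 * C12) / det
    K21 = (T12 * C22 - T22 * C12) / det
    K22 = (T22 * C11 - T12 * C12) / det
    e1 = target.y1 - d1[..., None]
    e2 = target.y2 - d2[..., None]
    m1 = d1[..., None] + K11 * e1 + K12 * e2
    m2 = d2[..., None] + K21 * e1 + K22 * e2
    V11 = np.maximum(T11 - (K11 * T11 + K12 * T12), 0.0)
    V12 = T12 - (K11 * T12 + K12 * T22)
    V22 = np.maximum(T22 - (K21 * T12 + K22 * T22), 0.0)
    l11 = np.sqrt(V11)
    with np.errstate(invalid="ignore", divide="ignore"):
        l21 = np.where(l11 > 0, V12 / np.where(l11 > 0, l11, 1.0), 0.0)
    l22 = np.sqrt(np.maximum(V22 - l21 * l21, 0.0))
    z1 = rng.standard_normal((C, D, S))
    z2 = rng.standard_normal((C, D, S))
    return m1 + l11 * z1, m2 + l21 * z1 + l22 * z2


def fit_brma(data: list[LogORStudy], priors: Priors | None = None,
             cfg: McmcConfig | None = None,
             rho_w_draws: np.ndarray | None = None) -> PosteriorSummary:
    """Fit the log-OR-scale model.

    Every study must carry a known ``rho_w``; alternatively pass
    ``rho_w_draws`` (bootstrap draws of a shared within-study correlation)
    to propagate dependence uncertainty through a matched Fisher-z normal
    prior on a single shared ``rho_w``.
    """
    priors = priors or Priors()
    cfg = cfg or McmcConfig()
    if len(data) < 3:
        raise ValueError("at least 3 studies are required to identify the "
                         "between-study parameters")
    rho_prior = None
    if rho_w_draws is not None:
        rho_prior = _fisher_z_prior(rho_w_draws)
    elif any(s.rho_w is None for s in data):
        raise ValueError("every study needs rho_w (or pass rho_w_draws)")
    target = _BrmaTarget(data, priors, rho_prior)
    g, _ = run_mcmc(target, cfg)
    draws = {n: g[..., j] for j, n in enumerate(target.global_names)}
    draws["rho_b"] = np.tanh(draws["z"])
    if rho_prior is not None:
        draws["rho_w"] = np.tanh(draws.pop("z_w"))
    d1l, d2l = _brma_latent_draws(target, g, cfg.seed)
    for i, s in enumerate(data):
        draws[f"delta1[{i}]"] = d1l[..., i]
        draws[f"delta2[{i}]"] = d2l[..., i]
    return summarize_posterior(draws, cfg.rhat_threshold)


# ---------------------------------------------------------------------------
# BRMA-IB and BRMA-BC: exact binomial within-study likelihoods

def _bc_common_denominators(data: list[StudyCounts], strict: bool):
    """The joint per-arm likelihood needs one denominator per arm.  Studies
    reporting outcome-specific denominators are reduced to the smaller
    denominator per arm, with the other outcome's count rescaled
    proportionally (rounded) so its event rate is preserved; a warning is
    emitted per study, or an error under ``strict``."""
    nA = np.empty(len(data))
    nB = np.empty(len(data))
    r = np.empty((len(data), 4))

    def scale(count, n_from, n_to):
        if n_from == n_to:
            return float(count)
        return float(min(round(count * n_to / n_from), n_to))

    for i, s in enumerate(data):
        if not s.equal_denominators:
            if strict:
                raise ValueError(
                    f"study {s.study_id}: outcome-specific denominators are "
                    "not representable in the joint per-arm likelihood "
                    "(strict mode)")
            warnings.warn(
                f"study {s.study_id}: unequal per-outcome denominators; "
                "using the smaller denominator per arm with proportionally "
                "rescaled counts")
        nA[i] = min(s.n_A, s.n2_A)
        nB[i] = min(s.n_B, s.n2_B)
        r[i] = [scale(s.r1_A, s.n_A, nA[i]), scale(s.r2_A, s.n2_A, nA[i]),
                scale(s.r1_B, s.n_B, nB[i]), scale(s.r2_B, s.n2_B, nB[i])]
    return nA, nB, r


class _IbTarget(HierarchicalTarget):
    """Independent exact binomial within-study likelihoods (logit link)."""

    local_names = ["mu1", "mu2", "u1", "u2"]

    def __init__(self, data: list[StudyCounts], priors: Priors):
        self.n1A = np.array([s.n_A for s in data], dtype=float)
        self.n1B = np.array([s.n_B for s in data], dtype=float)
        self.n2A = np.array([s.n2_A for s in data], dtype=float)
        self.n2B = np.array([s.n2_B for s in data], dtype=float)
        self.r1A = np.array([s.r1_A for s in data], dtype=float)
        self.r1B = np.array([s.r1_B for s in data], dtype=float)
        self.r2A = np.array([s.r2_A for s in data], dtype=float)
        self.r2B = np.array([s.r2_B for s in data], dtype=float)
        self.pr = priors
        self.n_studies = len(data)
        self.global_names = ["d1", "d2", "tau1", "tau2", "z"]
        self.global_widths = np.array([0.3, 0.3, 0.3, 0.3, 0.5])
        self.local_widths = np.array([0.4, 0.4, 0.8, 0.8])
        self._lchoose = sum(
            gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)
            for n, r in [(self.n1A, self.r1A), (self.n1B, self.r1B),
                         (self.n2A, self.r2A), (self.n2B, self.r2B)])

    def log_prior_global(self, g):
        d1, d2, t1, t2, z = g[:5]
        if not (0.0 < t1 < self.pr.tau_upper and 0.0 < t2 < self.pr.tau_upper):
            return -np.inf
        return -0.5 * (d1 * d1 + d2 * d2) / self.pr.d_sd ** 2 \
            - 0.5 * (z / self.pr.z_sd) ** 2

    def local_prior(self, group, x):
        if group < 2:  # mu1, mu2
            return -0.5 * x * x / self.pr.mu_sd ** 2
        return -0.5 * x * x

    def _linear_predictors(self, g, loc, sl=slice(None)):
        d1, d2, t1, t2, z = g[:5]
        rb = np.tanh(z)
        mu1, mu2, u1, u2 = loc[0][sl], loc[1][sl], loc[2][sl], loc[3][sl]
        delta1 = d1 + t1 * u1
        delta2 = d2 + t2 * (rb * u1 + np.sqrt(1.0 - rb * rb) * u2)
        return mu1, mu2, mu1 + delta1, mu2 + delta2

    def study_loglik(self, g, loc, idx=None):
        sl = slice(None) if idx is None else idx
        e1A, e2A, e1B, e2B = self._linear_predictors(g, loc, sl)
        ll = self.r1A[sl] * e1A - self.n1A[sl] * np.logaddexp(0.0, e1A) \
            + self.r2A[sl] * e2A - self.n2A[sl] * np.logaddexp(0.0, e2A) \
            + self.r1B[sl] * e1B - self.n1B[sl] * np.logaddexp(0.0, e1B) \
            + self.r2B[sl] * e2B - self.n2B[sl] * np.logaddexp(0.0, e2B)
        return ll + self._lchoose[sl]

    def initial(self, rng):
        g = np.array([rng.normal(0, 0.3), rng.normal(0, 0.3),
                      rng.uniform(0.1, 1.0), rng.uniform(0.1, 1.0),
                      rng.normal(0, 0.5)])
        # start baselines near the empirical control-arm log odds
        p1 = np.clip(self.r1A / self.n1A, 0.02, 0.98)
        p2 = np.clip(self.r2A / self.n2A, 0.02, 0.98)
        loc = np.stack([np.log(p1 / (1 - p1)) + rng.normal(0, 0.2, self.n_studies),
                        np.log(p2 / (1 - p2)) + rng.normal(0, 0.2, self.n_studies),
                        rng.normal(0, 0.5, self.n_studies),
                        rng.normal(0, 0.5, self.n_studies)])
        return g, loc


class _BcTarget(_IbTarget):
    """Joint per-arm likelihood: bivariate binomial pmf with a normal
    copula; dependence parameters fixed per study/shared, or sampled under
    a Fisher-z normal prior fitted to bootstrap draws."""

    def __init__(self, data: list[StudyCounts], dep: WithinDependence,
                 priors: Priors, strict_denominators: bool = False):
        super().__init__(data, priors)
        nA, nB, r = _bc_common_denominators(data, strict_denominators)
        self.bnA, self.bnB = nA, nB
        self.br1A, self.br2A, self.br1B, self.br2B = r.T
        self.dep = dep
        S = self.n_studies
        # precomputed incomplete-beta parameters of the four corner CDFs,
        # shaped (count in {r1, r1-1, r2, r2-1}, arm, study)
        r1 = np.stack([self.br1A, self.br1B])
        r2 = np.stack([self.br2A, self.br2B])
        narm = np.stack([self.bnA, self.bnB])
        k = np.stack([r1, r1 - 1.0, r2, r2 - 1.0])
        n4 = np.broadcast_to(narm, k.shape)
        kk = np.clip(k, 0.0, np.maximum(n4 - 1.0, 0.0))
        self._bc_a = n4 - kk
        self._bc_b = kk + 1.0
        self._bc_lo = k < 0
        self._bc_hi = k >= n4
        if dep.mode == "prior_samples":
            self.zA_prior = _fisher_z_prior(dep.rho_A)
            self.zB_prior = _fisher_z_prior(dep.rho_B)
            self.global_names = self.global_names + ["z_A", "z_B"]
            self.global_widths = np.append(self.global_widths, [0.2, 0.2])
            self.rhoA = self.rhoB = None
        else:
            rA, rB = dep.rho_A, dep.rho_B
            if dep.mode == "shared_fixed":
                rA = np.full(S, rA[0])
                rB = np.full(S, rB[0])
            if len(rA) != S or len(rB) != S:
                raise ValueError("per_study_fixed dependence needs one value "
                                 "per study and arm")
            self.rhoA, self.rhoB = rA, rB

    def log_prior_global(self, g):
        lp = super().log_prior_global(g)
        if self.dep.mode == "prior_samples" and np.isfinite(lp):
            (mA, sA), (mB, sB) = self.zA_prior, self.zB_prior
            lp += -0.5 * ((g[5] - mA) / sA) ** 2 - 0.5 * ((g[6] - mB) / sB) ** 2
        return lp

    def study_loglik(self, g, loc, idx=None):
        sl = slice(None) if idx is None else idx
        e1A, e2A, e1B, e2B = self._linear_predictors(g, loc, sl)
        if self.dep.mode == "prior_samples":
            rho = np.broadcast_to(np.tanh(g[5:7])[:, None], (2, len(e1A)))
        else:
            rho = np.stack([self.rhoA[sl], self.rhoB[sl]])
        # one vectorised special-function call over arms x corners x studies
        p1 = expit(np.stack([e1A, e1B]))           # (arm, study)
        p2 = expit(np.stack([e2A, e2B]))
        p = np.stack([p1, p1, p2, p2])             # aligned with _bc_a corners
        F = betainc(self._bc_a[:, :, sl], self._bc_b[:, :, sl], 1.0 - p)
        F = np.where(self._bc_lo[:, :, sl], 0.0,
                     np.where(self._bc_hi[:, :, sl], 1.0, F))
        F1hi, F1lo, F2hi, F2lo = F
        rho = np.clip(rho, -1 + RHO_EPS, 1 - RHO_EPS)
        u1 = np.stack([F1hi, F1lo, F1hi, F1lo])
        u2 = np.stack([F2hi, F2hi, F2lo, F2lo])
        c = _copula_cdf_formula(u1, u2, rho[None])
        h = c[0] - c[1] - c[2] + c[3]
        ll = np.log(np.maximum(h, PMF_FLOOR))
        return ll[0] + ll[1]

    def initial(self, rng):
        g, loc = super().initial(rng)
        if self.dep.mode == "prior_samples":
            (mA, sA), (mB, sB) = self.zA_prior, self.zB_prior
            g = np.append(g, [rng.normal(mA, sA), rng.normal(mB, sB)])
        return g, loc


def _binomial_fit(target: _IbTarget, data: list[StudyCounts], cfg: McmcConfig,
                  inits=None) -> PosteriorSummary:
    g, loc = run_mcmc(target, cfg, inits=inits)
    draws = {n: g[..., j] for j, n in enumerate(target.global_names)}
    draws["rho_b"] = np.tanh(draws["z"])
    if "z_A" in draws:
        draws["rho_A"] = np.tanh(draws.pop("z_A"))
        draws["rho_B"] = np.tanh(draws.pop("z_B"))
    rb = draws["rho_b"]
    t1, t2 = draws["tau1"], draws["tau2"]
    for i in range(target.n_studies):
        u1 = loc[..., 2, i]
        u2 = loc[..., 3, i]
        draws[f"mu1[{i}]"] = loc[..., 0, i]
        draws[f"mu2[{i}]"] = loc[..., 1, i]
        draws[f"u1[{i}]"] = u1
        draws[f"u2[{i}]"] = u2
        draws[f"delta1[{i}]"] = draws["d1"] + t1 * u1
        draws[f"delta2[{i}]"] = draws["d2"] + t2 * (rb * u1 + np.sqrt(1 - rb ** 2) * u2)
    return summarize_posterior(draws, cfg.rhat_threshold)


def fit_brma_ib(data: list[StudyCounts], priors: Priors | None = None,
                cfg: McmcConfig | None = None) -> PosteriorSummary:
    """Fit the independent-binomial model to arm-level counts."""
    priors = priors or Priors()
    cfg = cfg or McmcConfig()
    if len(data) < 3:
        raise ValueError("at least 3 studies are required to identify the "
                         "between-study parameters")
    return _binomial_fit(_IbTarget(data, priors), data, cfg)


def fit_brma_bc(data: list[StudyCounts], dep: WithinDependence,
                priors: Priors | None = None, cfg: McmcConfig | None = None,
                inits=None, strict_denominators: bool = False) -> PosteriorSummary:
    """Fit the copula model to arm-level counts.

    ``dep`` supplies the within-study dependence parameters; ``inits`` may
    come from :func:`init_bc_from_ib` (recommended — the joint likelihood is
    sensitive to starting values).
    """
    priors = priors or Priors()
    cfg = cfg or McmcConfig()
    if len(data) < 3:
        raise ValueError("at least 3 studies are required to identify the "
                         "between-study parameters")
    target = _BcTarget(data, dep, priors, strict_denominators)
    return _binomial_fit(target, data, cfg, inits=inits)


def init_bc_from_ib(ib_posterior: PosteriorSummary, dep: WithinDependence | None = None,
                    chains: int = 4, jitter: float = 0.05,
                    seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-chain initial values for the copula model taken from the
    independent-binomial posterior means (latents included), jittered
    per chain.  With ``jitter=0`` every chain starts identically."""
    d = ib_posterior.draws
    S = sum(1 for k in d if k.startswith("mu1["))
    mean = lambda k: float(np.mean(d[k]))
    g0 = np.array([mean("d1"), mean("d2"), mean("tau1"), mean("tau2"), mean("z")])
    if dep is not None and dep.mode == "prior_samples":
        g0 = np.append(g0, [_fisher_z_prior(dep.rho_A)[0], _fisher_z_prior(dep.rho_B)[0]])
    loc0 = np.stack([[mean(f"{nm}[{i}]") for i in range(S)]
                     for nm in ("mu1", "mu2", "u1", "u2")])
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x1B)))
    inits = []
    for _ in range(chains):
        g = g0 + rng.normal(0, jitter, g0.shape) if jitter else g0.copy()
        g[2:4] = np.abs(g[2:4]) + 1e-6  # taus stay positive
        loc = loc0 + rng.normal(0, jitter, loc0.shape) if jitter else loc0.copy()
        inits.append((g, loc))
    return inits


def sample_prior(priors: Priors | None = None,
                 cfg: McmcConfig | None = None) -> PosteriorSummary:
    """Sample the between-study prior (no data): useful for prior-predictive
    checks, e.g. that rho_b follows the tanh-transformed normal prior."""
    priors = priors or Priors()
    cfg = cfg or McmcConfig()

    class _PriorOnly(_BrmaTarget):
        def __init__(self):
            self.pr = priors
            self.rho_w_prior = None
            self.n_studies = 0
            self.y1 = self.y2 = self.v1 = self.v2 = self.s12 = np.zeros(0)
            self.global_names = ["d1", "d2", "tau1", "tau2", "z"]
            self.global_widths = np.array([5.0, 5.0, 1.0, 1.0, 0.5])

    g, _ = run_mcmc(_PriorOnly(), cfg)
    draws = {n: g[..., j] for j, n in enumerate(["d1", "d2", "tau1", "tau2", "z"])}
    draws["rho_b"] = np.tanh(draws["z"])
    return summarize_posterior(draws, cfg.rhat_threshold)
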