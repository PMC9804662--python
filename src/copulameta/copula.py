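"""Bivariate Gaussian copula with binomial margins.

The joint law of two correlated event counts is built by gluing two binomial
marginal CDFs with the normal (Gaussian) copula.  Because the margins are
discrete, the joint pmf is the four-corner rectangle difference of the copula
CDF evaluated at neighbouring CDF values (Sklar representation for discrete
margins).  The copula CDF itself is evaluated in closed form through Owen's
T-function rather than by 2-D quadrature, which makes likelihood evaluation
cheap enough for MCMC.

Conventions
-----------
* ``rho`` is the copula dependence parameter, strictly inside (-1, 1);
  ``rho = 0`` reduces every joint quantity to the independence product and
  ``rho -> +/-1`` approaches the Frechet-Hoeffding upper/lower bounds.
* Binomial CDF endpoints are returned exactly: ``F(-1) = 0`` and
  ``F(n) = 1``; the copula CDF handles arguments of 0 and 1 analytically so
  the normal quantile function is never evaluated at an endpoint.
* The rectangle rule can produce tiny negative values through floating-point
  cancellation; the pmf is clamped at a configurable floor (default 1e-12)
  so log-likelihoods stay finite.  Normalisation holds pre-clamp.
* Bernoulli sampling dichotomises a latent standard bivariate normal at the
  upper tail: outcome ``j`` equals 1 when the latent variable exceeds
  ``Phi^{-1}(1 - p_j)``, so the "event" is the upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy.stats import binom

__all__ = [
    "BinomialMargin",
    "CopulaParam",
    "owens_t",
    "normal_copula_cdf",
    "bivariate_binomial_pmf",
    "log_bivariate_binomial_pmf",
    "sample_bernoulli_pair",
]

#: clamp floor applied to the rectangle-rule pmf so logs stay finite
PMF_FLOOR = 1e-12
#: |rho| is capped at 1 - RHO_EPS inside likelihood evaluations
RHO_EPS = 1e-6


@dataclass(frozen=True)
class BinomialMargin:
    """A binomial marginal distribution: ``n_trials`` draws at event rate ``p``."""

    n_trials: int
    p: float

    def __post_init__(self) -> None:
        if not (int(self.n_trials) == self.n_trials and self.n_trials >= 1):
            raise ValueError(f"n_trials must be a positive integer, got {self.n_trials}")
        if not (0.0 < self.p < 1.0):
            raise ValueError(f"p must lie strictly in (0, 1), got {self.p}")

    def cdf(self, x) -> np.ndarray | float:
        """CDF with exact endpoints: ``cdf(-1) == 0`` and ``cdf(n_trials) == 1``."""
        x = np.asarray(x)
        out = np.where(x < 0, 0.0, np.where(x >= self.n_trials, 1.0,
                                            binom.cdf(x, self.n_trials, self.p)))
        return out[()] if out.ndim == 0 else out


@dataclass(frozen=True)
class CopulaParam:
    """Dependence parameter of the normal copula, strictly inside (-1, 1)."""

    rho: float

    def __post_init__(self) -> None:
        if not (-1.0 < self.rho < 1.0):
            raise ValueError(f"rho must lie strictly in (-1, 1), got {self.rho}")


def _as_rho(rho):
    return rho.rho if isinstance(rho, CopulaParam) else rho


def owens_t(h: float, a: float):
    """Owen's T-function ``T(h, a)``.

    ``T(h, a) = (2*pi)^{-1} \\int_0^a exp(-h^2 (1 + x^2) / 2) / (1 + x^2) dx``.
    Even in ``h`` and odd in ``a``; ``T(h, 0) = 0``.  Delegates to the vetted
    scipy routine after validating the arguments.
    """
    h = np.asarray(h, dtype=float)
    a = np.asarray(a, dtype=float)
    if not (np.all(np.isfinite(h)) and np.all(np.isfinite(a))):
        raise ValueError("owens_t requires finite arguments")
    out = special.owens_t(h, a)
    return float(out) if out.ndim == 0 else out


def normal_copula_cdf(u1, u2, rho):
    """Normal-copula CDF ``C(u1, u2; rho)`` via Owen's T-function.

    Implements the closed form

        ``C = (u1 + u2)/2 - T(x1, a1) - T(x2, a2) - delta``

    with ``x_j = Phi^{-1}(u_j)``, ``a1 = (x2/x1 - rho)/sqrt(1-rho^2)`` (and
    symmetrically ``a2``), and the correction ``delta = 1/2`` exactly when one
    argument is below 1/2 and the other at or above it.  Arguments equal to
    1/2 (where ``x = 0``) are handled analytically:

    * ``u1 = u2 = 1/2``:  ``C = 1/4 + arcsin(rho)/(2*pi)``;
    * one argument 1/2:   ``C = u/2 - T(x, -rho/sqrt(1-rho^2))``.

    Boundary values 0 and 1 short-circuit without evaluating ``Phi^{-1}``.
    The result is clamped into the Frechet-Hoeffding bounds
    ``max(0, u1+u2-1) <= C <= min(u1, u2)`` (the exact value always lies
    inside; the clamp removes sub-1e-15 floating noise).
    """
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    r = np.asarray(_as_rho(rho), dtype=float)
    if np.any(u1 < 0) or np.any(u1 > 1) or np.any(u2 < 0) or np.any(u2 > 1):
        raise ValueError("copula arguments must lie in [0, 1]")
    if np.any(np.abs(r) >= 1):
        raise ValueError("rho must lie strictly in (-1, 1)")
    out = _copula_cdf_raw(u1, u2, r)
    return float(out) if out.ndim == 0 else out


def _copula_cdf_raw(u1, u2, r):
    """Validation-free vectorised core of :func:`normal_copula_cdf`."""
    u1, u2, r = np.broadcast_arrays(np.asarray(u1, float), np.asarray(u2, float),
                                    np.asarray(r, float))
    out = np.empty(u1.shape, dtype=float)

    zero = (u1 <= 0) | (u2 <= 0)
    one1 = (u1 >= 1) & ~zero
    one2 = (u2 >= 1) & ~zero
    interior = ~(zero | one1 | one2)
    out[zero] = 0.0
    out[one1] = u2[one1]
    out[one2] = u1[one2]
    # both at 1: min rule gives 1 either way (one1 branch wins, u2 == 1)

    if np.any(interior):
        v1, v2, rr = u1[interior], u2[interior], r[interior]
        s = np.sqrt(1.0 - rr * rr)
        x1 = special.ndtri(v1)
        x2 = special.ndtri(v2)
        res = np.empty(v1.shape, dtype=float)

        both_half = (x1 == 0) & (x2 == 0)
        half1 = (x1 == 0) & ~both_half
        half2 = (x2 == 0) & ~both_half
        gen = ~(both_half | half1 | half2)

        res[both_half] = 0.25 + np.arcsin(rr[both_half]) / (2.0 * np.pi)
        if np.any(half1):
            m = half1
            res[m] = v2[m] / 2.0 - special.owens_t(x2[m], -rr[m] / s[m])
        if np.any(half2):
            m = half2
            res[m] = v1[m] / 2.0 - special.owens_t(x1[m], -rr[m] / s[m])
        if np.any(gen):
            m = gen
            a1 = (x2[m] / x1[m] - rr[m]) / s[m]
            a2 = (x1[m] / x2[m] - rr[m]) / s[m]
            delta = np.where((v1 < 0.5) != (v2 < 0.5), 0.5, 0.0)[m]
            res[m] = (v1[m] + v2[m]) / 2.0 \
                - special.owens_t(x1[m], a1) - special.owens_t(x2[m], a2) - delta

        lo = np.maximum(0.0, v1 + v2 - 1.0)
        hi = np.minimum(v1, v2)
        out[interior] = np.clip(res, lo, hi)

    return out


def _copula_cdf_formula(u1, u2, rho):
    """Lean vectorised copula CDF for likelihood hot paths.

    Pure Owen's-T formula with endpoint clipping instead of explicit
    boundary masks: arguments are clipped into [1e-15, 1 - 1e-15] and exact
    normal quantiles of 0 are nudged to +1e-13 (consistently with the
    ``u >= 1/2`` convention of the half-correction term).  Agrees with
    :func:`normal_copula_cdf` to ~1e-14; assumes ``|rho| < 1`` and performs
    no input validation.
    """
    tiny = 1e-15
    v1 = np.clip(u1, tiny, 1.0 - tiny)
    v2 = np.clip(u2, tiny, 1.0 - tiny)
    x1 = special.ndtri(v1)
    x2 = special.ndtri(v2)
    x1 = np.where(x1 == 0.0, 1e-13, x1)
    x2 = np.where(x2 == 0.0, 1e-13, x2)
    s = np.sqrt(1.0 - rho * rho)
    a1 = (x2 / x1 - rho) / s
    a2 = (x1 / x2 - rho) / s
    delta = np.where((v1 < 0.5) != (v2 < 0.5), 0.5, 0.0)
    return ((v1 + v2) / 2.0 - special.owens_t(x1, a1)
            - special.owens_t(x2, a2) - delta)


def _rect_pmf(r1, r2, n1, n2, p1, p2, rho):
    """Vectorised rectangle-rule joint pmf, pre-clamp (may be ~-1e-16)."""
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    rho = np.clip(np.asarray(rho, dtype=float), -1 + RHO_EPS, 1 - RHO_EPS)
    F1 = lambda x: np.where(x < 0, 0.0, np.where(x >= n1, 1.0, binom.cdf(x, n1, p1)))
    F2 = lambda x: np.where(x < 0, 0.0, np.where(x >= n2, 1.0, binom.cdf(x, n2, p2)))
    c11 = normal_copula_cdf(F1(r1), F2(r2), rho)
    c01 = normal_copula_cdf(F1(r1 - 1), F2(r2), rho)
    c10 = normal_copula_cdf(F1(r1), F2(r2 - 1), rho)
    c00 = normal_copula_cdf(F1(r1 - 1), F2(r2 - 1), rho)
    return c11 - c01 - c10 + c00


def bivariate_binomial_pmf(r1, r2, margin1: BinomialMargin, margin2: BinomialMargin,
                           rho, floor: float | None = PMF_FLOOR):
    """Joint pmf of two binomial counts coupled by a normal copula.

    Rectangle rule on the copula CDF:
    ``h(r1, r2) = C(F1(r1), F2(r2)) - C(F1(r1-1), F2(r2))
    - C(F1(r1), F2(r2-1)) + C(F1(r1-1), F2(r2-1))``.

    Parameters
    ----------
    floor
        Lower clamp applied to the result so downstream logs stay finite.
        Pass ``None`` (or 0) for the raw pre-clamp value, which sums to 1
        over the full support but can dip to ~-1e-16 by cancellation.
    """
    r1a = np.asarray(r1)
    r2a = np.asarray(r2)
    if np.any(r1a < 0) or np.any(r1a > margin1.n_trials):
        raise ValueError(f"r1 outside support [0, {margin1.n_trials}]")
    if np.any(r2a < 0) or np.any(r2a > margin2.n_trials):
        raise ValueError(f"r2 outside support [0, {margin2.n_trials}]")
    h = _rect_pmf(r1a, r2a, margin1.n_trials, margin2.n_trials,
                  margin1.p, margin2.p, _as_rho(rho))
    if floor:
        h = np.maximum(h, floor)
    return float(h) if np.ndim(h) == 0 else h


def log_bivariate_binomial_pmf(r1, r2, margin1: BinomialMargin, margin2: BinomialMargin,
                               rho, floor: float = PMF_FLOOR):
    """Log of the (floor-clamped) joint pmf; never ``-inf``."""
    h = bivariate_binomial_pmf(r1, r2, margin1, margin2, rho, floor=floor)
    out = np.log(h)
    return float(out) if np.ndim(out) == 0 else out


def sample_bernoulli_pair(p1: float, p2: float, rho, size: int, seed=None) -> np.ndarray:
    """Draw ``size`` correlated Bernoulli pairs via the Gaussian-copula
    threshold construction.

    A latent pair ``(Z1, Z2)`` is standard bivariate normal with correlation
    ``rho``; outcome ``j`` is 1 when ``Z_j > Phi^{-1}(1 - p_j)`` (events are
    the upper tail).  Each column is marginally Bernoulli(``p_j``) and the
    (1,1) cell has probability ``p1 + p2 - 1 + C(1-p1, 1-p2; rho)``.

    Returns an integer array of shape ``(size, 2)``.
    """
    if not (0.0 < p1 < 1.0 and 0.0 < p2 < 1.0):
        raise ValueError("p1, p2 must lie strictly in (0, 1)")
    if size < 1:
        raise ValueError(f"size must be >= 1, got {size}")
    r = _as_rho(rho)
    if not (-1.0 < r < 1.0):
        raise ValueError(f"rho must lie strictly in (-1, 1), got {r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z1 = rng.standard_normal(size)
    e = rng.standard_normal(size)
    z2 = r * z1 + np.sqrt(1.0 - r * r) * e
    x1 = (z1 > special.ndtri(1.0 - p1)).astype(np.int8)
    x2 = (z2 > special.ndtri(1.0 - p2)).astype(np.int8)
    return np.column_stack([x1, x2])
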