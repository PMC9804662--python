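"""Bootstrap estimation of within-study association from binary IPD.

Two estimators feed the meta-analytic models:

* :func:`bootstrap_rho_w` — the within-study correlation ``rho_w`` between
  the two log odds ratios, estimated as the Pearson correlation of the log
  ORs computed on patient resamples (drawn with replacement within each
  arm); this populates the log-OR-scale model.
* :func:`bootstrap_rho_arm` — the copula dependence parameter of one arm's
  joint count law, estimated by a two-stage (inference-functions-for-
  margins) maximum likelihood on bootstrap count pairs: binomial margins
  first, then the dependence parameter with margins held fixed; this
  populates the copula model.

When no IPD exist, :func:`double_bootstrap_prior` turns a published cohort
summary (response rate plus final-outcome rates conditional on response)
into an empirical prior for either association parameter: pseudo-IPD are
reconstructed from the 2x2 table, an outer bootstrap perturbs the cohort,
and the inner estimator is applied to every outer draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .copula import PMF_FLOOR, RHO_EPS, _copula_cdf_formula
from .data import BinaryIpdStudy, CohortSummary
from scipy.special import betainc

__all__ = ["BootstrapConfig", "BootstrapResult", "DependenceFit",
           "bootstrap_rho_w", "fit_dependence_two_stage",
           "bootstrap_rho_arm", "double_bootstrap_prior"]

_RHO_BOUND = 1.0 - RHO_EPS
_MAX_REDRAWS = 100


@dataclass
class BootstrapConfig:
    """``n_boot`` patient resamples per estimate; ``degenerate_policy`` is
    ``"resample"`` (redraw a degenerate bootstrap, the default) or
    ``"fail"`` (raise)."""

    n_boot: int = 3000
    seed: int = 0
    degenerate_policy: str = "resample"

    def __post_init__(self) -> None:
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")
        if self.degenerate_policy not in ("resample", "fail"):
            raise ValueError("degenerate_policy must be 'resample' or 'fail'")


@dataclass
class BootstrapResult:
    estimate: float
    draws: np.ndarray
    n_redraws: int = 0


@dataclass
class DependenceFit:
    rho: float
    converged: bool
    loglik: float = np.nan


def _cells(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """2x2 cell counts (n11, n10, n01, n00) of two binary vectors."""
    n11 = int(np.sum((x1 == 1) & (x2 == 1)))
    n10 = int(np.sum((x1 == 1) & (x2 == 0)))
    n01 = int(np.sum((x1 == 0) & (x2 == 1)))
    n00 = int(np.sum((x1 == 0) & (x2 == 0)))
    return np.array([n11, n10, n01, n00])


def _resample_counts(cells: np.ndarray, n_boot: int,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap (r1*, r2*) count pairs for one arm by multinomial
    resampling of its 2x2 cells (equivalent to resampling patients with
    replacement)."""
    n = int(cells.sum())
    draws = rng.multinomial(n, cells / n, size=n_boot)
    r1 = draws[:, 0] + draws[:, 1]
    r2 = draws[:, 0] + draws[:, 2]
    return r1, r2


def _log_or_series(rB, nB, rA, nA, correction=0.5):
    """Vectorised log OR of bootstrap counts, continuity-corrected per
    resample whenever a cell of that resample's 2x2 table is zero."""
    a, b = np.asarray(rB, float), nB - np.asarray(rB, float)
    c, d = np.asarray(rA, float), nA - np.asarray(rA, float)
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    corr = np.where(zero, correction, 0.0)
    a, b, c, d = a + corr, b + corr, c + corr, d + corr
    return np.log(a / b) - np.log(c / d)


def bootstrap_rho_w(ipd: BinaryIpdStudy, cfg: BootstrapConfig | None = None) -> BootstrapResult:
    """Within-study correlation of the two log ORs by patient bootstrap.

    Patients are resampled with replacement within each arm; both outcomes'
    log ORs are computed from the same resample, and the estimate is the
    Pearson correlation of the ``n_boot`` (y1*, y2*) pairs.
    """
    cfg = cfg or BootstrapConfig()
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xB00)))
    x1A, x2A = ipd.arm_data("A")
    x1B, x2B = ipd.arm_data("B")
    if len(x1A) == 0 or len(x1B) == 0:
        raise ValueError(f"study {ipd.study_id}: both arms must be present")
    cA, cB = _cells(x1A, x2A), _cells(x1B, x2B)
    nA, nB = len(x1A), len(x1B)
    redraws = 0
    for _ in range(_MAX_REDRAWS + 1):
        r1A, r2A = _resample_counts(cA, cfg.n_boot, rng)
        r1B, r2B = _resample_counts(cB, cfg.n_boot, rng)
        y1 = _log_or_series(r1B, nB, r1A, nA)
        y2 = _log_or_series(r2B, nB, r2A, nA)
        if y1.std() > 0 and y2.std() > 0:
            est = float(np.corrcoef(y1, y2)[0, 1])
            return BootstrapResult(est, np.column_stack([y1, y2]), redraws)
        if cfg.degenerate_policy == "fail":
            raise ValueError(f"study {ipd.study_id}: zero variance in a "
                             "bootstrap log-OR series")
        # constant series can only arise from constant IPD; a redraw is
        # attempted but cannot succeed then, so the loop is capped
        redraws += 1
    raise ValueError(f"study {ipd.study_id}: degenerate IPD, bootstrap "
                     f"log-OR series has zero variance after {redraws} redraws")


def _binom_cdf(k, n, p):
    kk = np.clip(k, 0, max(n - 1, 0))
    val = betainc(n - kk, kk + 1.0, 1.0 - p)
    return np.where(k < 0, 0.0, np.where(k >= n, 1.0, val))


def _corner_cdfs(r1u, r2u, n, p1, p2):
    """Rectangle-corner margin CDFs for unique count pairs (independent of
    the dependence parameter, so computed once per optimisation)."""
    F1hi = _binom_cdf(r1u, n, p1)
    F1lo = _binom_cdf(r1u - 1.0, n, p1)
    F2hi = _binom_cdf(r2u, n, p2)
    F2lo = _binom_cdf(r2u - 1.0, n, p2)
    return (np.stack([F1hi, F1lo, F1hi, F1lo]),
            np.stack([F2hi, F2hi, F2lo, F2lo]))


def _pairs_loglik(u1, u2, w, rho):
    """Copula-pmf log likelihood of weighted unique count pairs given the
    precomputed corner CDFs."""
    rho = float(np.clip(rho, -_RHO_BOUND, _RHO_BOUND))
    c = _copula_cdf_formula(u1, u2, rho)
    h = c[0] - c[1] - c[2] + c[3]
    return float(np.sum(w * np.log(np.maximum(h, PMF_FLOOR))))


def fit_dependence_two_stage(count_pairs, n: int) -> DependenceFit:
    """Two-stage MLE of the copula dependence parameter from (r1, r2)
    count pairs sharing arm size ``n``.

    Stage 1 estimates the binomial margins, ``p_j = sum(r_j) / (n * K)``;
    stage 2 maximises the joint copula-pmf likelihood over the dependence
    parameter alone, bounded inside (-1, 1), with multi-start at
    {-0.5, 0, 0.5}.
    """
    pairs = np.asarray(count_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or len(pairs) < 2:
        raise ValueError("count_pairs must be a (K, 2) array with K >= 2")
    r1, r2 = pairs[:, 0], pairs[:, 1]
    p1 = r1.sum() / (n * len(pairs))
    p2 = r2.sum() / (n * len(pairs))
    if np.ptp(r1) == 0 and np.ptp(r2) == 0:
        raise ValueError("count pairs have no variance; dependence is not identifiable")
    if not (0.0 < p1 < 1.0 and 0.0 < p2 < 1.0):
        raise ValueError("a margin is degenerate (p-hat of 0 or 1); "
                         "dependence is not identifiable")
    uniq, w = np.unique(pairs, axis=0, return_counts=True)
    u1, u2 = _corner_cdfs(uniq[:, 0], uniq[:, 1], n, p1, p2)
    obj = lambda v: -_pairs_loglik(u1, u2, w, v[0])
    best = None
    ok = False
    for start in (-0.5, 0.0, 0.5):
        res = minimize(obj, x0=[start], method="L-BFGS-B",
                       bounds=[(-_RHO_BOUND, _RHO_BOUND)])
        if best is None or res.fun < best.fun:
            best = res
        ok = ok or (res.success and np.isfinite(res.fun))
    return DependenceFit(rho=float(best.x[0]), converged=bool(ok),
                         loglik=float(-best.fun))


def bootstrap_rho_arm(x1: np.ndarray, x2: np.ndarray,
                      cfg: BootstrapConfig | None = None) -> tuple[DependenceFit, BootstrapResult]:
    """Copula dependence parameter of one arm by bootstrap + two-stage MLE.

    ``n_boot`` count pairs (r1*, r2*) are generated by resampling the arm's
    patients with replacement, and the two-stage MLE is applied to the
    pairs.  Returns the fit (estimate + optimiser convergence status) and a
    bootstrap record with the count pairs and redraw count.
    """
    cfg = cfg or BootstrapConfig()
    x1 = np.asarray(x1)
    x2 = np.asarray(x2)
    if len(x1) < 2:
        raise ValueError("an arm needs at least 2 patients")
    cells = _cells(x1, x2)
    if np.ptp(x1) == 0 and np.ptp(x2) == 0:
        raise ValueError("degenerate arm IPD: both outcomes are constant, "
                         "the bootstrap cannot estimate the dependence")
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xA12)))
    n = len(x1)
    redraws = 0
    last = None
    for _ in range(_MAX_REDRAWS + 1):
        r1, r2 = _resample_counts(cells, cfg.n_boot, rng)
        try:
            fit = fit_dependence_two_stage(np.column_stack([r1, r2]), n)
        except ValueError:
            fit = DependenceFit(rho=np.nan, converged=False)
        last = (fit, BootstrapResult(fit.rho, np.column_stack([r1, r2]), redraws))
        if fit.converged:
            return last
        if cfg.degenerate_policy == "fail":
            raise ValueError("dependence optimiser failed to converge on the "
                             "bootstrap count pairs")
        redraws += 1
    return last


def _pseudo_ipd_cells(cohort: CohortSummary) -> np.ndarray:
    """2x2 cell counts from the cohort rates, largest-remainder rounded so
    the cells sum exactly to n."""
    p = np.array([
        cohort.p_surrogate * cohort.p_final_given_resp,
        cohort.p_surrogate * (1 - cohort.p_final_given_resp),
        (1 - cohort.p_surrogate) * cohort.p_final_given_nonresp,
        (1 - cohort.p_surrogate) * (1 - cohort.p_final_given_nonresp)])
    raw = p * cohort.n
    cells = np.floor(raw).astype(int)
    short = cohort.n - cells.sum()
    order = np.argsort(-(raw - np.floor(raw)))
    cells[order[:short]] += 1
    return cells


def double_bootstrap_prior(cohort: CohortSummary, outer_reps: int = 1000,
                           cfg: BootstrapConfig | None = None,
                           target: str = "rho_arm") -> np.ndarray:
    """Empirical prior draws for a within-study association parameter from
    a cohort summary, by double bootstrap.

    The cohort's 2x2 table (surrogate response x final outcome) is
    reconstructed as pseudo-IPD.  The outer loop resamples the pseudo-IPD;
    for each outer draw the inner bootstrap computes the requested
    association: the copula dependence parameter (``target="rho_arm"``) or
    the correlation between the two outcomes' bootstrap log odds
    (``target="rho_w"``).  Returns ``outer_reps`` association values.
    """
    cfg = cfg or BootstrapConfig()
    if target not in ("rho_arm", "rho_w"):
        raise ValueError("target must be 'rho_arm' or 'rho_w'")
    if outer_reps < 1:
        raise ValueError("outer_reps must be >= 1")
    cells0 = _pseudo_ipd_cells(cohort)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xDB)))
    n = cohort.n
    out = np.empty(outer_reps)
    i = 0
    attempts = 0
    while i < outer_reps:
        attempts += 1
        if attempts > outer_reps * 20:
            raise RuntimeError("double bootstrap failed to produce usable "
                               "outer resamples")
        cells = rng.multinomial(n, cells0 / n)
        inner_seed = int(rng.integers(2 ** 31))
        inner = BootstrapConfig(n_boot=cfg.n_boot, seed=inner_seed,
                                degenerate_policy=cfg.degenerate_policy)
        if target == "rho_arm":
            x1 = np.repeat([1, 1, 0, 0], cells)
            x2 = np.repeat([1, 0, 1, 0], cells)
            if np.ptp(x1) == 0 and np.ptp(x2) == 0:
                continue
            try:
                fit, _ = bootstrap_rho_arm(x1, x2, inner)
            except ValueError:
                continue
            if not np.isfinite(fit.rho):
                continue
            out[i] = fit.rho
        else:
            irng = np.random.default_rng(np.random.SeedSequence((inner_seed, 0xB00)))
            r1, r2 = _resample_counts(cells, cfg.n_boot, irng)
            # single-cohort log odds on each outcome, corrected at the edges
            c1 = np.where((r1 == 0) | (r1 == n), 0.5, 0.0)
            c2 = np.where((r2 == 0) | (r2 == n), 0.5, 0.0)
            y1 = np.log((r1 + c1) / (n - r1 + c1))
            y2 = np.log((r2 + c2) / (n - r2 + c2))
            if y1.std() == 0 or y2.std() == 0:
                continue
            out[i] = float(np.corrcoef(y1, y2)[0, 1])
        i += 1
    return np.clip(out, -_RHO_BOUND, _RHO_BOUND)
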