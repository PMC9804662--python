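"""Domain containers for arm-level counts, log-OR summaries, binary IPD,
within-study dependence inputs and cohort summaries.

The central object is :class:`StudyCounts`: one randomized study's event
counts on two binary outcomes (a surrogate endpoint and a final outcome) in
a control arm A and a treatment arm B.  Some trials report the two outcomes
on different denominators (for example a response endpoint evaluated on a
molecular-monitoring subset but survival on everyone); ``n2_A``/``n2_B``
carry the outcome-2 denominators when they differ from the outcome-1 arm
sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StudyCounts",
    "LogORStudy",
    "WithinDependence",
    "BinaryIpdStudy",
    "CohortSummary",
]


@dataclass(frozen=True)
class StudyCounts:
    """Arm-level counts for one study.

    ``r1_A`` is the outcome-1 (surrogate) event count in control arm A out of
    ``n_A`` patients; ``r2_B`` the outcome-2 (final) count in treatment arm B
    out of ``n2_B`` (defaults to ``n_B``), and so on.
    """

    study_id: str
    n_A: int
    n_B: int
    r1_A: int
    r2_A: int
    r1_B: int
    r2_B: int
    n2_A: int | None = None
    n2_B: int | None = None

    def __post_init__(self) -> None:
        if self.n_A < 1 or self.n_B < 1:
            raise ValueError(f"study {self.study_id}: arm sizes must be >= 1")
        if self.n2_A is None:
            object.__setattr__(self, "n2_A", self.n_A)
        if self.n2_B is None:
            object.__setattr__(self, "n2_B", self.n_B)
        if self.n2_A < 1 or self.n2_B < 1:
            raise ValueError(f"study {self.study_id}: outcome-2 denominators must be >= 1")
        for name, r, n in [("r1_A", self.r1_A, self.n_A), ("r1_B", self.r1_B, self.n_B),
                           ("r2_A", self.r2_A, self.n2_A), ("r2_B", self.r2_B, self.n2_B)]:
            if not (0 <= r <= n):
                raise ValueError(
                    f"study {self.study_id}: count {name}={r} outside [0, {n}]")

    @property
    def equal_denominators(self) -> bool:
        return self.n2_A == self.n_A and self.n2_B == self.n_B


@dataclass
class LogORStudy:
    """Normal-approximation view of one study: log odds ratios on both
    outcomes with their within-study variances and (optionally) the
    within-study correlation ``rho_w`` between the two log ORs."""

    study_id: str
    y1: float
    y2: float
    v1: float
    v2: float
    rho_w: float | None = None

    def __post_init__(self) -> None:
        if self.v1 <= 0 or self.v2 <= 0:
            raise ValueError(f"study {self.study_id}: variances must be positive")
        if self.rho_w is not None and not (-1.0 <= self.rho_w <= 1.0):
            raise ValueError(f"study {self.study_id}: rho_w outside [-1, 1]")


@dataclass
class WithinDependence:
    """Within-study copula dependence input for the copula model.

    ``mode`` selects how the per-arm dependence parameters enter the fit:

    * ``per_study_fixed`` — ``rho_A``/``rho_B`` are sequences, one known
      value per study and arm (the bootstrap plug-in route);
    * ``shared_fixed`` — a single known value per arm shared by all studies;
    * ``prior_samples`` — ``rho_A``/``rho_B`` are empirical prior draws
      (>= 100 each); the fit propagates the dependence uncertainty through
      a Fisher-z normal prior matched to the draws.
    """

    mode: str
    rho_A: np.ndarray = field(default_factory=lambda: np.array([]))
    rho_B: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if self.mode not in ("per_study_fixed", "shared_fixed", "prior_samples"):
            raise ValueError(f"unknown dependence mode {self.mode!r}")
        self.rho_A = np.atleast_1d(np.asarray(self.rho_A, dtype=float))
        self.rho_B = np.atleast_1d(np.asarray(self.rho_B, dtype=float))
        for name, v in [("rho_A", self.rho_A), ("rho_B", self.rho_B)]:
            if np.any(np.abs(v) >= 1.0):
                raise ValueError(f"{name}: dependence values must lie strictly in (-1, 1)")
        if self.mode == "prior_samples" and (len(self.rho_A) < 100 or len(self.rho_B) < 100):
            raise ValueError("prior_samples mode requires >= 100 draws per arm")
        if self.mode == "shared_fixed" and (self.rho_A.size != 1 or self.rho_B.size != 1):
            raise ValueError("shared_fixed mode takes exactly one value per arm")


@dataclass
class BinaryIpdStudy:
    """Binary individual-patient data for one study: per-patient arm label
    ('A' or 'B') and the two outcome indicators."""

    study_id: str
    arm: np.ndarray
    x1: np.ndarray
    x2: np.ndarray

    def __post_init__(self) -> None:
        self.arm = np.asarray(self.arm)
        self.x1 = np.asarray(self.x1, dtype=np.int8)
        self.x2 = np.asarray(self.x2, dtype=np.int8)
        if not (len(self.arm) == len(self.x1) == len(self.x2)):
            raise ValueError("arm, x1, x2 must have equal length")
        if not np.all(np.isin(self.arm, ["A", "B"])):
            raise ValueError("arm labels must be 'A' or 'B'")
        if not (np.all(np.isin(self.x1, [0, 1])) and np.all(np.isin(self.x2, [0, 1]))):
            raise ValueError("outcome indicators must be 0/1")
        for a in np.unique(self.arm):
            if np.sum(self.arm == a) < 2:
                raise ValueError(f"study {self.study_id}: arm {a} has fewer than 2 patients")

    def arm_data(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.arm == label
        return self.x1[m], self.x2[m]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"study": self.study_id, "arm": self.arm,
                             "x1": self.x1, "x2": self.x2})


@dataclass(frozen=True)
class CohortSummary:
    """Published summary of a single-arm observational cohort: cohort size,
    the surrogate response rate, and the final-outcome rate conditional on
    response status.  Enough to reconstruct the 2x2 pseudo-IPD table."""

    n: int
    p_surrogate: float
    p_final_given_resp: float
    p_final_given_nonresp: float

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("cohort size must be at least 4")
        for name in ("p_surrogate", "p_final_given_resp", "p_final_given_nonresp"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie strictly in (0, 1), got {v}")
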