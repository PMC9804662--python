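"""Readers and writers for the plain-text formats the package consumes and
produces, plus the packaged 10-study chronic myeloid leukemia (CML) example
dataset (CCyR response at 12 months as the surrogate endpoint, event-free
survival at 24 months as the final outcome).

All formats are CSV/JSON.  The counts schema is one row per study::

    study,n_A,r1_A,r2_A,n_B,r1_B,r2_B[,n2_A,n2_B]

where ``n2_A``/``n2_B`` are optional outcome-2 denominators for trials that
report the two outcomes on different patient sets.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

from .data import BinaryIpdStudy, StudyCounts
from .sampler import PosteriorSummary

__all__ = ["read_counts", "write_counts", "load_cml", "read_ipd",
           "write_posterior", "write_draws"]

_REQUIRED = ["study", "n_A", "r1_A", "r2_A", "n_B", "r1_B", "r2_B"]
_OPTIONAL = ["n2_A", "n2_B"]


def read_counts(path) -> list[StudyCounts]:
    """Read and validate an arm-level counts CSV into StudyCounts rows."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty dataset (no study rows)")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out = []
    for idx, row in df.iterrows():
        for col in _REQUIRED[1:] + [c for c in _OPTIONAL if c in df.columns]:
            v = row[col]
            if pd.isna(v) or int(v) != v or int(v) < 0:
                raise ValueError(f"{path}: row {idx} column {col!r}: "
                                 f"expected a non-negative integer, got {v!r}")
        try:
            out.append(StudyCounts(
                study_id=str(row["study"]),
                n_A=int(row["n_A"]), n_B=int(row["n_B"]),
                r1_A=int(row["r1_A"]), r2_A=int(row["r2_A"]),
                r1_B=int(row["r1_B"]), r2_B=int(row["r2_B"]),
                n2_A=int(row["n2_A"]) if "n2_A" in df.columns else None,
                n2_B=int(row["n2_B"]) if "n2_B" in df.columns else None))
        except ValueError as e:
            raise ValueError(f"{path}: row {idx}: {e}") from e
    return out


def write_counts(studies: list[StudyCounts], path) -> None:
    pd.DataFrame([{
        "study": s.study_id, "n_A": s.n_A, "r1_A": s.r1_A, "r2_A": s.r2_A,
        "n_B": s.n_B, "r1_B": s.r1_B, "r2_B": s.r2_B,
        "n2_A": s.n2_A, "n2_B": s.n2_B} for s in studies]).to_csv(path, index=False)


def load_cml() -> list[StudyCounts]:
    """The packaged 10-study CML dataset (arm-level counts for CCyR at 12
    months and event-free survival at 24 months; the survival outcome counts
    patients who were event-free, so both correlations are positive)."""
    ref = importlib.resources.files("copulameta") / "data" / "cml.csv"
    with importlib.resources.as_file(ref) as p:
        return read_counts(p)


def read_ipd(path) -> list[BinaryIpdStudy]:
    """Read binary IPD (one row per patient: study,arm,x1,x2)."""
    df = pd.read_csv(path)
    need = ["study", "arm", "x1", "x2"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out = []
    for sid, grp in df.groupby("study", sort=False):
        out.append(BinaryIpdStudy(study_id=str(sid), arm=grp["arm"].to_numpy(),
                                  x1=grp["x1"].to_numpy(), x2=grp["x2"].to_numpy()))
    return out


def write_posterior(summary: PosteriorSummary, path) -> None:
    """Posterior summary CSV: parameter, mean, median, q2.5, q97.5, rhat, ess."""
    t = summary.table.copy()
    t.insert(0, "parameter", t.index)
    t.to_csv(path, index=False)


def write_draws(summary: PosteriorSummary, path) -> None:
    """Retained draws in long columnar CSV (chain, draw, one column per
    parameter)."""
    cols = {}
    for name, d in summary.draws.items():
        d = np.asarray(d)
        cols[name] = d.reshape(-1)
    nchain, ndraw = next(iter(summary.draws.values())).shape
    idx = pd.MultiIndex.from_product([range(nchain), range(ndraw)],
                                     names=["chain", "draw"])
    pd.DataFrame(cols, index=idx).reset_index().to_csv(path, index=False)
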