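"""Drought-screen statistics: plant water content, tolerance classes,
PWC–wilting correlation and ecotype ranking.

Plant water content on a fresh-weight basis,

    PWC (%) = (FW − DW) / FW × 100,

summarizes how well an ecotype retained water through a terminal drought.
Ecotypes are classed tolerant (TOL) above 70% PWC, susceptible (SUS) below
55%, intermediate (INT) in between (both boundary values inclusive to INT).
Visual wilting on the ordinal 1–6 scale is the complementary eye-based
score; across a panel of ecotypes the two measures are strongly negatively
correlated, which is checked at the ecotype-mean level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, DomainError, InsufficientDataError

__all__ = [
    "TOL",
    "INT",
    "SUS",
    "DEFAULT_THRESHOLDS",
    "compute_pwc",
    "classify_tolerance",
    "correlate_pwc_wilting",
    "rank_ecotypes",
]

TOL, INT, SUS = "TOL", "INT", "SUS"

# (sus_below, tol_above) PWC percentage thresholds
DEFAULT_THRESHOLDS = (55.0, 70.0)


def compute_pwc(fw, dw):
    """Plant water content (%) on a fresh-weight basis: (FW − DW)/FW × 100.

    Accepts scalars or aligned arrays; scale-invariant in (FW, DW).
    """
    fw_arr = np.asarray(fw, dtype=float)
    dw_arr = np.asarray(dw, dtype=float)
    if (fw_arr <= 0).any():
        raise DomainError("fresh weight must be > 0")
    if (dw_arr < 0).any() or (dw_arr > fw_arr).any():
        raise DomainError("dry weight must satisfy 0 <= DW <= FW")
    out = (fw_arr - dw_arr) / fw_arr * 100.0
    return float(out) if out.ndim == 0 else out


def classify_tolerance(pwc: float, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS) -> str:
    """Tolerance class from PWC: TOL iff pwc > 70, SUS iff pwc < 55, else INT.

    Both boundary values belong to INT (the intermediate band is printed as
    a closed range).  Thresholds are overridable as (sus_below, tol_above).
    """
    if not 0.0 <= pwc <= 100.0:
        raise DomainError(f"PWC must be in [0, 100], got {pwc}")
    sus_below, tol_above = thresholds
    if pwc > tol_above:
        return TOL
    if pwc < sus_below:
        return SUS
    return INT


def _ecotype_means(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    if "PWC" not in df.columns:
        df["PWC"] = compute_pwc(df["FW"].to_numpy(), df["DW"].to_numpy())
    return df.groupby("ecotype").agg(
        pwc_mean=("PWC", "mean"), pwc_sd=("PWC", "std"),
        wilting_mean=("wilting", "mean"), n=("PWC", "size"),
    )


def correlate_pwc_wilting(records: pd.DataFrame) -> tuple[float, float]:
    """Pearson r (with two-sided p) between ecotype-mean PWC and ecotype-mean
    wilting.

    ``records`` is replicate-level with columns ecotype, FW, DW, wilting
    (or a precomputed PWC column).  Requires >= 3 ecotypes and non-constant
    vectors.
    """
    means = _ecotype_means(records)
    if len(means) < 3:
        raise InsufficientDataError("need at least 3 ecotypes for a correlation")
    x = means["pwc_mean"].to_numpy()
    y = means["wilting_mean"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("correlation undefined: constant PWC or wilting")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def rank_ecotypes(
    records: pd.DataFrame, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Ecotypes ranked by mean PWC (descending; ties alphabetical), with
    per-ecotype SD, mean wilting and tolerance class."""
    means = _ecotype_means(records).reset_index()
    means["tolerance"] = [
        classify_tolerance(v, thresholds) for v in means["pwc_mean"]
    ]
    means = means.sort_values(
        ["pwc_mean", "ecotype"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    means.insert(0, "rank", np.arange(1, len(means) + 1))
    return means
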