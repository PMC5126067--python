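"""FIE-MS matrix preprocessing and univariate feature screening.

Flow-injection electrospray mass spectrometry yields one ion-intensity
profile per sample, indexed by nominal m/z.  Preprocessing removes features
below a mass cutoff (default 50 m/z, where instrument noise dominates) and
expresses every remaining intensity as a percentage of the sample's total
ion count (TIC), making profiles comparable across injections.  Screening
is per-feature one-way fixed-effects ANOVA across tolerance classes, with
optional Benjamini–Hochberg q-values, plus targeted extraction of features
matching a list of pathway m/z values within a mass tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, FormatError, NormalizationError

__all__ = [
    "DEFAULT_MIN_MZ",
    "MetaboliteMatrix",
    "tic_normalize",
    "anova_oneway",
    "anova_screen",
    "extract_pathway_features",
]

DEFAULT_MIN_MZ = 50.0

_META_COLUMNS = ("sample", "group", "treatment")


@dataclass
class MetaboliteMatrix:
    """Samples x m/z intensity table with per-sample class labels.

    ``intensities`` is a DataFrame indexed by sample id with float m/z
    column labels; ``groups`` assigns each sample a tolerance class
    (TOL/INT/SUS); ``treatment`` optionally records the soil-water-content
    level.
    """

    intensities: pd.DataFrame
    groups: pd.Series | None = None
    treatment: pd.Series | None = None

    def __post_init__(self):
        vals = self.intensities.to_numpy()
        if (vals < 0).any():
            raise FormatError("ion intensities must be non-negative")
        mz = np.asarray(self.intensities.columns, dtype=float)
        if (mz <= 0).any():
            raise FormatError("m/z values must be positive")
        self.intensities.columns = mz
        if self.groups is not None:
            self.groups = self.groups.reindex(self.intensities.index)

    @property
    def mz(self) -> np.ndarray:
        return np.asarray(self.intensities.columns, dtype=float)

    # -- CSV layout: sample, group, treatment, then one column per m/z -----

    def to_csv(self, path) -> None:
        out = self.intensities.copy()
        out.insert(0, "treatment", self.treatment if self.treatment is not None else "")
        out.insert(0, "group", self.groups if self.groups is not None else "")
        out.index.name = "sample"
        out.to_csv(Path(path))

    @classmethod
    def from_csv(cls, path) -> "MetaboliteMatrix":
        df = pd.read_csv(Path(path), index_col="sample")
        groups = df.pop("group") if "group" in df.columns else None
        treatment = df.pop("treatment") if "treatment" in df.columns else None
        df.columns = [float(c) for c in df.columns]
        if groups is not None and groups.isna().all():
            groups = None
        return cls(intensities=df, groups=groups, treatment=treatment)


def tic_normalize(matrix: MetaboliteMatrix, min_mz: float = DEFAULT_MIN_MZ) -> MetaboliteMatrix:
    """Remove features below ``min_mz``, then scale each sample to total 100.

    Every intensity becomes a percentage of its sample's total ion count, so
    each row sums to exactly 100 and the result is invariant to per-sample
    rescaling of the raw intensities.
    """
    keep = matrix.mz >= min_mz
    if not keep.any():
        raise NormalizationError(f"no features with m/z >= {min_mz}")
    sub = matrix.intensities.loc[:, keep]
    totals = sub.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise NormalizationError(f"all-zero sample(s) after filtering: {list(zero.index)}")
    normalized = sub.div(totals, axis=0) * 100.0
    return MetaboliteMatrix(
        intensities=normalized, groups=matrix.groups, treatment=matrix.treatment
    )


def anova_oneway(groups_values: Sequence[np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA from group value arrays: (F, p).

    Degenerate contracts: zero between-group variance reports F = 0, p = 1;
    zero within-group variance with real between-group differences reports
    F = +inf, p = 0.
    """
    groups_values = [np.asarray(g, dtype=float) for g in groups_values]
    if len(groups_values) < 2:
        raise DegenerateDataError("ANOVA needs at least 2 groups")
    if any(len(g) < 2 for g in groups_values):
        raise DegenerateDataError("every group needs at least 2 samples")
    allv = np.concatenate(groups_values)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups_values)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups_values)
    dfb = len(groups_values) - 1
    dfw = len(allv) - len(groups_values)
    if ssb <= 0:
        return 0.0, 1.0
    if ssw <= 0:
        return float("inf"), 0.0
    f = (ssb / dfb) / (ssw / dfw)
    return float(f), float(stats.f.sf(f, dfb, dfw))


def _anova_matrix(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-column one-way ANOVA. values: samples x features."""
    classes, idx = np.unique(labels, return_inverse=True)
    k = len(classes)
    if k < 2:
        raise DegenerateDataError("ANOVA needs at least 2 groups")
    n_per = np.bincount(idx, minlength=k).astype(float)
    if (n_per < 2).any():
        small = classes[n_per < 2]
        raise DegenerateDataError(f"group(s) with < 2 samples: {list(small)}")
    n = values.shape[0]
    grand = values.mean(axis=0)
    sums = np.zeros((k, values.shape[1]))
    for g in range(k):
        sums[g] = values[idx == g].sum(axis=0)
    means = sums / n_per[:, None]
    ssb = (n_per[:, None] * (means - grand) ** 2).sum(axis=0)
    sst = ((values - grand) ** 2).sum(axis=0)
    ssw = np.maximum(sst - ssb, 0.0)
    dfb, dfw = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / dfb) / (ssw / dfw)
    p = np.where(ssb <= 1e-300 * np.maximum(sst, 1.0), 1.0, stats.f.sf(f, dfb, dfw))
    f = np.where(ssb <= 1e-300 * np.maximum(sst, 1.0), 0.0, f)
    p = np.where(np.isinf(f), 0.0, p)
    return f, p


def anova_screen(
    matrix: MetaboliteMatrix,
    groups: pd.Series | None = None,
    *,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-feature one-way ANOVA across tolerance classes.

    Returns a DataFrame sorted by ascending p with columns ``mz``, ``F``,
    ``p``, per-class mean columns ``mean_<class>``, and ``q``
    (Benjamini–Hochberg) when ``fdr`` is set.
    """
    g = groups if groups is not None else matrix.groups
    if g is None:
        raise DegenerateDataError("no group labels available for ANOVA")
    g = g.reindex(matrix.intensities.index)
    values = matrix.intensities.to_numpy(dtype=float)
    labels = g.to_numpy()
    f, p = _anova_matrix(values, labels)
    out = pd.DataFrame({"mz": matrix.mz, "F": f, "p": p})
    for cls_name in np.unique(labels):
        out[f"mean_{cls_name}"] = values[labels == cls_name].mean(axis=0)
    if fdr:
        out["q"] = stats.false_discovery_control(np.clip(p, 0.0, 1.0), method="bh")
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def extract_pathway_features(
    matrix: MetaboliteMatrix,
    mz_targets: Sequence[float],
    *,
    tolerance_ppm: float | None = 10.0,
    tolerance_da: float | None = None,
) -> MetaboliteMatrix:
    """Extract the sub-matrix of features matching target pathway m/z values.

    Each target is matched to at most the nearest feature within tolerance
    (ppm by default; absolute Daltons when ``tolerance_da`` is given); ties
    resolve to the lower m/z.  Unmatched targets produce a warning, never an
    error.
    """
    if tolerance_da is None and (tolerance_ppm is None or tolerance_ppm <= 0):
        raise FormatError("tolerance must be positive")
    if tolerance_da is not None and tolerance_da <= 0:
        raise FormatError("tolerance must be positive")
    mz = matrix.mz
    chosen: list[int] = []
    unmatched: list[float] = []
    for t in mz_targets:
        delta = np.abs(mz - t)
        tol = tolerance_da if tolerance_da is not None else t * tolerance_ppm * 1e-6
        ok = np.flatnonzero(delta <= tol)
        if ok.size == 0:
            unmatched.append(t)
            continue
        best = delta[ok].min()
        cands = ok[delta[ok] == best]
        chosen.append(int(cands[np.argmin(mz[cands])]))  # tie -> lower m/z
    if unmatched:
        warnings.warn(f"no feature within tolerance of target(s): {unmatched}", stacklevel=2)
    cols = sorted(set(chosen))
    sub = matrix.intensities.iloc[:, cols]
    return MetaboliteMatrix(
        intensities=sub, groups=matrix.groups, treatment=matrix.treatment
    )
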