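"""Growth-curve normalization and between-treatment biomass contrasts.

Projected shoot area over days-after-sowing (das) is a proxy for
above-ground biomass.  Curves are normalized against the value on the
baseline day (the first imaging day, 34 das), making them dimensionless and
invariant to camera zoom; "biomass accumulation during the treatment" is
then the normalized final value minus one.  Treatment contrasts compare
mean accumulation between matched ecotype panels, e.g. the relative extra
accumulation under mild versus severe drought, or the yield penalty of a
drought treatment against the well-watered control, 1 − mean(a)/mean(b).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError, InsufficientDataError, NormalizationError

__all__ = [
    "normalize_series",
    "normalize_table",
    "accumulation",
    "relative_difference",
    "TreatmentContrast",
    "treatment_contrast",
    "ecotype_accumulation",
]


def normalize_series(values, das, baseline_das: int) -> np.ndarray:
    """Divide a feature series by its value on the baseline day.

    The baseline day must be present with a positive value; it maps to 1.0.
    Idempotent on already-normalized series.
    """
    values = np.asarray(values, dtype=float)
    das = np.asarray(das)
    hits = np.flatnonzero(das == baseline_das)
    if hits.size == 0:
        raise NormalizationError(f"baseline day {baseline_das} not in series")
    base = values[hits[0]]
    if not base > 0:
        raise NormalizationError(f"baseline value must be > 0, got {base}")
    return values / base


def normalize_table(
    df: pd.DataFrame,
    baseline_das: int,
    *,
    value_col: str = "area_side",
    by: str = "plant_id",
) -> pd.DataFrame:
    """Per-plant normalization of a tidy feature table.

    Adds a ``norm_<value_col>`` column; all other columns pass through.
    """
    def _norm(g: pd.DataFrame) -> pd.Series:
        return pd.Series(
            normalize_series(g[value_col].to_numpy(), g["das"].to_numpy(), baseline_das),
            index=g.index,
        )

    out = df.copy()
    parts = [
        _norm(g) for _, g in out.groupby(by, sort=False)
    ]
    out[f"norm_{value_col}"] = pd.concat(parts)
    return out


def accumulation(normalized, *, atol: float = 1e-9) -> float:
    """Normalized area gain over the treatment: final/baseline − 1.

    Expects a normalized series whose first element is the baseline (== 1);
    anything else violates the contract.  Negative values mean the plant
    shrank (e.g. through wilting or senescence-driven area loss).
    """
    arr = np.asarray(normalized, dtype=float)
    if arr.size == 0 or abs(arr[0] - 1.0) > atol:
        raise ContractError("accumulation expects a normalized series starting at 1.0")
    return float(arr[-1] - 1.0)


def relative_difference(a: float, b: float) -> float:
    """Relative difference (a − b)/b, e.g. extra accumulation of a over b."""
    if b == 0:
        raise ContractError("reference accumulation is zero")
    return (a - b) / b


def ecotype_accumulation(
    df: pd.DataFrame, baseline_das: int, *, value_col: str = "area_side"
) -> pd.Series:
    """Per-ecotype mean accumulation (mean over plants of per-plant gains)."""
    norm = normalize_table(df, baseline_das, value_col=value_col)
    col = f"norm_{value_col}"

    def _plant_gain(g: pd.DataFrame) -> float:
        g = g.sort_values("das")
        return accumulation(g[col].to_numpy())

    per_plant = norm.groupby(["ecotype", "plant_id"], sort=False).apply(
        _plant_gain, include_groups=False
    )
    return per_plant.groupby("ecotype").mean().rename("accumulation")


@dataclass
class TreatmentContrast:
    """Accumulation contrast between two matched ecotype panels."""

    mean_a: float
    mean_b: float
    per_ecotype_pct: pd.Series      # 100 * (a_i − b_i)/b_i
    mean_pct_difference: float      # 100 * (mean_a − mean_b)/mean_b
    penalty_pct: float              # 100 * (1 − mean_a/mean_b)

    @property
    def pct_range(self) -> tuple[float, float]:
        return float(self.per_ecotype_pct.min()), float(self.per_ecotype_pct.max())


def treatment_contrast(
    group_a: pd.Series | pd.DataFrame,
    group_b: pd.Series | pd.DataFrame,
    *,
    baseline_das: int | None = None,
) -> TreatmentContrast:
    """Compare accumulation between two treatments over matched ecotypes.

    Inputs are per-ecotype accumulation Series (or tidy feature tables, in
    which case ``baseline_das`` is required and accumulations are computed
    first).  ``penalty_pct`` reads group b as the well-watered reference.
    """
    def _as_series(g):
        if isinstance(g, pd.DataFrame):
            if baseline_das is None:
                raise ContractError("baseline_das required for raw feature tables")
            return ecotype_accumulation(g, baseline_das)
        return g

    a = _as_series(group_a)
    b = _as_series(group_b)
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise InsufficientDataError("no common ecotypes between the two groups")
    a, b = a.loc[common], b.loc[common]
    mean_a, mean_b = float(a.mean()), float(b.mean())
    per = 100.0 * (a - b) / b
    return TreatmentContrast(
        mean_a=mean_a,
        mean_b=mean_b,
        per_ecotype_pct=per,
        mean_pct_difference=100.0 * (mean_a - mean_b) / mean_b,
        penalty_pct=100.0 * (1.0 - mean_a / mean_b),
    )
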