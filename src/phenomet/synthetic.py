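"""Seeded synthetic data with exact ground truth for the whole pipeline.

The study's raw tray images, plant weights and FIE-MS spectra are not
available, so every downstream operation is exercised against generated
stand-ins whose ground truth is known by construction:

* tray images — two-plant side views and four-plant top views with a
  saturated-blue separating panel, plant silhouettes drawn as unions of
  rectangles in reserved colors that provably satisfy exactly one intended
  color classifier, and optional 10–20 px background noise patches in a
  plant color to exercise the morphological filter;
* drought-screen tables — fresh/dry weight pairs constructed so the computed
  plant water content (PWC) has a prescribed per-ecotype mean, with ordinal
  wilting scores generated on a latent linear scale and rounded/clipped to
  the 1–6 visual scale, inducing a negative PWC–wilting association;
* metabolite matrices — log-normal ion intensities with multiplicative
  class effects on designated "pathway" features for three tolerance
  classes, including sub-50 m/z features to exercise the low-mass filter;
* growth tables — per-plant projected-shoot-area time courses whose
  treatment-level accumulation gains are generator parameters.

Realism is deliberately sacrificed for exact bookkeeping: silhouettes are
rectangles, not plants, because pixel-exact ground truth is what the tests
need.  All generators are deterministic given their spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ParameterError
from .metabolomics import MetaboliteMatrix

__all__ = [
    "PLANT_GREEN",
    "SENESCENT_YELLOW",
    "STRESS_GREY",
    "PANEL_BLUE",
    "BACKGROUND",
    "CLASS_COLORS",
    "PlantSpec",
    "SideViewSpec",
    "TopViewSpec",
    "ImageGroundTruth",
    "generate_side_view",
    "generate_top_view",
    "save_png",
    "ScreenSpec",
    "generate_screen_table",
    "MetabolomeSpec",
    "generate_metabolome",
    "DEFAULT_TREATMENT_GAINS",
    "generate_growth_table",
]

# Reserved colors.  Each plant color satisfies exactly its intended
# classifier (green -> top-view plant rule, yellow -> yellow rule, grey ->
# grey rule); panel and background fail all three.
PLANT_GREEN = (60, 120, 70)
SENESCENT_YELLOW = (150, 100, 40)
STRESS_GREY = (35, 40, 30)
PANEL_BLUE = (0, 0, 255)
BACKGROUND = (200, 210, 220)

CLASS_COLORS = {
    "plant_green": PLANT_GREEN,
    "yellow": SENESCENT_YELLOW,
    "grey": STRESS_GREY,
}


# ---------------------------------------------------------------------------
# tray images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantSpec:
    """One plant silhouette: target height (rows above the ROI baseline),
    exact pixel area, and the fraction of pixels drawn in a senescent color."""

    height_px: int = 120
    area_px: int = 800
    senescent_fraction: float = 0.0
    senescent_class: str = "yellow"  # "yellow" or "grey"

    def validate(self):
        if self.area_px == 0:
            return
        if self.height_px < 1 or self.area_px < self.height_px:
            raise ParameterError(
                f"need area_px >= height_px >= 1, got {self.area_px}, {self.height_px}"
            )
        if not 0 <= self.senescent_fraction <= 1:
            raise ParameterError("senescent_fraction must be in [0, 1]")
        if self.senescent_class not in ("yellow", "grey"):
            raise ParameterError(f"unknown senescent class {self.senescent_class!r}")


@dataclass(frozen=True)
class SideViewSpec:
    """Two plants flanking a full-height vertical panel."""

    width: int = 640
    height: int = 480
    panel_x: int = 320          # panel center column
    panel_halfwidth: int = 2
    roi_row_top: int = 10
    roi_bottom_row: int = 460   # baseline just above the pot, inclusive
    plants: tuple[PlantSpec, PlantSpec] = (PlantSpec(), PlantSpec())
    n_noise_patches: int = 0
    seed: int = 0


@dataclass(frozen=True)
class TopViewSpec:
    """Four plants in quadrants separated by a panel cross.

    Top-view plants are drawn in plant-green only (the top-view extractor
    uses the plant rule alone, so senescent colors would not count there).
    """

    width: int = 640
    height: int = 640
    panel_x: int = 320
    panel_y: int = 320
    panel_halfwidth: int = 2
    areas_px: tuple[int, int, int, int] = (300, 300, 300, 300)
    n_noise_patches: int = 0
    seed: int = 0


@dataclass
class ImageGroundTruth:
    """Exact per-plant bookkeeping for a generated tray image."""

    plant_masks: list[np.ndarray]
    heights_px: list[int]
    class_counts: list[dict[str, int]]
    panel_x: int
    panel_y: int | None = None

    def to_json_dict(self) -> dict:
        """JSON-serializable sidecar (masks summarized as areas)."""
        return {
            "panel_x": self.panel_x,
            "panel_y": self.panel_y,
            "heights_px": list(self.heights_px),
            "areas_px": [int(m.sum()) for m in self.plant_masks],
            "class_counts": self.class_counts,
        }


def _blank(width: int, height: int) -> np.ndarray:
    img = np.empty((height, width, 3), dtype=np.uint8)
    img[:] = BACKGROUND
    return img


def _rect_mask_exact(
    shape: tuple[int, int], bottom_row: int, col_start: int, n_rows: int, area: int
) -> np.ndarray:
    """Bottom-anchored silhouette of exactly ``area`` pixels: full columns of
    ``n_rows`` plus one shorter column for the remainder, so the topmost
    pixel sits exactly ``n_rows`` rows above (and including) the baseline."""
    mask = np.zeros(shape, dtype=bool)
    if area == 0:
        return mask
    n_full, rem = divmod(area, n_rows)
    top = bottom_row - n_rows + 1
    mask[top : bottom_row + 1, col_start : col_start + n_full] = True
    if rem:
        mask[bottom_row - rem + 1 : bottom_row + 1, col_start + n_full] = True
    return mask


def _paint_plant(
    img: np.ndarray, mask: np.ndarray, plant: PlantSpec, rng: np.random.Generator
) -> dict[str, int]:
    """Color mask pixels, assigning a seeded random subset to the senescent
    class; returns exact class counts."""
    area = int(mask.sum())
    counts = {"plant_green": area, "yellow": 0, "grey": 0}
    ys, xs = np.nonzero(mask)
    img[ys, xs] = PLANT_GREEN
    k = int(round(plant.senescent_fraction * area))
    if k > 0:
        pick = rng.choice(area, size=k, replace=False)
        img[ys[pick], xs[pick]] = CLASS_COLORS[plant.senescent_class]
        counts["plant_green"] = area - k
        counts[plant.senescent_class] = k
    return counts


def _add_noise_patches(
    img: np.ndarray,
    occupied: np.ndarray,
    n_patches: int,
    rng: np.random.Generator,
    row_range: tuple[int, int],
    col_ranges: Sequence[tuple[int, int]],
) -> None:
    """Scatter 8-connected plant-green patches of 10–20 px in background
    regions, never touching (or diagonally adjacent to) occupied pixels."""
    h, w = occupied.shape
    placed = 0
    for _ in range(200 * max(n_patches, 1)):
        if placed == n_patches:
            break
        area = int(rng.integers(10, 21))
        pw = 2
        ph = (area + 1) // 2
        cr = col_ranges[int(rng.integers(len(col_ranges)))]
        r0_lo, r0_hi = row_range[0], row_range[1] - ph
        c0_lo, c0_hi = cr[0], cr[1] - pw
        if r0_hi <= r0_lo or c0_hi <= c0_lo:
            continue
        r0 = int(rng.integers(r0_lo, r0_hi))
        c0 = int(rng.integers(c0_lo, c0_hi))
        # 1-px guard band keeps patches 8-disconnected from everything else
        g0, g1 = max(r0 - 1, 0), min(r0 + ph + 1, h)
        g2, g3 = max(c0 - 1, 0), min(c0 + pw + 1, w)
        if occupied[g0:g1, g2:g3].any():
            continue
        patch = np.zeros((ph, pw), dtype=bool)
        patch[:] = True
        if 2 * ph > area:  # odd area: clip one corner, connectivity preserved
            patch[-1, -1] = False
        img[r0 : r0 + ph, c0 : c0 + pw][patch] = PLANT_GREEN
        occupied[r0 : r0 + ph, c0 : c0 + pw][patch] = True
        placed += 1
    if placed < n_patches:
        raise ParameterError("could not place all noise patches without overlap")


def generate_side_view(spec: SideViewSpec) -> tuple[np.ndarray, ImageGroundTruth]:
    """Render a two-plant side-view tray image plus exact ground truth."""
    for p in spec.plants:
        p.validate()
    if not (0 <= spec.roi_row_top <= spec.roi_bottom_row < spec.height):
        raise ParameterError("ROI rows out of image bounds")
    rng = np.random.default_rng(spec.seed)
    img = _blank(spec.width, spec.height)
    hw = spec.panel_halfwidth
    p0, p1 = spec.panel_x - hw, spec.panel_x + hw + 1
    if p0 <= 0 or p1 >= spec.width:
        raise ParameterError("panel out of image bounds")
    img[:, p0:p1] = PANEL_BLUE

    margin = 4
    regions = [(margin, p0 - margin), (p1 + margin, spec.width - margin)]
    occupied = np.zeros((spec.height, spec.width), dtype=bool)
    occupied[:, p0:p1] = True

    masks, heights, counts = [], [], []
    for plant, (c0, c1) in zip(spec.plants, regions):
        if plant.area_px == 0:
            mask = np.zeros((spec.height, spec.width), dtype=bool)
            masks.append(mask)
            heights.append(0)
            counts.append({"plant_green": 0, "yellow": 0, "grey": 0})
            continue
        n_rows = plant.height_px
        if spec.roi_bottom_row - n_rows + 1 < spec.roi_row_top:
            raise ParameterError(f"plant height {n_rows} exceeds ROI rows")
        n_cols = -(-plant.area_px // n_rows)  # ceil
        if n_cols > c1 - c0:
            raise ParameterError(f"plant area {plant.area_px} too wide for its region")
        start = c0 + (c1 - c0 - n_cols) // 2
        mask = _rect_mask_exact(
            occupied.shape, spec.roi_bottom_row, start, n_rows, plant.area_px
        )
        counts.append(_paint_plant(img, mask, plant, rng))
        masks.append(mask)
        heights.append(n_rows)
        occupied |= mask

    if spec.n_noise_patches:
        _add_noise_patches(
            img, occupied, spec.n_noise_patches, rng,
            row_range=(spec.roi_row_top, spec.roi_bottom_row + 1),
            col_ranges=regions,
        )
    gt = ImageGroundTruth(masks, heights, counts, panel_x=spec.panel_x)
    return img, gt


def generate_top_view(spec: TopViewSpec) -> tuple[np.ndarray, ImageGroundTruth]:
    """Render a four-plant top-view tray image plus exact ground truth.

    Quadrant order matches the extractor: top-left, top-right, bottom-left,
    bottom-right.
    """
    rng = np.random.default_rng(spec.seed)
    img = _blank(spec.width, spec.height)
    hw = spec.panel_halfwidth
    c0p, c1p = spec.panel_x - hw, spec.panel_x + hw + 1
    r0p, r1p = spec.panel_y - hw, spec.panel_y + hw + 1
    if c0p <= 0 or c1p >= spec.width or r0p <= 0 or r1p >= spec.height:
        raise ParameterError("panel cross out of image bounds")
    img[:, c0p:c1p] = PANEL_BLUE
    img[r0p:r1p, :] = PANEL_BLUE

    margin = 4
    quads = [
        (margin, r0p - margin, margin, c0p - margin),
        (margin, r0p - margin, c1p + margin, spec.width - margin),
        (r1p + margin, spec.height - margin, margin, c0p - margin),
        (r1p + margin, spec.height - margin, c1p + margin, spec.width - margin),
    ]
    occupied = np.zeros((spec.height, spec.width), dtype=bool)
    occupied[:, c0p:c1p] = True
    occupied[r0p:r1p, :] = True

    masks, counts = [], []
    for area, (r0, r1, c0, c1) in zip(spec.areas_px, quads):
        if area == 0:
            masks.append(np.zeros_like(occupied))
            counts.append({"plant_green": 0, "yellow": 0, "grey": 0})
            continue
        avail_rows, avail_cols = r1 - r0, c1 - c0
        n_rows = min(max(1, int(np.ceil(np.sqrt(area)))), avail_rows)
        n_cols = -(-area // n_rows)
        if n_cols > avail_cols:
            raise ParameterError(f"plant area {area} does not fit its quadrant")
        bottom = r0 + (avail_rows + n_rows) // 2 - 1
        start = c0 + (avail_cols - n_cols) // 2
        mask = _rect_mask_exact(occupied.shape, bottom, start, n_rows, area)
        ys, xs = np.nonzero(mask)
        img[ys, xs] = PLANT_GREEN
        masks.append(mask)
        counts.append({"plant_green": int(area), "yellow": 0, "grey": 0})
        occupied |= mask

    if spec.n_noise_patches:
        _add_noise_patches(
            img, occupied, spec.n_noise_patches, rng,
            row_range=(margin, spec.height - margin),
            col_ranges=[(margin, c0p - margin), (c1p + margin, spec.width - margin)],
        )
    gt = ImageGroundTruth(
        masks, heights_px=[0, 0, 0, 0], class_counts=counts,
        panel_x=spec.panel_x, panel_y=spec.panel_y,
    )
    return img, gt


def save_png(image: np.ndarray, path) -> None:
    """Lossless PNG export (JPEG is forbidden: the classifiers are exact
    inequalities and compression artifacts would flip them)."""
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path, format="PNG")


# ---------------------------------------------------------------------------
# drought-screen tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenSpec:
    """Replicate-level drought screen with known PWC structure.

    Wilting is generated on a latent linear scale,
    ``1 + wilting_slope * (100 − PWC) + ε``, then rounded and clipped to the
    ordinal 1–6 visual scale, so higher water content maps to less wilting.
    """

    n_ecotypes: int = 48
    replicates: int = 6
    pwc_means: tuple[float, ...] | None = None  # default: linspace(30, 80)
    pwc_sd: float = 5.0
    wilting_slope: float = 0.07
    wilting_noise_sd: float = 0.5
    seed: int = 0

    def resolved_means(self) -> np.ndarray:
        if self.pwc_means is not None:
            means = np.asarray(self.pwc_means, dtype=float)
            if len(means) != self.n_ecotypes:
                raise ParameterError("pwc_means length must equal n_ecotypes")
        else:
            means = np.linspace(30.0, 80.0, self.n_ecotypes)
        if means.min() < 0 or means.max() > 100:
            raise ParameterError("pwc_means must lie in [0, 100]")
        return means

    def validate(self):
        if self.replicates < 2:
            raise ParameterError("need at least 2 replicates")
        self.resolved_means()

    @classmethod
    def for_correlation(
        cls,
        rho: float,
        *,
        n_ecotypes: int = 48,
        replicates: int = 6,
        pwc_sd: float = 5.0,
        wilting_slope: float = 0.07,
        seed: int = 0,
    ) -> "ScreenSpec":
        """Spec whose latent ecotype-level PWC–wilting correlation is ``rho``.

        With slope b, m replicates and ecotype-mean PWC variance
        sigma_u^2 = Var(means) + pwc_sd^2/m, the latent correlation is
        -b*sigma_u / sqrt(b^2*sigma_u^2 + sigma_eps^2/m); this solves for the
        per-replicate noise SD sigma_eps.  Rounding/clipping to the 1–6 scale
        attenuates the realized correlation slightly.
        """
        if not -1 < rho < 0:
            raise ParameterError("rho must be in (-1, 0): wilting falls as PWC rises")
        means = np.linspace(30.0, 80.0, n_ecotypes)
        var_u = means.var() + pwc_sd**2 / replicates
        a = abs(rho)
        sigma_eps = wilting_slope * np.sqrt(var_u * replicates * (1 / a**2 - 1))
        return cls(
            n_ecotypes=n_ecotypes, replicates=replicates, pwc_sd=pwc_sd,
            wilting_slope=wilting_slope, wilting_noise_sd=float(sigma_eps), seed=seed,
        )


def generate_screen_table(spec: ScreenSpec) -> pd.DataFrame:
    """Replicate-level screen table: ecotype, replicate, FW, DW, wilting.

    Dry weights are drawn in the 0.18–0.32 g range typical of well-watered
    grass shoots at harvest; fresh weight is back-computed as
    FW = DW / (1 − PWC/100) so the computed PWC is exact by construction.
    """
    spec.validate()
    means = spec.resolved_means()
    rng = np.random.default_rng(spec.seed)
    m = spec.replicates
    rows = []
    width = len(str(spec.n_ecotypes))
    for i, mu in enumerate(means):
        pwc = np.clip(rng.normal(mu, spec.pwc_sd, size=m), 1.0, 99.0)
        dw = rng.uniform(0.18, 0.32, size=m)
        fw = dw / (1 - pwc / 100.0)
        latent = 1.0 + spec.wilting_slope * (100.0 - pwc)
        latent = latent + rng.normal(0.0, spec.wilting_noise_sd, size=m)
        wilt = np.clip(np.rint(latent), 1, 6).astype(int)
        for j in range(m):
            rows.append((f"E{i + 1:0{width}d}", j + 1, fw[j], dw[j], wilt[j]))
    return pd.DataFrame(rows, columns=["ecotype", "replicate", "FW", "DW", "wilting"])


# ---------------------------------------------------------------------------
# metabolite matrices
# ---------------------------------------------------------------------------

TOLERANCE_CLASSES = ("TOL", "INT", "SUS")


@dataclass(frozen=True)
class MetabolomeSpec:
    """Log-normal ion-intensity matrix with class effects on chosen features.

    ``effect_features`` index into the in-range (m/z >= mz_range[0]) feature
    block so the low-mass filter never removes a planted effect;
    ``fold_changes`` gives the multiplicative effect per tolerance class.
    """

    n_features: int = 120
    mz_range: tuple[float, float] = (50.0, 1200.0)
    n_below_min: int = 10
    below_min_range: tuple[float, float] = (15.0, 50.0)
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"TOL": 3, "INT": 3, "SUS": 3}
    )
    effect_features: tuple[int, ...] = ()
    fold_changes: Mapping[str, float] = field(
        default_factory=lambda: {"TOL": 1.0, "INT": 1.0, "SUS": 1.0}
    )
    effect_pattern: str = "shared"  # "shared" or "blocks"
    noise_sigma: float = 0.1
    seed: int = 0

    def validate(self):
        if any(fc <= 0 for fc in self.fold_changes.values()):
            raise ParameterError("fold_changes must be > 0")
        if any(not 0 <= i < self.n_features for i in self.effect_features):
            raise ParameterError("effect_features out of range")
        if any(g not in TOLERANCE_CLASSES for g in self.group_sizes):
            raise ParameterError(f"group labels must be among {TOLERANCE_CLASSES}")
        if self.effect_pattern not in ("shared", "blocks"):
            raise ParameterError("effect_pattern must be 'shared' or 'blocks'")

    @classmethod
    def severe_drought(cls, seed: int = 0, fold: float = 8.0, noise_sigma: float = 0.1):
        """Strong class responses on a third of the features.

        Uses the "blocks" pattern: each responding class elevates its own
        block of pathway features, giving the classes distinct metabolite
        signatures (as observed for real tolerance groups) rather than
        positions along a single axis — a purely graded shared effect would
        leave the intermediate class at the profile centroid, where
        correlation distance is blind to it.
        """
        return cls(
            effect_features=tuple(range(40)),
            fold_changes={"TOL": fold, "INT": fold, "SUS": 1.0},
            effect_pattern="blocks",
            noise_sigma=noise_sigma, seed=seed,
        )

    @classmethod
    def control(cls, seed: int = 0, noise_sigma: float = 0.1):
        """Matched no-effect regime (all fold changes 1)."""
        return cls(
            effect_features=tuple(range(40)),
            fold_changes={"TOL": 1.0, "INT": 1.0, "SUS": 1.0},
            effect_pattern="blocks",
            noise_sigma=noise_sigma, seed=seed,
        )


def generate_metabolome(spec: MetabolomeSpec) -> MetaboliteMatrix:
    """Samples x m/z intensity matrix with known class structure."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.mz_range
    mz_main = np.sort(rng.uniform(lo, hi, size=spec.n_features))
    blo, bhi = spec.below_min_range
    mz_low = np.sort(rng.uniform(blo, bhi, size=spec.n_below_min))
    mz = np.concatenate([mz_low, mz_main])

    labels, sample_ids = [], []
    for cls_name in TOLERANCE_CLASSES:
        n = int(spec.group_sizes.get(cls_name, 0))
        for k in range(n):
            labels.append(cls_name)
            sample_ids.append(f"{cls_name}{k + 1}")
    n_samples = len(sample_ids)
    if n_samples == 0:
        raise ParameterError("group_sizes defines no samples")

    n_total = spec.n_below_min + spec.n_features
    base_logmean = rng.uniform(np.log(1e3), np.log(1e6), size=n_total)
    log_i = base_logmean + rng.normal(0.0, spec.noise_sigma, size=(n_samples, n_total))
    intens = np.exp(log_i)

    effect_cols = spec.n_below_min + np.asarray(spec.effect_features, dtype=int)
    if spec.effect_pattern == "shared" or effect_cols.size == 0:
        class_cols = {c: effect_cols for c in TOLERANCE_CLASSES}
    else:  # "blocks": responding classes get disjoint equal feature blocks
        responders = [c for c in TOLERANCE_CLASSES
                      if float(spec.fold_changes.get(c, 1.0)) != 1.0]
        class_cols = {c: np.array([], dtype=int) for c in TOLERANCE_CLASSES}
        if responders:
            for blk, c in zip(np.array_split(effect_cols, len(responders)), responders):
                class_cols[c] = blk
    for s, cls_name in enumerate(labels):
        fc = float(spec.fold_changes.get(cls_name, 1.0))
        cols = class_cols[cls_name]
        if cols.size and fc != 1.0:
            intens[s, cols] *= fc

    df = pd.DataFrame(intens, index=pd.Index(sample_ids, name="sample"), columns=mz)
    groups = pd.Series(labels, index=df.index, name="group")
    return MetaboliteMatrix(intensities=df, groups=groups)


# ---------------------------------------------------------------------------
# growth time courses
# ---------------------------------------------------------------------------

# Mean normalized-area gain over the 12-day treatment window per soil water
# content treatment (% of field capacity).  Control 0.60; mild drought set so
# the mild-vs-control yield penalty is 38%; severe set so mild accumulates
# 85% more than severe — the study conditions the contrasts must recover.
DEFAULT_TREATMENT_GAINS: dict[int, float] = {75: 0.60, 15: 0.372, 0: 0.201}


def generate_growth_table(
    n_ecotypes: int = 9,
    *,
    treatment_gains: Mapping[int, float] = None,
    n_plants: int = 4,
    das: Sequence[int] = tuple(range(34, 46)),
    baseline_area: float = 500.0,
    gain_cv: float = 0.05,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy projected-shoot-area time courses.

    Each ecotype x treatment gets a gain drawn around the treatment mean
    (relative SD ``gain_cv``); each plant gets its own baseline size factor
    (accumulation is invariant to it); multiplicative day-to-day noise has
    relative SD ``noise_sd``.  Columns: plant_id, ecotype, treatment, das,
    area_side.
    """
    gains = dict(DEFAULT_TREATMENT_GAINS if treatment_gains is None else treatment_gains)
    if any(g <= -1 for g in gains.values()):
        raise ParameterError("treatment gains must be > -1 (area cannot go negative)")
    rng = np.random.default_rng(seed)
    das = np.asarray(list(das), dtype=int)
    span = das[-1] - das[0]
    rows = []
    for e in range(n_ecotypes):
        eco = f"eco{e + 1:02d}"
        for trt, g in gains.items():
            g_e = g * max(0.05, 1.0 + rng.normal(0.0, gain_cv))
            for p in range(n_plants):
                size = rng.uniform(0.8, 1.2) * baseline_area
                frac = (das - das[0]) / span
                area = size * (1.0 + g_e * frac)
                area = area * (1.0 + rng.normal(0.0, noise_sd, size=len(das)))
                for d, a in zip(das, area):
                    rows.append((f"{eco}_t{trt}_p{p + 1}", eco, trt, int(d), float(a)))
    return pd.DataFrame(rows, columns=["plant_id", "ecotype", "treatment", "das", "area_side"])


# ---------------------------------------------------------------------------
# linked phenotype / metabolite blocks
# ---------------------------------------------------------------------------

def generate_correlated_blocks(
    n_rows: int = 9,
    *,
    n_pos: int = 3,
    n_neg: int = 2,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Per-ecotype phenotype and metabolite blocks with known sign structure.

    A latent per-ecotype drought-tolerance score drives biomass features
    (area_side, area_top, height) up and stress features (yellow, grey)
    down; ``n_pos`` metabolites follow the score positively and ``n_neg``
    negatively, each with relative noise ``noise_sd``.  Returns
    (phenotypes, metabolites, expected_sign) where ``expected_sign`` gives
    the generative sign of each metabolite's association with biomass.
    """
    rng = np.random.default_rng(seed)
    t = rng.uniform(-1.0, 1.0, size=n_rows)
    z = (t - t.mean()) / t.std()
    idx = pd.Index([f"eco{i + 1:02d}" for i in range(n_rows)], name="ecotype")

    def noisy(scale_base, coef):
        return scale_base + coef * z + abs(coef) * noise_sd * rng.normal(size=n_rows)

    pheno = pd.DataFrame(
        {
            "area_side": noisy(1200.0, 300.0),
            "area_top": noisy(900.0, 200.0),
            "height": noisy(160.0, 40.0),
            "yellow": np.maximum(noisy(250.0, -120.0), 0.0),
            "grey": np.maximum(noisy(180.0, -80.0), 0.0),
        },
        index=idx,
    )
    metab = {}
    signs = {}
    for k in range(n_pos):
        name = f"met_up_{k + 1}"
        metab[name] = z + noise_sd * rng.normal(size=n_rows)
        signs[name] = 1.0
    for k in range(n_neg):
        name = f"met_down_{k + 1}"
        metab[name] = -z + noise_sd * rng.normal(size=n_rows)
        signs[name] = -1.0
    return pheno, pd.DataFrame(metab, index=idx), pd.Series(signs, name="sign")
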