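"""Rule-based RGB plant segmentation and feature extraction for tray images.

Plants imaged against a uniform background, two per side view separated by a
vertical panel and four per top view separated by a panel cross, are
segmented with exact inequalities in 8-bit RGB space:

* *yellow* (senescent tissue): the red channel is at least 10 levels above
  the green channel;
* *grey* (stress-related discoloration): 1.15 < G/B < 2, G/R < 1.4 and
  G < 150;
* *top-view plant*: 20 < G < 200, 20 < R < 200, G − B > 12, R/G < 1.5 and
  G/B > 1.5.

The side-view plant rule is configurable and defaults to the union of the
three classes above, so senescent tissue counts toward projected shoot area.
Small background patches that pass the color rules (noise clustering around
10–20 pixels) are removed by an 8-connected component-area filter before
features — height, side/top projected area, yellow and grey pixel counts —
are measured per plant and written to CSV.

Coordinate convention: row 0 is the image top; heights are counted in rows;
the ROI bottom row is inclusive; all pixel counts are integers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from skimage import measure

from .errors import FormatError, LayoutError, PanelDetectionError, ParameterError

__all__ = [
    "DEFAULT_YELLOW_THRESHOLD",
    "DEFAULT_MAX_PATCH_AREA",
    "PreprocessConfig",
    "SideViewROI",
    "PlantFeatureRecord",
    "TrayLayout",
    "is_yellow",
    "is_grey",
    "is_top_plant",
    "is_panel",
    "side_plant_rule",
    "preprocess",
    "detect_panel",
    "detect_panel_cross",
    "remove_small_patches",
    "segment_side_plant",
    "extract_height",
    "extract_features",
    "write_feature_csv",
    "read_feature_csv",
]

DEFAULT_YELLOW_THRESHOLD = 10
DEFAULT_MAX_PATCH_AREA = 20

FEATURE_COLUMNS = ["plant_id", "das", "height", "area_side", "area_top", "yellow", "grey"]


# ---------------------------------------------------------------------------
# pixel classifiers
# ---------------------------------------------------------------------------

def _channels(pixels) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Split an (..., 3) RGB array (or a single (r, g, b) triple) into float
    channel arrays.  Returns (r, g, b, scalar_input)."""
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.shape[-1] != 3:
        raise FormatError(f"expected RGB data with a trailing axis of 3, got shape {arr.shape}")
    scalar = arr.ndim == 1
    return arr[..., 0], arr[..., 1], arr[..., 2], scalar


def _maybe_item(mask: np.ndarray, scalar: bool):
    return bool(mask.item()) if scalar else mask


def is_yellow(pixels, threshold: int = DEFAULT_YELLOW_THRESHOLD):
    """Senescent-yellow rule: V_Red − V_Green ≥ ``threshold`` (default 10).

    Accepts a single ``(r, g, b)`` triple or any array with a trailing RGB
    axis; returns a bool or boolean array accordingly.
    """
    r, g, _, scalar = _channels(pixels)
    return _maybe_item(r - g >= threshold, scalar)


def is_grey(pixels):
    """Grey discoloration rule: 1.15 < G/B < 2 and G/R < 1.4 and G < 150.

    Zero-valued red or blue channels make a ratio undefined; such pixels are
    classified as not grey.
    """
    r, g, b, scalar = _channels(pixels)
    valid = (b > 0) & (r > 0)
    gb = np.divide(g, b, out=np.zeros_like(g), where=valid)
    gr = np.divide(g, r, out=np.zeros_like(g), where=valid)
    out = valid & (gb < 2) & (gb > 1.15) & (gr < 1.4) & (g < 150)
    return _maybe_item(out, scalar)


def is_top_plant(pixels):
    """Top-view plant rule: 20 < G < 200, 20 < R < 200, G − B > 12,
    R/G < 1.5 and G/B > 1.5.

    A zero blue channel is treated as ratio +inf, so G/B > 1.5 passes
    whenever G > 0 (the G > 20 term already excludes black pixels).
    """
    r, g, b, scalar = _channels(pixels)
    with np.errstate(divide="ignore", invalid="ignore"):
        rg = np.where(g > 0, r / np.where(g > 0, g, 1.0), np.inf)
        gb = np.where(b > 0, g / np.where(b > 0, b, 1.0), np.inf)
    out = (
        (g < 200) & (g > 20) & (r > 20) & (r < 200)
        & ((g - b) > 12) & (rg < 1.5) & (gb > 1.5)
    )
    return _maybe_item(out, scalar)


def is_panel(pixels):
    """Reserved panel color band: saturated blue (B ≥ 200, R ≤ 60, G ≤ 60).

    Chosen to fail all three plant classifiers so the separating panel can
    never be confused with plant tissue.
    """
    r, g, b, scalar = _channels(pixels)
    return _maybe_item((b >= 200) & (r <= 60) & (g <= 60), scalar)


def side_plant_rule(pixels, yellow_threshold: int = DEFAULT_YELLOW_THRESHOLD):
    """Default side-view plant rule: union of top-view plant, yellow and grey.

    Senescent (yellow/grey) tissue must count toward side area so that the
    color features are subsets of the plant mask.
    """
    return (
        is_top_plant(pixels)
        | is_yellow(pixels, threshold=yellow_threshold)
        | is_grey(pixels)
    )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

@dataclass
class PreprocessConfig:
    """Configurable stand-in for scene-dependent image normalization.

    enabled : master switch; when False :func:`preprocess` is the identity.
    white_balance : grey-world white balance (scale channels to a common mean).
    luminance_reference : per-channel background reference (r, g, b).  When
        set, the per-channel mode (the dominant background level) is shifted
        to the reference, correcting global luminance offsets.
    """

    enabled: bool = False
    white_balance: bool = False
    luminance_reference: tuple[int, int, int] | None = None


def _check_rgb_image(image) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise FormatError(f"expected an H x W x 3 RGB image, got shape {arr.shape}")
    return arr


def preprocess(image: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Optional white balance and luminance correction; identity when disabled."""
    arr = _check_rgb_image(image)
    if config is None or not config.enabled:
        return arr
    out = arr.astype(np.float64)
    if config.luminance_reference is not None:
        ref = np.asarray(config.luminance_reference, dtype=np.float64)
        for c in range(3):
            counts = np.bincount(arr[..., c].astype(np.int64).ravel(), minlength=256)
            mode = float(np.argmax(counts))
            out[..., c] -= mode - ref[c]
    if config.white_balance:
        means = out.reshape(-1, 3).mean(axis=0)
        grand = means.mean()
        scale = np.divide(grand, means, out=np.ones(3), where=means > 0)
        out *= scale
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# panel detection and ROIs
# ---------------------------------------------------------------------------

def _runs_of_true(flags: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous [start, stop) runs of True in a 1-D boolean array."""
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    return list(zip(starts.tolist(), stops.tolist()))


def _panel_run(panel_mask: np.ndarray, axis: int, min_fraction: float) -> tuple[int, int] | None:
    """Maximal run of panel-dominated lines along ``axis`` (0 = rows scanned
    per column, giving column indices)."""
    counts = panel_mask.sum(axis=axis)
    extent = panel_mask.shape[axis]
    flags = counts >= min_fraction * extent
    runs = _runs_of_true(flags)
    if not runs:
        return None
    return max(runs, key=lambda r: r[1] - r[0])


def detect_panel(
    image: np.ndarray,
    *,
    min_fraction: float = 0.5,
    fallback: int | None = None,
) -> int:
    """Locate the vertical separating panel in a side-view image.

    Returns the center column of the maximal run of panel-colored columns
    (a column qualifies when at least ``min_fraction`` of its pixels match
    the panel color).  Falls back to the configured column, with a warning,
    when no panel is found.
    """
    arr = _check_rgb_image(image)
    run = _panel_run(is_panel(arr), axis=0, min_fraction=min_fraction)
    if run is None:
        if fallback is not None:
            warnings.warn("no panel detected; using configured fallback column", stacklevel=2)
            return int(fallback)
        raise PanelDetectionError("no panel found and no fallback configured")
    start, stop = run
    return (start + stop - 1) // 2


def detect_panel_cross(
    image: np.ndarray,
    *,
    min_fraction: float = 0.5,
    fallback: tuple[int, int] | None = None,
) -> tuple[int, int]:
    """Locate the panel cross (vertical column, horizontal row) in a top view."""
    arr = _check_rgb_image(image)
    mask = is_panel(arr)
    col_run = _panel_run(mask, axis=0, min_fraction=min_fraction)
    row_run = _panel_run(mask, axis=1, min_fraction=min_fraction)
    if col_run is None or row_run is None:
        if fallback is not None:
            warnings.warn("no panel cross detected; using configured fallback", stacklevel=2)
            return int(fallback[0]), int(fallback[1])
        raise PanelDetectionError("no panel cross found and no fallback configured")
    col = (col_run[0] + col_run[1] - 1) // 2
    row = (row_run[0] + row_run[1] - 1) // 2
    return col, row


@dataclass(frozen=True)
class SideViewROI:
    """Single-plant region of a side-view image.

    Columns span [col_left, col_right); rows span [row_top, bottom_row]
    with ``bottom_row`` the fixed baseline just above the pot, from which
    plant height is measured.
    """

    col_left: int
    col_right: int
    row_top: int
    bottom_row: int

    def __post_init__(self):
        if self.col_right <= self.col_left or self.bottom_row < self.row_top:
            raise ParameterError(f"empty ROI: {self}")

    @property
    def n_rows(self) -> int:
        return self.bottom_row - self.row_top + 1

    @property
    def n_cols(self) -> int:
        return self.col_right - self.col_left

    def crop(self, image: np.ndarray) -> np.ndarray:
        arr = _check_rgb_image(image)
        if self.bottom_row >= arr.shape[0] or self.col_right > arr.shape[1]:
            raise ParameterError("ROI exceeds image bounds")
        return arr[self.row_top : self.bottom_row + 1, self.col_left : self.col_right]


# ---------------------------------------------------------------------------
# segmentation and per-plant features
# ---------------------------------------------------------------------------

def remove_small_patches(mask: np.ndarray, max_area: int = DEFAULT_MAX_PATCH_AREA) -> np.ndarray:
    """Drop 8-connected components of area ≤ ``max_area`` pixels.

    Larger components are preserved pixel-for-pixel.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    labels, n = measure.label(mask, connectivity=2, return_num=True)
    if n == 0:
        return mask.copy()
    areas = np.bincount(labels.ravel())
    keep = areas > max_area
    keep[0] = False
    return keep[labels]


def segment_side_plant(
    image: np.ndarray,
    roi: SideViewROI,
    *,
    rule: Callable[[np.ndarray], np.ndarray] | None = None,
    max_patch_area: int = DEFAULT_MAX_PATCH_AREA,
) -> np.ndarray:
    """Segment one plant inside its side-view ROI.

    Returns an ROI-shaped boolean mask of pixels passing the side-view plant
    rule (default: top-view-plant OR yellow OR grey) after small-patch
    removal.
    """
    sub = roi.crop(image)
    rule = rule or side_plant_rule
    return remove_small_patches(rule(sub), max_area=max_patch_area)


def extract_height(mask: np.ndarray, roi: SideViewROI) -> int:
    """Plant height in rows, from the ROI baseline up to the topmost mask
    pixel (inclusive); 0 for an empty mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != roi.n_rows:
        raise ParameterError("mask rows do not match ROI rows")
    rows = np.flatnonzero(mask.any(axis=1))
    if rows.size == 0:
        return 0
    return roi.n_rows - int(rows[0])


@dataclass(frozen=True)
class PlantFeatureRecord:
    """Per-plant, per-day extracted features (all pixel counts)."""

    plant_id: str
    das: int
    height: int
    area_side: int
    area_top: int
    yellow: int
    grey: int


@dataclass
class TrayLayout:
    """How a tray's views map to individual plants.

    ``plant_ids`` are ordered [side-view-1 left, side-view-1 right,
    side-view-2 left, side-view-2 right]; top-view quadrants map to the same
    order as [top-left, top-right, bottom-left, bottom-right].
    """

    plant_ids: Sequence[str] = ("p1", "p2", "p3", "p4")
    das: int = 34
    roi_row_top: int = 0
    roi_bottom_row: int | None = None  # default: 2 rows above the image bottom
    panel_fallback: int | None = None
    panel_cross_fallback: tuple[int, int] | None = None
    max_patch_area: int = DEFAULT_MAX_PATCH_AREA
    yellow_threshold: int = DEFAULT_YELLOW_THRESHOLD
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)


def _side_rois(image: np.ndarray, layout: TrayLayout) -> tuple[SideViewROI, SideViewROI]:
    h, w = image.shape[:2]
    bottom = layout.roi_bottom_row if layout.roi_bottom_row is not None else h - 3
    center = detect_panel(image, fallback=layout.panel_fallback)
    # widen to the panel's own extent so panel pixels stay out of both ROIs
    mask = is_panel(image)
    run = _panel_run(mask, axis=0, min_fraction=0.5)
    if run is not None:
        left_edge, right_edge = run
    else:
        left_edge, right_edge = center, center + 1
    roi_l = SideViewROI(0, left_edge, layout.roi_row_top, bottom)
    roi_r = SideViewROI(right_edge, w, layout.roi_row_top, bottom)
    return roi_l, roi_r


def _top_quadrants(image: np.ndarray, layout: TrayLayout):
    h, w = image.shape[:2]
    col, row = detect_panel_cross(image, fallback=layout.panel_cross_fallback)
    mask = is_panel(image)
    col_run = _panel_run(mask, axis=0, min_fraction=0.5) or (col, col + 1)
    row_run = _panel_run(mask, axis=1, min_fraction=0.5) or (row, row + 1)
    c0, c1 = col_run
    r0, r1 = row_run
    return [
        image[0:r0, 0:c0],
        image[0:r0, c1:w],
        image[r1:h, 0:c0],
        image[r1:h, c1:w],
    ]


def extract_features(
    side_images: Iterable[np.ndarray],
    top_image: np.ndarray | None,
    layout: TrayLayout | None = None,
) -> list[PlantFeatureRecord]:
    """Extract height, side/top projected area and yellow/grey counts for
    every plant in one tray on one day.

    ``side_images`` holds one image per pair of plants (two plants flank the
    panel in each view); the optional ``top_image`` holds all four plants in
    quadrants separated by a panel cross.
    """
    layout = layout or TrayLayout()
    side_images = [_check_rgb_image(im) for im in side_images]
    n_plants = len(layout.plant_ids)
    if 2 * len(side_images) != n_plants:
        raise LayoutError(
            f"{len(side_images)} side view(s) cover {2 * len(side_images)} plants "
            f"but layout names {n_plants}"
        )

    heights: list[int] = []
    areas_side: list[int] = []
    yellows: list[int] = []
    greys: list[int] = []
    for im in side_images:
        im = preprocess(im, layout.preprocess)
        for roi in _side_rois(im, layout):
            mask = segment_side_plant(
                im, roi, max_patch_area=layout.max_patch_area,
                rule=lambda px: side_plant_rule(px, yellow_threshold=layout.yellow_threshold),
            )
            sub = roi.crop(im)
            heights.append(extract_height(mask, roi))
            areas_side.append(int(mask.sum()))
            yellows.append(int((is_yellow(sub, threshold=layout.yellow_threshold) & mask).sum()))
            greys.append(int((is_grey(sub) & mask).sum()))

    areas_top = [0] * n_plants
    if top_image is not None:
        top = preprocess(_check_rgb_image(top_image), layout.preprocess)
        quads = _top_quadrants(top, layout)
        if len(quads) != n_plants:
            raise LayoutError("top view quadrants do not match the number of plants")
        for i, quad in enumerate(quads):
            qmask = remove_small_patches(is_top_plant(quad), max_area=layout.max_patch_area)
            areas_top[i] = int(qmask.sum())

    return [
        PlantFeatureRecord(
            plant_id=str(pid), das=int(layout.das), height=heights[i],
            area_side=areas_side[i], area_top=areas_top[i],
            yellow=yellows[i], grey=greys[i],
        )
        for i, pid in enumerate(layout.plant_ids)
    ]


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def write_feature_csv(records: Iterable[PlantFeatureRecord], path) -> None:
    """Write feature records as CSV (integer counts, no decimal points)."""
    rows = [
        (r.plant_id, r.das, r.height, r.area_side, r.area_top, r.yellow, r.grey)
        for r in records
    ]
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    df.to_csv(Path(path), index=False)


def read_feature_csv(path) -> list[PlantFeatureRecord]:
    df = pd.read_csv(Path(path), dtype={"plant_id": str})
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"feature CSV missing columns: {sorted(missing)}")
    return [
        PlantFeatureRecord(
            plant_id=str(row.plant_id), das=int(row.das), height=int(row.height),
            area_side=int(row.area_side), area_top=int(row.area_top),
            yellow=int(row.yellow), grey=int(row.grey),
        )
        for row in df.itertuples()
    ]
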