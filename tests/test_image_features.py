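"""Color classifiers, segmentation geometry and feature extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenomet import image_features as feat
from phenomet import synthetic as syn
from phenomet.errors import (
    FormatError,
    LayoutError,
    PanelDetectionError,
    ParameterError,
)


# ---------------------------------------------------------------------------
# pixel classifiers: worked examples and oracle equivalence
# ---------------------------------------------------------------------------

def _oracle_yellow(r, g, b):
    return r - g >= 10


def _oracle_grey(r, g, b):
    if b == 0 or r == 0:
        return False
    return g / b < 2 and g / b > 1.15 and g / r < 1.4 and g < 150


def _oracle_top(r, g, b):
    gb = float("inf") if b == 0 else g / b
    if not (20 < g < 200 and 20 < r < 200):
        return False
    return (g - b) > 12 and r / g < 1.5 and gb > 1.5


@pytest.mark.parametrize(
    "pixel, expected",
    [
        ((120, 100, 50), True),
        ((100, 100, 100), False),
        ((109, 100, 0), False),   # one level below the threshold
        ((110, 100, 0), True),    # exactly 10 levels higher
    ],
)
def test_yellow_rule_examples(pixel, expected):
    assert feat.is_yellow(pixel) is expected


@pytest.mark.parametrize(
    "pixel, expected",
    [
        ((100, 130, 80), True),   # ratios 1.625 and 1.3, G < 150
        ((50, 160, 100), False),  # G over the 150 cap
        ((0, 0, 0), False),       # zero-channel guard
    ],
)
def test_grey_rule_examples(pixel, expected):
    assert feat.is_grey(pixel) is expected


@pytest.mark.parametrize(
    "pixel, expected",
    [
        ((60, 120, 70), True),
        ((210, 120, 70), False),   # red out of range
        ((60, 120, 110), False),   # green-blue gap too small
        ((30, 120, 0), True),      # zero blue reads as ratio +inf
    ],
)
def test_top_plant_rule_examples(pixel, expected):
    assert feat.is_top_plant(pixel) is expected


channel = st.integers(min_value=0, max_value=255)


@settings(max_examples=300, derandomize=True)
@given(r=channel, g=channel, b=channel)
def test_classifiers_match_independent_oracle(r, g, b):
    """The vectorized inequalities agree with a direct scalar evaluation."""
    assert feat.is_yellow((r, g, b)) == _oracle_yellow(r, g, b)
    assert feat.is_grey((r, g, b)) == _oracle_grey(r, g, b)
    assert feat.is_top_plant((r, g, b)) == _oracle_top(r, g, b)


def test_classifiers_vectorize_over_images(rng):
    img = rng.integers(0, 256, size=(20, 30, 3), dtype=np.uint8)
    for vec, oracle in [
        (feat.is_yellow, _oracle_yellow),
        (feat.is_grey, _oracle_grey),
        (feat.is_top_plant, _oracle_top),
    ]:
        got = vec(img)
        want = np.array(
            [[oracle(*img[i, j].tolist()) for j in range(30)] for i in range(20)]
        )
        np.testing.assert_array_equal(got, want)


def test_classifier_rejects_non_rgb():
    with pytest.raises(FormatError):
        feat.is_yellow(np.zeros((4, 4)))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def test_preprocess_disabled_is_identity(rng):
    img = rng.integers(0, 256, size=(10, 10, 3), dtype=np.uint8)
    out = feat.preprocess(img, feat.PreprocessConfig(enabled=False))
    np.testing.assert_array_equal(out, img)


def test_preprocess_constant_image_stays_constant():
    img = np.full((10, 10, 3), 90, dtype=np.uint8)
    cfg = feat.PreprocessConfig(enabled=True, white_balance=True,
                                luminance_reference=(90, 90, 90))
    out = feat.preprocess(img, cfg)
    assert len(np.unique(out.reshape(-1, 3), axis=0)) == 1


def test_luminance_correction_restores_classification_counts():
    """A +30 global luminance offset is undone to within 2% of plant pixels."""
    spec = syn.SideViewSpec(
        plants=(syn.PlantSpec(120, 800, 0.2), syn.PlantSpec(90, 500)), seed=3
    )
    img, _ = syn.generate_side_view(spec)
    shifted = np.clip(img.astype(int) + 30, 0, 255).astype(np.uint8)
    cfg = feat.PreprocessConfig(enabled=True, luminance_reference=syn.BACKGROUND)
    corrected = feat.preprocess(shifted, cfg)
    n_ref = int(feat.side_plant_rule(img).sum())
    n_cor = int(feat.side_plant_rule(corrected).sum())
    assert abs(n_cor - n_ref) <= 0.02 * n_ref


# ---------------------------------------------------------------------------
# panel detection
# ---------------------------------------------------------------------------

def test_detect_panel_center_matches_ground_truth(side_tray):
    spec, img, gt = side_tray
    assert abs(feat.detect_panel(img) - gt.panel_x) <= 1


def test_detect_panel_midpoint_of_run():
    img = np.full((50, 800, 3), syn.BACKGROUND, dtype=np.uint8)
    img[:, 398:403] = syn.PANEL_BLUE  # columns 398–402
    assert feat.detect_panel(img) == 400


def test_detect_panel_fallback_warns_and_error_without():
    img = np.full((50, 800, 3), syn.BACKGROUND, dtype=np.uint8)
    with pytest.warns(UserWarning):
        assert feat.detect_panel(img, fallback=512) == 512
    with pytest.raises(PanelDetectionError):
        feat.detect_panel(img)


def test_detect_panel_cross_matches_ground_truth(top_tray):
    spec, img, gt = top_tray
    col, row = feat.detect_panel_cross(img)
    assert (col, row) == (gt.panel_x, gt.panel_y)


# ---------------------------------------------------------------------------
# small-patch removal
# ---------------------------------------------------------------------------

def _blob(area):
    mask = np.zeros((50, 50), dtype=bool)
    ph = (area + 1) // 2
    mask[10 : 10 + ph, 10:12] = True
    if 2 * ph > area:
        mask[10 + ph - 1, 11] = False
    return mask


@pytest.mark.parametrize("area, survives", [(20, False), (21, True)])
def test_patch_area_boundary(area, survives):
    mask = _blob(area)
    out = feat.remove_small_patches(mask, max_area=20)
    if survives:
        np.testing.assert_array_equal(out, mask)
    else:
        assert not out.any()


def test_remove_small_patches_empty_mask():
    out = feat.remove_small_patches(np.zeros((5, 5), dtype=bool))
    assert not out.any()


def test_diagonal_pixels_count_as_one_component():
    mask = np.zeros((30, 30), dtype=bool)
    for i in range(12):  # 12-px diagonal: 8-connected single component
        mask[i, i] = True
    assert not feat.remove_small_patches(mask, max_area=20).any()


# ---------------------------------------------------------------------------
# segmentation, height and full extraction
# ---------------------------------------------------------------------------

def test_segment_exact_area_and_noise_removal():
    for n_noise in (0, 3):
        spec = syn.SideViewSpec(
            plants=(syn.PlantSpec(100, 500), syn.PlantSpec(80, 400)),
            n_noise_patches=n_noise, seed=21 + n_noise,
        )
        img, gt = syn.generate_side_view(spec)
        roi = feat.SideViewROI(0, gt.panel_x - 2, spec.roi_row_top, spec.roi_bottom_row)
        mask = feat.segment_side_plant(img, roi)
        assert int(mask.sum()) == 500


def test_segment_pure_background_is_empty():
    img = np.full((100, 100, 3), syn.BACKGROUND, dtype=np.uint8)
    roi = feat.SideViewROI(0, 100, 0, 99)
    assert feat.segment_side_plant(img, roi).sum() == 0


def test_empty_roi_rejected():
    with pytest.raises(ParameterError):
        feat.SideViewROI(10, 10, 0, 50)


def test_extract_height_cases():
    roi = feat.SideViewROI(0, 10, 0, 199)  # 200 rows
    mask = np.zeros((200, 10), dtype=bool)
    assert feat.extract_height(mask, roi) == 0
    mask[199, 5] = True  # single pixel on the baseline row
    assert feat.extract_height(mask, roi) == 1
    mask[80, 3] = True  # top 120 rows above the baseline (inclusive)
    assert feat.extract_height(mask, roi) == 120


def test_extract_features_matches_ground_truth(side_tray, top_tray):
    sspec, simg, sgt = side_tray
    tspec, timg, tgt = top_tray
    layout = feat.TrayLayout(
        plant_ids=("p1", "p2", "p3", "p4"), das=40,
        roi_row_top=sspec.roi_row_top, roi_bottom_row=sspec.roi_bottom_row,
    )
    records = feat.extract_features([simg, simg], timg, layout)
    for k, rec in enumerate(records):
        gt_idx = k % 2  # both side views show the same synthetic pair
        assert rec.area_side == int(sgt.plant_masks[gt_idx].sum())
        assert rec.height == sgt.heights_px[gt_idx]
        assert rec.yellow == sgt.class_counts[gt_idx]["yellow"]
        assert rec.grey == sgt.class_counts[gt_idx]["grey"]
        assert rec.area_top == int(tgt.plant_masks[k].sum())


def test_extract_features_empty_pots():
    spec = syn.SideViewSpec(
        plants=(syn.PlantSpec(area_px=0), syn.PlantSpec(area_px=0)), seed=5
    )
    img, _ = syn.generate_side_view(spec)
    layout = feat.TrayLayout(plant_ids=("a", "b"),
                             roi_row_top=spec.roi_row_top,
                             roi_bottom_row=spec.roi_bottom_row)
    recs = feat.extract_features([img], None, layout)
    assert all(r.height == r.area_side == r.yellow == r.grey == 0 for r in recs)


def test_mirror_invariance(side_tray):
    """Horizontally mirroring a side view leaves areas and heights unchanged."""
    spec, img, gt = side_tray
    layout = feat.TrayLayout(plant_ids=("a", "b"),
                             roi_row_top=spec.roi_row_top,
                             roi_bottom_row=spec.roi_bottom_row)
    fwd = feat.extract_features([img], None, layout)
    rev = feat.extract_features([img[:, ::-1]], None, layout)
    assert {(r.area_side, r.height) for r in fwd} == {(r.area_side, r.height) for r in rev}


def test_adding_plant_pixels_never_decreases_area(side_tray):
    spec, img, gt = side_tray
    roi = feat.SideViewROI(0, gt.panel_x - 2, spec.roi_row_top, spec.roi_bottom_row)
    base = int(feat.segment_side_plant(img, roi).sum())
    grown = img.copy()
    grown[30:80, 10:20] = syn.PLANT_GREEN  # new foliage away from the plant
    assert int(feat.segment_side_plant(grown, roi).sum()) >= base


def test_layout_mismatch_rejected(side_tray):
    _, img, _ = side_tray
    with pytest.raises(LayoutError):
        feat.extract_features([img], None, feat.TrayLayout(plant_ids=("a", "b", "c")))


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def test_feature_csv_round_trip(tmp_path, rng):
    records = [
        feat.PlantFeatureRecord(
            plant_id=f"p{i}", das=34 + i % 12, height=int(rng.integers(0, 300)),
            area_side=int(rng.integers(0, 5000)), area_top=int(rng.integers(0, 5000)),
            yellow=int(rng.integers(0, 500)), grey=int(rng.integers(0, 500)),
        )
        for i in range(100)
    ]
    path = tmp_path / "features.csv"
    feat.write_feature_csv(records, path)
    assert feat.read_feature_csv(path) == records
    body = path.read_text().splitlines()
    assert body[0] == "plant_id,das,height,area_side,area_top,yellow,grey"
    assert "." not in body[1]  # integer counts serialized without decimals


def test_feature_csv_empty_list(tmp_path):
    path = tmp_path / "empty.csv"
    feat.write_feature_csv([], path)
    assert path.read_text().strip() == "plant_id,das,height,area_side,area_top,yellow,grey"
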