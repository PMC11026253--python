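"""Pixel classification, exclusion rules, percent-fibrosis, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myotrace.fibrosis import (
    PixelClass,
    aggregate_patient,
    build_exclusion_mask,
    classify_pixels,
    percent_fibrosis,
    quantify_section,
)
from myotrace.synth import HistologyGroundTruth, generate_histology_image
from myotrace.synth.histology import LABELS, true_percent_fibrosis


def _solid(rgb, h=8, w=8):
    return np.tile(np.array(rgb, dtype=np.uint8), (h, w, 1))


def test_hue_decision_rule_on_known_pixels():
    assert classify_pixels(_solid((220, 30, 40)))[0, 0] == PixelClass.COLLAGEN
    assert classify_pixels(_solid((230, 200, 40)))[0, 0] == PixelClass.MYOCARDIUM
    assert classify_pixels(_solid((250, 250, 250)))[0, 0] == PixelClass.CANDIDATE_EXCLUDED


def test_non_rgb_input_rejected():
    with pytest.raises(ValueError, match="RGB"):
        classify_pixels(np.zeros((8, 8), dtype=np.uint8))


def test_percent_fibrosis_ratio():
    labels = np.full((40, 25), PixelClass.MYOCARDIUM, dtype=np.uint8)
    labels[:12, :25] = PixelClass.COLLAGEN  # 300 collagen vs 700 myocardium
    q = percent_fibrosis(labels)
    assert q.collagen_px == 300 and q.myocardium_px == 700
    assert q.percent_fibrosis == pytest.approx(30.0)
    labels[:] = PixelClass.MYOCARDIUM
    assert percent_fibrosis(labels).percent_fibrosis == 0.0


def test_partition_invariant_on_generated_images():
    for frac in (0.0, 0.159, 0.6):
        img, _ = generate_histology_image(
            HistologyGroundTruth(frac, 10, 0.05), 160, 160, seed=1)
        q = quantify_section(img)
        assert q.total_px == img.shape[0] * img.shape[1]


def test_endocardial_band_excluded_interior_retained():
    img, labels = generate_histology_image(
        HistologyGroundTruth(0.2, endocardium_band_px=10, gap_fraction=0.0),
        200, 200, seed=2)
    cls = classify_pixels(img)
    excluded, usable = build_exclusion_mask(cls)
    assert usable
    # the top band is collagen-coloured but must be excluded
    assert excluded[:8, :].mean() > 0.9
    # interior collagen speckle is retained
    interior_collagen = (cls == PixelClass.COLLAGEN) & ~excluded
    assert interior_collagen.sum() > 0
    q = percent_fibrosis(cls, excluded)
    assert q.percent_fibrosis == pytest.approx(20.0, abs=1.0)


def test_interior_gap_excluded():
    img, labels = generate_histology_image(
        HistologyGroundTruth(0.1, 0, gap_fraction=0.2), 200, 200, seed=3)
    cls = classify_pixels(img)
    gaps = labels == LABELS["gap"]
    assert gaps.sum() > 0
    excluded, usable = build_exclusion_mask(cls)
    assert usable
    assert (excluded[gaps]).mean() > 0.95


def test_blank_image_unusable():
    img = _solid((250, 250, 250), 64, 64)
    q = quantify_section(img)
    assert not q.usable
    assert np.isnan(q.percent_fibrosis)


def test_recovery_across_fractions():
    for frac in (0.0, 0.05, 0.159, 0.3, 0.6):
        img, labels = generate_histology_image(
            HistologyGroundTruth(frac, 10, 0.05), 256, 256, seed=4)
        truth_pct = true_percent_fibrosis(labels)
        assert truth_pct == pytest.approx(100 * frac, abs=0.5)
        q = quantify_section(img)
        assert q.percent_fibrosis == pytest.approx(truth_pct, abs=1.0)


def test_scale_invariance():
    img, _ = generate_histology_image(
        HistologyGroundTruth(0.25, 10, 0.05), 160, 160, seed=5)
    doubled = np.repeat(np.repeat(img, 2, axis=0), 2, axis=1)
    a = quantify_section(img).percent_fibrosis
    b = quantify_section(doubled).percent_fibrosis
    assert abs(a - b) < 0.5


def test_generator_determinism_and_errors():
    t = HistologyGroundTruth(0.2, 10, 0.05)
    a, la = generate_histology_image(t, 128, 128, seed=6)
    b, lb = generate_histology_image(t, 128, 128, seed=6)
    assert np.array_equal(a, b) and np.array_equal(la, lb)
    with pytest.raises(ValueError, match="collagen_fraction"):
        HistologyGroundTruth(collagen_fraction=1.2)
    with pytest.raises(ValueError, match="too small"):
        generate_histology_image(t, 64, 12, seed=0)


def test_aggregate_patient():
    assert aggregate_patient([20.0] * 30)["percent_fibrosis"] == pytest.approx(20.0)
    with pytest.warns(UserWarning, match="only 3"):
        agg = aggregate_patient([10.0, 20.0, 30.0])
    assert agg["percent_fibrosis"] == pytest.approx(20.0)
    with pytest.warns(UserWarning, match="no usable"):
        agg = aggregate_patient([])
    assert np.isnan(agg["percent_fibrosis"]) and agg["n_sections"] == 0


@settings(max_examples=15, deadline=None)
@given(frac=st.floats(0.0, 0.7), seed=st.integers(0, 10_000))
def test_partition_property(frac, seed):
    img, labels = generate_histology_image(
        HistologyGroundTruth(frac, 6, 0.05), 96, 96, seed=seed)
    cls = classify_pixels(img)
    # classified labels partition the image
    assert cls.size == np.sum(
        [(cls == c).sum() for c in (0, 1, 2)]
    )
    q = quantify_section(img)
    assert q.total_px == cls.size
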