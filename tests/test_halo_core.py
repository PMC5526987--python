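"""Thresholding arithmetic, segmentation and radius derivation."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from halokit import (
    IntensityField,
    ThresholdConfig,
    area_to_radius,
    compute_thresholds,
    detect_objects,
    measure_field,
    segment_region,
)
from halokit import synthgen as sg
from oracles import flood_fill_area


def make_field(array) -> IntensityField:
    return IntensityField(np.asarray(array, dtype=np.uint8), source_id="test")


# --- shorthand -------------------------------------------------------------

@pytest.mark.parametrize(
    "text,rn,mode,value",
    [
        ("x55/15", 55, "absolute", 15),
        ("x75/x180", 75, "relative", 180),
        ("x55/x240", 55, "relative", 240),
    ],
)
def test_shorthand_parses_to_documented_config(text, rn, mode, value):
    cfg = ThresholdConfig.from_shorthand(text)
    assert (cfg.rn_offset_x, cfg.outer_mode, cfg.outer_value) == (rn, mode, value)
    assert cfg.shorthand() == text


@pytest.mark.parametrize("bad", ["x55x15", "55/15", "x55/", "x/15", "x55/15/2"])
def test_unparseable_shorthand_raises(bad):
    with pytest.raises(ValueError):
        ThresholdConfig.from_shorthand(bad)


@settings(derandomize=True, max_examples=200)
@given(
    rn=st.integers(1, 254),
    absolute=st.booleans(),
    value=st.integers(1, 254),
)
def test_shorthand_round_trips(rn, absolute, value):
    if not absolute and value <= rn:
        value = rn + 1
        if value > 254:
            rn, value = 253, 254
    cfg = ThresholdConfig(
        rn_offset_x=rn,
        outer_mode="absolute" if absolute else "relative",
        outer_value=value,
    )
    assert ThresholdConfig.from_shorthand(cfg.shorthand()) == cfg


def test_relative_outer_must_exceed_rn_offset():
    with pytest.raises(ValueError):
        ThresholdConfig(rn_offset_x=180, outer_mode="relative", outer_value=75)


# --- compute_thresholds ----------------------------------------------------

@pytest.mark.parametrize(
    "local_max,shorthand,expected",
    [
        (255, "x55/15", (200, 15)),
        (255, "x75/x180", (180, 75)),
        (150, "x75/x180", (75, None)),  # 150 - 180 < 1: outer unmeasurable
        (40, "x55/15", (None, 15)),  # 40 - 55 < 1: RN unmeasurable
    ],
)
def test_compute_thresholds_examples(local_max, shorthand, expected):
    cfg = ThresholdConfig.from_shorthand(shorthand)
    assert compute_thresholds(local_max, cfg) == expected


def test_local_max_out_of_range_rejected():
    cfg = ThresholdConfig.from_shorthand("x55/15")
    with pytest.raises(ValueError):
        compute_thresholds(256, cfg)


# --- area_to_radius --------------------------------------------------------

def test_area_to_radius_examples():
    assert area_to_radius(0) == 0
    assert area_to_radius(314) == pytest.approx(math.sqrt(314 / math.pi))
    with pytest.raises(ValueError):
        area_to_radius(-1)


def test_rasterized_disk_radius_recovered_within_half_pixel():
    size = 128
    rr, cc = np.mgrid[0:size, 0:size]
    dist = np.hypot(rr - 63.5, cc - 63.5)
    pixels = np.where(dist <= 50.0, 255, 0).astype(np.uint8)
    area = int((pixels > 0).sum())
    assert abs(area_to_radius(area) - 50.0) < 0.5


# --- detection -------------------------------------------------------------

def test_uniform_background_below_seed_yields_no_objects():
    cfg = ThresholdConfig(rn_offset_x=55, seed_threshold=15, min_object_area_px=1)
    field = make_field(np.full((20, 20), 5))
    assert detect_objects(field, cfg) == []


def test_two_separated_blobs_merge_when_supports_touch():
    cfg = ThresholdConfig(
        rn_offset_x=55, seed_threshold=15, min_object_area_px=1, border_policy="keep"
    )
    apart = np.zeros((9, 15), dtype=np.uint8)
    apart[3:6, 2:5] = 100
    apart[3:6, 9:12] = 200
    objs = detect_objects(make_field(apart), cfg)
    assert len(objs) == 2
    assert sorted(o.local_max for o in objs) == [100, 200]

    touching = np.zeros((9, 15), dtype=np.uint8)
    touching[3:6, 2:8] = 100
    touching[3:6, 8:12] = 200
    merged = detect_objects(make_field(touching), cfg)
    assert len(merged) == 1
    assert merged[0].local_max == 200


def test_detected_phantom_local_max_matches_brute_force(simple_phantom):
    field, _ = sg.single_phantom_field(simple_phantom, seed=9)
    cfg = ThresholdConfig(rn_offset_x=55, min_object_area_px=100)
    objs = detect_objects(field, cfg)
    assert len(objs) == 1
    assert objs[0].local_max == int(field.pixels.max())


def test_border_touching_objects_dropped_by_default():
    pixels = np.zeros((20, 20), dtype=np.uint8)
    pixels[0:5, 0:5] = 200  # touches the border
    pixels[10:15, 10:15] = 200
    field = make_field(pixels)
    cfg = ThresholdConfig(rn_offset_x=55, min_object_area_px=1)
    assert len(detect_objects(field, cfg)) == 1
    kept = detect_objects(field, replace(cfg, border_policy="keep"))
    assert len(kept) == 2


def test_max_pixel_tie_breaks_topmost_then_leftmost():
    pixels = np.zeros((10, 10), dtype=np.uint8)
    pixels[4:7, 4:7] = 200  # nine-way tie at the maximum
    cfg = ThresholdConfig(rn_offset_x=55, min_object_area_px=1, border_policy="keep")
    (obj,) = detect_objects(make_field(pixels), cfg)
    assert obj.max_pixel == (4, 4)


# --- segmentation ----------------------------------------------------------

def test_disk_segmentation_area_within_rasterization_bounds():
    size = 128
    rr, cc = np.mgrid[0:size, 0:size]
    dist = np.hypot(rr - 63.5, cc - 63.5)
    field = make_field(np.where(dist <= 50.0, 255, 0))
    cfg = ThresholdConfig(rn_offset_x=55, min_object_area_px=1, border_policy="keep")
    (obj,) = detect_objects(field, cfg)
    _, area = segment_region(field, obj, 100)
    assert math.pi * 49.5**2 <= area <= math.pi * 50.5**2


def test_threshold_one_on_saturated_field_selects_whole_frame():
    field = make_field(np.full((12, 17), 255))
    cfg = ThresholdConfig(rn_offset_x=55, min_object_area_px=1, border_policy="keep")
    (obj,) = detect_objects(field, cfg)
    _, area = segment_region(field, obj, 1)
    assert area == 12 * 17


def test_threshold_above_local_max_returns_empty_region():
    field = make_field(np.full((10, 10), 100))
    cfg = ThresholdConfig(rn_offset_x=55, min_object_area_px=1, border_policy="keep")
    (obj,) = detect_objects(field, cfg)
    coords, area = segment_region(field, obj, 150)
    assert area == 0 and len(coords) == 0


@pytest.mark.parametrize("seed", range(6))
def test_segment_region_matches_brute_force_flood_fill(seed):
    rng = np.random.default_rng(seed)
    shape = (int(rng.integers(8, 65)), int(rng.integers(8, 65)))
    pixels = rng.integers(0, 256, size=shape, dtype=np.uint8)
    field = make_field(pixels)
    cfg = ThresholdConfig(
        rn_offset_x=55, seed_threshold=1, min_object_area_px=1, border_policy="keep"
    )
    for obj in detect_objects(field, cfg):
        for threshold in (1, 64, 128, 200):
            coords, area = segment_region(field, obj, threshold)
            expected = flood_fill_area(pixels.tolist(), obj.max_pixel, threshold)
            assert area == len(expected)
            assert set(map(tuple, coords)) == set(expected)


# --- measure_field ---------------------------------------------------------

def test_measured_halo_radius_matches_analytic_crossing(recovery_config, simple_phantom):
    field, truth = sg.single_phantom_field(simple_phantom, seed=4)
    (m,) = measure_field(field, recovery_config).measurements
    assert m.status == "measured"
    rn_true = sg.crossing_radius(truth, m.rn_threshold)
    outer_true = sg.crossing_radius(truth, m.outer_threshold)
    assert abs(m.rn_radius_px - rn_true) < 1.0
    assert abs(m.outer_radius_px - outer_true) < 1.0
    assert m.halo_radius_px == pytest.approx(m.outer_radius_px - m.rn_radius_px)


def test_dim_peak_under_relative_outer_gives_outer_fail(relative_config):
    spec = sg.PhantomSpec(
        center=(0.0, 0.0), rn_radius_px=16.0, peak_intensity=150, halo_scale_px=10.0
    )
    field, _ = sg.single_phantom_field(spec, seed=4)
    (m,) = measure_field(field, relative_config).measurements
    assert m.status == "outer_fail"
    assert m.outer_area_px is None
    assert m.rn_area_px is not None  # 150 - 75 is still measurable


def test_empty_field_yields_zero_measurements(recovery_config):
    field = make_field(np.zeros((30, 30)))
    assert measure_field(field, recovery_config).measurements == []


def test_rn_region_nested_inside_outer_region(recovery_config, simple_phantom):
    field, _ = sg.single_phantom_field(simple_phantom, seed=6)
    (m,) = measure_field(field, recovery_config).measurements
    rn = set(map(tuple, m.rn_pixels))
    outer = set(map(tuple, m.outer_pixels))
    assert rn < outer


def test_outer_area_monotone_in_absolute_threshold(recovery_config, simple_phantom):
    field, _ = sg.single_phantom_field(simple_phantom, seed=7)
    areas = []
    for outer_value in (60, 40, 25, 15):
        cfg = replace(recovery_config, outer_value=outer_value)
        (m,) = measure_field(field, cfg).measurements
        areas.append(m.outer_area_px)
    assert areas == sorted(areas)


def test_rn_area_monotone_in_offset(recovery_config, simple_phantom):
    field, _ = sg.single_phantom_field(simple_phantom, seed=8)
    areas = []
    for x in (30, 55, 80, 110):
        cfg = replace(recovery_config, rn_offset_x=x)
        (m,) = measure_field(field, cfg).measurements
        areas.append(m.rn_area_px)
    assert areas == sorted(areas)


def test_per_image_maxima_scope_anchors_all_objects_to_brightest():
    rng = np.random.default_rng(2)
    bright = replace(sg.sample_recovery_phantom(rng), center=(150.0, 160.0))
    dim = replace(
        sg.sample_recovery_phantom(rng), center=(150.0, 480.0), peak_intensity=200
    )
    field, _ = sg.render_field([bright, dim], 640, 300, seed=3)
    per_object = measure_field(
        field, ThresholdConfig.from_shorthand("x55/15", min_object_area_px=200)
    )
    per_image = measure_field(
        field,
        ThresholdConfig.from_shorthand(
            "x55/15", min_object_area_px=200, maxima_scope="image"
        ),
    )
    by_col = lambda ms: sorted(ms, key=lambda m: m.centroid[1])
    assert [m.local_max for m in by_col(per_object.measurements)] == [255, 200]
    assert [m.local_max for m in by_col(per_image.measurements)] == [255, 255]
    assert [m.rn_threshold for m in by_col(per_image.measurements)] == [200, 200]
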