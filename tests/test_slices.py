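"""Ramp thickness profilometry and slice/laser position metrics."""

import numpy as np
import pytest

from phantomqa.geometry import register_phantom
from phantomqa.imageio import QAImage
from phantomqa.simulate import SimConfig, render_series
from phantomqa.slices import (
    MeasurementError,
    RampProfile,
    combine_alignment,
    extract_ramp_profile,
    marker_visibility_insight,
    measure_ramp_pair,
    slice_position_acr,
    thickness_from_profile,
    thickness_fwhm,
)


def _trapezoid(b1: float, b2: float, high=1000.0, low=120.0, span=(-35.0, 35.0), noise=0.0, seed=0):
    u = np.arange(span[0], span[1], 0.1)
    frac = np.clip((u - b1) / (b2 - b1), 0.0, 1.0)
    y = high - (high - low) * frac
    if noise:
        y = y + np.random.default_rng(seed).normal(0, noise, y.shape)
    return RampProfile("synthetic", "top", u, y)


@pytest.mark.parametrize(
    "b1,b2",
    [(-15.0, 15.0), (-25.0, 25.0), (-12.3, 17.7), (-3.0, 3.0)],
)
def test_piecewise_fit_recovers_known_breakpoints(b1, b2):
    tr = thickness_from_profile(_trapezoid(b1, b2), slope_ratio=10.0)
    assert tr.start_mm == pytest.approx(b1, abs=0.2)
    assert tr.end_mm == pytest.approx(b2, abs=0.2)


def test_transition_lengths_to_thickness():
    """50 mm transition at slope ratio 10 is a 5 mm slice; 30 mm is 3 mm."""
    assert thickness_from_profile(_trapezoid(-25, 25, span=(-44, 44)), 10.0).thickness_mm == pytest.approx(5.0, abs=0.01)
    assert thickness_from_profile(_trapezoid(-15, 15), 10.0).thickness_mm == pytest.approx(3.0, abs=0.01)


def test_fit_tolerates_noise():
    tr = thickness_from_profile(_trapezoid(-15.0, 15.0, noise=30.0), 10.0)
    assert tr.thickness_mm == pytest.approx(3.0, abs=0.1)


def test_flat_profile_raises():
    u = np.arange(-30, 30, 0.1)
    with pytest.raises(MeasurementError):
        thickness_from_profile(RampProfile("flat", "top", u, np.full_like(u, 500.0)), 10.0)


def test_fwhm_estimator_agrees_on_ideal_trapezoid():
    prof = _trapezoid(-15.0, 15.0)
    a = thickness_from_profile(prof, 10.0)
    b = thickness_fwhm(prof, 10.0)
    assert b.thickness_mm == pytest.approx(a.thickness_mm, abs=0.1)
    assert b.estimator == "fwhm"


def test_harmonic_combination_of_split_pair():
    """Per-ramp estimates of 4.0 and 6.6667 mm combine to 5.0 mm."""
    t_top, t_bot = 4.0, 6.6667
    assert 2 * t_top * t_bot / (t_top + t_bot) == pytest.approx(5.0, abs=1e-3)


def test_profile_shape_and_extent(insight_ideal, insight_layout, insight_reg):
    series, _ = insight_ideal
    img = series[insight_layout.analysis_slices["ramps"]]
    prof = extract_ramp_profile(img, insight_layout, insight_reg, "ramp_z1_a", "top")
    assert prof.positions_mm[-1] - prof.positions_mm[0] == pytest.approx(70.0, abs=0.1)
    # plateau / transition / plateau: flat at both ends, monotone in between
    y = prof.intensity
    assert np.ptp(y[5:50]) < 20 and np.ptp(y[-55:-5]) < 20  # flat plateaus (interior)
    assert y[5:50].mean() > 2 * y[-55:-5].mean()


def test_ideal_insight_thickness(insight_ideal, insight_layout, insight_reg):
    series, _ = insight_ideal
    img = series[insight_layout.analysis_slices["ramps"]]
    for rid in ("ramp_z1_a", "ramp_z1_b", "ramp_z2", "ramp_z3", "ramp_z4"):
        m = measure_ramp_pair(img, insight_layout, insight_reg, rid, 3.0)
        assert m.thickness_mm == pytest.approx(3.0, abs=0.05), rid
        assert m.l_top == pytest.approx(30.0, rel=0.01)


def test_ideal_acr_thickness(acr_ideal, acr_layout, acr_reg):
    series, _ = acr_ideal
    m = measure_ramp_pair(series[0], acr_layout, acr_reg, "ramp_acr", 5.0)
    assert m.thickness_mm == pytest.approx(5.0, abs=0.05)


@pytest.mark.parametrize("tilt", [1.0, 2.0])
def test_tilt_splits_lengths_but_harmonic_recovers(insight_layout, tilt):
    series, truth = render_series(SimConfig(layout="INSIGHT", tilt_deg=tilt, seed=105))
    reg = register_phantom(series[0], insight_layout)
    img = series[insight_layout.analysis_slices["ramps"]]
    m = measure_ramp_pair(img, insight_layout, reg, "ramp_z1_a", 3.0)
    l_top_true, l_bot_true = truth.ramp_lengths["ramp_z1_a"]
    assert m.l_top == pytest.approx(l_top_true, rel=0.015)
    assert m.l_bottom == pytest.approx(l_bot_true, rel=0.015)
    assert m.l_top != pytest.approx(m.l_bottom, abs=1.0)  # visibly mismatched
    assert m.thickness_mm == pytest.approx(3.0, abs=0.05)


def test_wedge_offset_zero_when_aligned(acr_ideal, acr_layout, acr_reg):
    series, _ = acr_ideal
    r = slice_position_acr(series[0], acr_layout, acr_reg)
    assert r.offset_mm == pytest.approx(0.0, abs=0.1)


@pytest.mark.parametrize("shift", [1.8, -1.8])
def test_wedge_offset_tracks_displacement_with_sign(acr_layout, shift):
    series, _ = render_series(SimConfig(layout="ACR", slice_offset_mm=shift))
    reg = register_phantom(series[2], acr_layout)
    r = slice_position_acr(series[0], acr_layout, reg)
    assert r.offset_mm == pytest.approx(shift, abs=0.2)


def test_all_markers_visible(insight_ideal, insight_layout, insight_reg):
    series, _ = insight_ideal
    r = marker_visibility_insight(series, insight_layout, insight_reg)
    assert (r.markers_visible, r.markers_expected) == (10, 10)
    assert r.percent_visible == 100.0
    for cid, w in r.channel_widths_mm.items():
        nominal = insight_layout.structure(cid).geometry["width_mm"]
        assert w == pytest.approx(nominal, abs=0.8)


def test_no_markers_rendered_is_zero_percent(insight_layout):
    all_ids = tuple(s.id for s in insight_layout.structures if s.kind == "alignment_channel")
    series, _ = render_series(SimConfig(layout="INSIGHT", hidden_markers=all_ids))
    reg = register_phantom(series[0], insight_layout)
    r = marker_visibility_insight(series, insight_layout, reg)
    assert r.percent_visible == 0.0  # valid result, no error


def test_session_of_four_acquisitions_gives_92_5_percent(insight_layout):
    """37 of 40 markers rendered across four acquisitions -> 92.5% visible."""
    results = []
    for i, hidden in enumerate([(), (), (), ("ch_t1", "ch_l2", "ch_r1")]):
        series, _ = render_series(SimConfig(layout="INSIGHT", hidden_markers=hidden, seed=107 + i))
        reg = register_phantom(series[0], insight_layout)
        results.append(marker_visibility_insight(series, insight_layout, reg))
    pooled = combine_alignment(results)
    assert (pooled.markers_visible, pooled.markers_expected) == (37, 40)
    assert pooled.percent_visible == pytest.approx(92.5)


def test_visibility_invariant_under_intensity_rescale(insight_ideal, insight_layout, insight_reg):
    series, _ = insight_ideal
    img = series[insight_layout.analysis_slices["alignment"]]
    scaled = QAImage(img.pixels * 3.7, img.pixel_spacing, img.slice_position, img.orientation)
    from dataclasses import replace

    doctored = replace(series, images=[scaled if i is img else i for i in series.images])
    r = marker_visibility_insight(doctored, insight_layout, insight_reg)
    assert r.percent_visible == 100.0
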