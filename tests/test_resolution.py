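"""MTF representative value and ACR hole-array scoring."""

import math

import numpy as np
import pytest

from phantomqa.geometry import DetectionError, RegistrationResult, register_phantom
from phantomqa.imageio import QAImage
from phantomqa.layouts import get_layout
from phantomqa.resolution import (
    evaluate_zone_resolution,
    mtf_from_roi,
    score_acr_hole_arrays,
)
from phantomqa.simulate import DistortionField, SimConfig, render_series
from phantomqa.transforms import RigidTransform


def _sinusoid_image(modulation: float, period_mm: float = 6.0, size: int = 96) -> QAImage:
    """Directly rasterized sinusoidal plate pattern at 1 mm pixels."""
    x = np.arange(size, dtype=float)
    pattern = 1000.0 * (1.0 + modulation * np.sin(2 * math.pi * x / period_mm))
    return QAImage(np.tile(pattern, (size, 1)), (1.0, 1.0))


def test_calibration_sigma_over_mu_056_maps_to_mtf_08():
    """The printed calibration: ROI std/mean of 0.56 corresponds to MTF 0.8."""
    center = (47.5, 47.5)
    probe = mtf_from_roi(_sinusoid_image(0.792), center, period_mm=6.0)
    m = 0.792 * 0.56 / probe.sigma_over_mu  # rescale so measured sigma/mu is 0.56
    res = mtf_from_roi(_sinusoid_image(m), center, period_mm=6.0)
    assert res.sigma_over_mu == pytest.approx(0.56, abs=0.002)
    assert res.mtf == pytest.approx(0.8, abs=0.02)
    assert math.sqrt(2.0) * 0.56 == pytest.approx(0.8, abs=0.01)


def test_constant_roi_gives_zero_mtf():
    img = QAImage(np.full((96, 96), 800.0), (1.0, 1.0))
    res = mtf_from_roi(img, (47.5, 47.5))
    assert res.sigma_over_mu == 0.0
    assert res.mtf == 0.0
    assert not res.passed


def test_half_modulation_sinusoid_gives_mtf_05():
    res = mtf_from_roi(_sinusoid_image(0.5), (47.5, 47.5), period_mm=6.0)
    assert res.sigma_over_mu == pytest.approx(0.3536, abs=0.005)
    assert res.mtf == pytest.approx(0.50, abs=0.01)


def test_zero_signal_roi_raises():
    img = QAImage(np.zeros((96, 96)), (1.0, 1.0))
    with pytest.raises(DetectionError):
        mtf_from_roi(img, (47.5, 47.5))


def test_mtf_linear_in_modulation():
    """MTF(m) is linear in m for noiseless sinusoids (R^2 > 0.999)."""
    ms = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
    vals = np.array([mtf_from_roi(_sinusoid_image(m), (47.5, 47.5), period_mm=6.0).mtf for m in ms])
    slope, intercept = np.polyfit(ms, vals, 1)
    pred = slope * ms + intercept
    r2 = 1 - np.sum((vals - pred) ** 2) / np.sum((vals - vals.mean()) ** 2)
    assert r2 > 0.999
    assert slope == pytest.approx(1.0, abs=0.07)


def test_ideal_render_high_mtf_and_oracle_consistency(insight_ideal, insight_layout, insight_reg):
    """Pipeline MTF agrees with a direct sigma/mu computed on the raw ROI."""
    series, _ = insight_ideal
    fe, pe = evaluate_zone_resolution(series, insight_layout, insight_reg, 1)
    for res in (fe, pe):
        assert res.valid and res.passed
        assert res.mtf > 0.9
    img = series[insight_layout.analysis_slices["resolution"]]
    s = next(x for x in insight_layout.structures if x.id == "pat_z1_fe")
    pos = insight_reg.transform.phantom_to_pixel(img, np.array([s.center], float))[0]
    rr, cc = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    roi = (rr - pos[0]) ** 2 + (cc - pos[1]) ** 2 <= (15.45) ** 2
    direct = math.sqrt(2.0) * img.pixels[roi].std() / img.pixels[roi].mean()
    assert fe.mtf == pytest.approx(direct, abs=0.02)


def test_blur_at_pattern_period_collapses_mtf(insight_layout):
    series, _ = render_series(SimConfig(layout="INSIGHT", blur_fwhm=6.0, seed=104))
    reg = register_phantom(series[0], insight_layout)
    fe, _ = evaluate_zone_resolution(series, insight_layout, reg, 1)
    assert fe.mtf < 0.2


def test_mtf_monotone_nonincreasing_in_blur(insight_layout):
    values = []
    for f in (0.0, 1.5, 3.0, 4.5, 6.0):
        series, _ = render_series(SimConfig(layout="INSIGHT", blur_fwhm=f, seed=104))
        reg = register_phantom(series[0], insight_layout)
        fe, _ = evaluate_zone_resolution(series, insight_layout, reg, 1)
        values.append(fe.mtf)
    assert all(a >= b - 1e-6 for a, b in zip(values, values[1:])), values


def test_warped_pattern_flagged_invalid(insight_layout):
    """Local distortion shifts the detected fundamental >10% off nominal."""
    field = DistortionField(affine=((0.88, 0.0), (0.0, 0.88)))
    series, _ = render_series(SimConfig(layout="INSIGHT", distortion=field))
    reg = RegistrationResult(RigidTransform(), 0.0, True)  # pose is known
    fe, _ = evaluate_zone_resolution(series, insight_layout, reg, 1)
    assert not fe.valid


def test_noise_floor_correction(insight_layout):
    """With 5% noise the corrected MTF stays close to the noiseless value."""
    clean, _ = render_series(SimConfig(layout="INSIGHT", seed=104))
    noisy, _ = render_series(SimConfig(layout="INSIGHT", noise_sigma=0.05, seed=11))
    fe0, _ = evaluate_zone_resolution(clean, insight_layout, register_phantom(clean[0], insight_layout), 1)
    fe1, _ = evaluate_zone_resolution(noisy, insight_layout, register_phantom(noisy[0], insight_layout), 1)
    assert fe1.mtf == pytest.approx(fe0.mtf, abs=0.03)


# ---------------------------------------------------------------------------
# ACR hole arrays (rendered at 0.25 mm pixels: the bundled pitches of about
# 1 mm need adequate display sampling before peak-to-valley contrast exists)
# ---------------------------------------------------------------------------


def _acr_fine(blur):
    return render_series(
        SimConfig(layout="ACR", pixel_spacing=(0.25, 0.25), matrix=(800, 800), blur_fwhm=blur)
    )[0]


def test_unblurred_resolves_smallest_pitch(acr_layout):
    series = _acr_fine(0.0)
    reg = register_phantom(series[2], acr_layout)
    res = score_acr_hole_arrays(series[0], acr_layout, reg)
    for direction in ("frequency_encode", "phase_encode"):
        assert res[direction].resolved_pitch_mm == 0.9  # smallest bundled pitch


def test_heavy_blur_resolves_nothing(acr_layout):
    series = _acr_fine(2.0)
    reg = register_phantom(series[2], acr_layout)
    res = score_acr_hole_arrays(series[0], acr_layout, reg)
    assert res["frequency_encode"].resolved_pitch_mm is None


def test_resolved_pitch_monotone_in_blur(acr_layout):
    resolved = []
    for blur in (0.0, 0.5, 1.0):
        series = _acr_fine(blur)
        reg = register_phantom(series[2], acr_layout)
        r = score_acr_hole_arrays(series[0], acr_layout, reg)["frequency_encode"]
        resolved.append(r.resolved_pitch_mm if r.resolved_pitch_mm is not None else float("inf"))
    assert resolved == sorted(resolved), resolved
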