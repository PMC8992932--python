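"""Simulator determinism, symmetry, ground-truth consistency, degradations."""

import math

import numpy as np
import pytest

from phantomqa.imageio import write_series, read_series
from phantomqa.layouts import get_layout
from phantomqa.simulate import (
    BiasField,
    DistortionField,
    SimConfig,
    SimulationError,
    ramp_transition_lengths,
    render_series,
    render_uniform_slab,
)


def test_same_seed_is_bit_identical():
    a, _ = render_series(SimConfig(layout="ACR", noise_sigma=0.03, seed=42))
    b, _ = render_series(SimConfig(layout="ACR", noise_sigma=0.03, seed=42))
    for ia, ib in zip(a.images, b.images):
        np.testing.assert_array_equal(ia.pixels, ib.pixels)


def test_different_seed_changes_noise():
    a, _ = render_series(SimConfig(layout="ACR", noise_sigma=0.03, seed=1, n_slices=1))
    b, _ = render_series(SimConfig(layout="ACR", noise_sigma=0.03, seed=2, n_slices=1))
    assert not np.array_equal(a[0].pixels, b[0].pixels)


@pytest.mark.parametrize("slice_name", ["grid", "resolution", "uniformity"])
def test_mirror_symmetry_of_symmetric_slices(insight_ideal, insight_layout, slice_name):
    """Noiseless distortion-free renders inherit the layout's left-right mirror symmetry."""
    series, _ = insight_ideal
    img = series[insight_layout.analysis_slices[slice_name]].pixels
    np.testing.assert_allclose(img, np.fliplr(img), atol=1.0)  # 1 DN of rounding


def test_disk_and_disk_render_on_disk_round_trip(tmp_path, acr_ideal):
    """Writing and re-reading a rendered series preserves every pixel."""
    series, _ = acr_ideal
    write_series(series, tmp_path)
    back = read_series(tmp_path)
    for a, b in zip(series.images, back.images):
        np.testing.assert_array_equal(a.pixels, b.pixels)


def test_blur_preserves_interior_mean(insight_layout):
    """Gaussian blur conserves flux: the mean over the interior, away from
    edges and structures, is blur-invariant."""
    sharp = render_uniform_slab(SimConfig(layout="INSIGHT"))
    soft = render_uniform_slab(SimConfig(layout="INSIGHT", blur_fwhm=4.0))
    c = sharp.pixels.shape[0] // 2
    win = slice(c - 40, c + 40)
    assert soft.pixels[win, win].mean() == pytest.approx(sharp.pixels[win, win].mean(), rel=1e-4)


def test_uniform_slab_flat_when_clean():
    img = render_uniform_slab(SimConfig(layout="ACR"))
    c = img.pixels.shape[0] // 2
    core = img.pixels[c - 30 : c + 30, c - 30 : c + 30]
    assert core.min() == core.max() == 1000.0


def test_uniform_slab_noise_statistics():
    """ROI std/mean converges to the configured noise fraction."""
    img = render_uniform_slab(SimConfig(layout="ACR", noise_sigma=0.05, seed=9))
    c = img.pixels.shape[0] // 2
    core = img.pixels[c - 50 : c + 50, c - 50 : c + 50]
    assert core.std() / core.mean() == pytest.approx(0.05, abs=0.002)


def test_ground_truth_matches_distortion_field(insight_layout):
    field = DistortionField(affine=((0.995, 0.002), (0.0, 1.003)), radial_k=-2e-5)
    _, truth = render_series(SimConfig(layout="INSIGHT", distortion=field, n_slices=1))
    for s in insight_layout.structures:
        if s.kind == "grid_line":
            expected = field.displacement(np.array([s.center]))[0]
            np.testing.assert_allclose(truth.grid_displacements[s.id], expected, atol=1e-12)


def test_radial_distortion_diagonal_truth(insight_layout):
    """A field pulling each 141.4 mm corner inward by 1 mm shortens the
    diagonal by 2 mm: both endpoints move toward the center."""
    r_corner = 100.0 * math.sqrt(2.0)
    k = -1.0 / r_corner**2
    _, truth = render_series(SimConfig(layout="INSIGHT", distortion=DistortionField(radial_k=k), n_slices=1))
    assert truth.path_length(insight_layout, "diag_BL_TR") == pytest.approx(r_corner * 2 - 2.0, abs=1e-9)


def test_ramp_tilt_lengths_and_harmonic_identity():
    """Tilt splits the opposed transition lengths exactly as 1/(1 +- R tan t),
    and the harmonic mean of the two per-ramp estimates is the true thickness."""
    l_top, l_bot = ramp_transition_lengths(3.0, 10.0, 1.5)
    c = 10.0 * math.tan(math.radians(1.5))
    assert l_top == pytest.approx(30.0 / (1 + c))
    assert l_bot == pytest.approx(30.0 / (1 - c))
    t_top, t_bot = l_top / 10.0, l_bot / 10.0
    assert 2 * t_top * t_bot / (t_top + t_bot) == pytest.approx(3.0, abs=1e-12)


def test_invalid_configs_rejected():
    with pytest.raises(SimulationError):
        SimConfig(layout="INSIGHT", modulation=1.5).resolve()
    with pytest.raises(SimulationError):
        SimConfig(layout="INSIGHT", blur_fwhm=-1.0).resolve()
    with pytest.raises(SimulationError):  # phantom no longer fits the matrix
        SimConfig(layout="INSIGHT", matrix=(128, 128)).resolve()
    with pytest.raises(SimulationError):  # tilt incompatible with ramp slope
        render_series(SimConfig(layout="INSIGHT", tilt_deg=45.0))


def test_bias_field_applied_multiplicatively():
    g = 0.001
    img = render_uniform_slab(SimConfig(layout="ACR", bias=BiasField(gx=g)))
    c = img.pixels.shape[0] // 2
    left = img.pixels[c, c - 60]
    right = img.pixels[c, c + 60]
    u = 60 * 0.98
    assert right / left == pytest.approx((1 + g * u) / (1 - g * u), rel=1e-3)


def test_rician_noise_has_positive_floor():
    cfg = SimConfig(layout="ACR", noise_sigma=0.05, noise_model="rician", seed=3)
    img = render_uniform_slab(cfg)
    corner = img.pixels[:20, :20]  # outside the phantom
    assert corner.mean() > 30.0  # magnitude noise floor ~ sigma*sqrt(pi/2)
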