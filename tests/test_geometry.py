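"""Registration accuracy, landmark recovery, and path-length measurement."""

import numpy as np
import pytest

from phantomqa.geometry import (
    DetectionError,
    QualityError,
    locate_grid_points,
    measure_geometry,
    measure_paths,
    register_phantom,
)
from phantomqa.imageio import QAImage
from phantomqa.simulate import DistortionField, SimConfig, render_series


def test_identity_render_registers_to_identity(insight_ideal, insight_layout):
    series, _ = insight_ideal
    reg = register_phantom(series[0], insight_layout)
    assert reg.success
    assert reg.transform.angle_deg == pytest.approx(0.0, abs=0.05)
    assert (reg.transform.tx, reg.transform.ty) == pytest.approx((0.0, 0.0), abs=0.05)
    assert reg.residual_mm < 0.1


def test_known_pose_recovered(insight_layout):
    series, _ = render_series(SimConfig(layout="INSIGHT", rotation_deg=2.0, offset_mm=(3.0, -4.0)))
    reg = register_phantom(series[0], insight_layout)
    assert reg.transform.angle_deg == pytest.approx(2.0, abs=0.2)
    assert reg.transform.tx == pytest.approx(3.0, abs=0.2)
    assert reg.transform.ty == pytest.approx(-4.0, abs=0.2)


def test_blank_image_raises_detection_error(insight_layout):
    blank = QAImage(np.zeros((128, 128)), (1.0, 1.0))
    with pytest.raises(DetectionError):
        register_phantom(blank, insight_layout)


def test_noiseless_landmarks_within_tenth_mm(insight_ideal, insight_layout, insight_reg):
    series, _ = insight_ideal
    pts = locate_grid_points(series[0], insight_layout, insight_reg)
    assert all(p.found for p in pts)
    for p in pts:
        err = np.hypot(
            p.position_mm[0] - p.nominal_phantom_mm[0],
            p.position_mm[1] - p.nominal_phantom_mm[1],
        )
        assert err < 0.1, p.point_id


def test_occluded_landmark_flagged_not_dropped(insight_ideal, insight_layout, insight_reg):
    series, _ = insight_ideal
    img = series[0]
    # paint over one rod with plateau signal: the landmark must be reported missing
    pix = img.pixels.copy()
    pos = insight_reg.transform.phantom_to_pixel(img, np.array([[50.0, 50.0]]))[0]
    r, c = int(round(pos[0])), int(round(pos[1]))
    pix[r - 4 : r + 5, c - 4 : c + 5] = 1000.0
    doctored = QAImage(pix, img.pixel_spacing, img.slice_position, img.orientation)
    pts = locate_grid_points(doctored, insight_layout, insight_reg)
    missing = [p.point_id for p in pts if not p.found]
    assert missing == ["n+050+050"]
    records = {m.path_id: m for m in measure_paths(pts, insight_layout)}
    assert records["horizontal"].measured_mm is not None  # unaffected path intact


def test_too_many_missing_landmarks_is_quality_error(insight_ideal, insight_layout, insight_reg):
    series, _ = insight_ideal
    img = series[0]
    pix = img.pixels.copy()
    for s in insight_layout.structures:
        if s.kind == "grid_line" and abs(s.center[0]) <= 50:  # hide >20% of rods
            pos = insight_reg.transform.phantom_to_pixel(img, np.array([s.center], float))[0]
            r, c = int(round(pos[0])), int(round(pos[1]))
            pix[r - 4 : r + 5, c - 4 : c + 5] = 1000.0
    doctored = QAImage(pix, img.pixel_spacing, img.slice_position, img.orientation)
    with pytest.raises(QualityError):
        locate_grid_points(doctored, insight_layout, insight_reg)


def test_missing_endpoint_skips_path_with_warning(insight_ideal, insight_layout, insight_reg):
    series, _ = insight_ideal
    pts = locate_grid_points(series[0], insight_layout, insight_reg)
    pts = [p for p in pts if p.point_id != "n+100+000"]  # drop one horizontal endpoint
    records = {m.path_id: m for m in measure_paths(pts, insight_layout)}
    assert records["horizontal"].measured_mm is None
    assert "missing" in records["horizontal"].warning
    assert records["vertical"].measured_mm == pytest.approx(200.0, abs=0.1)


def test_ideal_insight_paths_at_nominal(insight_ideal, insight_layout, insight_reg):
    series, _ = insight_ideal
    pts = locate_grid_points(series[0], insight_layout, insight_reg)
    measured = {m.path_id: m.measured_mm for m in measure_paths(pts, insight_layout)}
    assert measured["horizontal"] == pytest.approx(200.0, abs=0.1)
    assert measured["vertical"] == pytest.approx(200.0, abs=0.1)
    for d in ("diag_BL_TR", "diag_BR_TL"):
        assert measured[d] == pytest.approx(282.9, abs=0.2)
    for p in ("LP", "RP", "TP"):
        assert measured[p] == pytest.approx(100.0, abs=0.1)


def test_ideal_acr_paths_at_nominal(acr_ideal, acr_layout):
    series, _ = acr_ideal
    for m in measure_geometry(series[2], acr_layout):
        assert m.measured_mm == pytest.approx(190.0, abs=0.2), m.path_id


def test_uniform_contraction_gives_minus_two_mm_error(insight_layout):
    """A 1% isotropic scale error contracts the 200 mm paths by 2 mm."""
    field = DistortionField(affine=((0.99, 0.0), (0.0, 0.99)))
    series, _ = render_series(SimConfig(layout="INSIGHT", distortion=field, n_slices=1))
    errors = {m.path_id: m.error_mm for m in measure_geometry(series[0], insight_layout)}
    assert errors["horizontal"] == pytest.approx(-2.0, abs=0.2)
    assert errors["vertical"] == pytest.approx(-2.0, abs=0.2)


def test_distorted_landmarks_match_analytic_field(insight_layout):
    field = DistortionField(radial_k=-4e-5)
    series, truth = render_series(SimConfig(layout="INSIGHT", distortion=field, n_slices=1))
    reg = register_phantom(series[0], insight_layout)
    # with a pure radial field the pose is still identity; displacements are
    # absorbed into the landmark positions, not the rigid transform
    pts = locate_grid_points(series[0], insight_layout, reg)
    for p in pts:
        expected = truth.displaced_node(insight_layout, p.point_id)
        observed = reg.transform.image_mm_to_phantom(np.array([p.position_mm]))[0]
        assert np.hypot(*(observed - expected)) < 0.15, p.point_id


@pytest.mark.parametrize("pose", [(3.0, (3.0, -4.0)), (-2.0, (5.0, 2.0)), (1.5, (-8.0, 6.0))])
def test_path_lengths_invariant_under_pose(insight_ideal, insight_layout, pose):
    """Rigid pose changes within setup tolerance must not move the measurement."""
    baseline, _ = insight_ideal
    base = {m.path_id: m.measured_mm for m in measure_geometry(baseline[0], insight_layout)}
    angle, offset = pose
    series, _ = render_series(SimConfig(layout="INSIGHT", rotation_deg=angle, offset_mm=offset, n_slices=1))
    posed = {m.path_id: m.measured_mm for m in measure_geometry(series[0], insight_layout)}
    for pid, v in base.items():
        assert posed[pid] == pytest.approx(v, abs=0.05), pid
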