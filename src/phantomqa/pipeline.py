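"""One-call analysis pipelines: series in, session report out."""

from __future__ import annotations

from typing import Any

from .geometry import locate_grid_points, measure_paths, register_phantom
from .imageio import QASeries
from .layouts import PhantomLayout, get_layout
from .report import QAReport, Thresholds, build_report
from .resolution import evaluate_zone_resolution, score_acr_hole_arrays
from .slices import marker_visibility_insight, measure_ramp_pair, slice_position_acr
from .uniformity import acr_uniformity, insight_uniformity

__all__ = ["analyze_series"]


def analyze_series(
    series: QASeries,
    layout: PhantomLayout | str,
    thresholds: Thresholds | None = None,
    session: dict[str, Any] | None = None,
) -> QAReport:
    """Run every QA test the layout defines on one series.

    Registration is estimated once on the slice that carries the geometric
    landmarks and reused by all analyzers.
    """
    if isinstance(layout, str):
        layout = get_layout(layout)
    results: list[Any] = []
    if layout.name == "INSIGHT":
        reg = register_phantom(series[layout.analysis_slices["grid"]], layout)
        points = locate_grid_points(series[layout.analysis_slices["grid"]], layout, reg)
        results.extend(measure_paths(points, layout))
        for z in (1, 2, 3, 4):
            results.extend(evaluate_zone_resolution(series, layout, reg, z))
        ramp_img = series[layout.analysis_slices["ramps"]]
        for s in layout.structures:
            if s.kind == "ramp_pair":
                results.append(measure_ramp_pair(ramp_img, layout, reg, s.id, series.slice_thickness))
        results.append(marker_visibility_insight(series, layout, reg))
        results.append(insight_uniformity(series[layout.analysis_slices["uniformity"]], layout, reg))
    else:  # ACR
        geo_img = series[layout.analysis_slices["geometry"]]
        reg = register_phantom(geo_img, layout)
        points = locate_grid_points(geo_img, layout, reg)
        results.extend(measure_paths(points, layout))
        main_img = series[layout.analysis_slices["ramps"]]
        results.extend(score_acr_hole_arrays(main_img, layout, reg).values())
        for s in layout.structures:
            if s.kind == "ramp_pair":
                results.append(measure_ramp_pair(main_img, layout, reg, s.id, series.slice_thickness))
        results.append(slice_position_acr(main_img, layout, reg))
        results.append(acr_uniformity(series[layout.analysis_slices["uniformity"]], layout, reg))
    meta = {
        "phantom": layout.name,
        "orientation": series.orientation,
        "weighting": series.weighting,
        "coil": series.coil,
        "field_strength": series.field_strength,
    }
    meta.update(session or {})
    return build_report(results, thresholds, session=meta)
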