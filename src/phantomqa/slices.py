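"""Slice-thickness and slice/laser-position metrics.

Slice thickness comes from angled signal ramps: a thin plate of slope ratio
R (run per unit rise, 10 by default) intersected by a slice of thickness t
projects onto the image as a transition of length ``L = R * t`` between a
saturated-top and a saturated-bottom plateau.  The transition endpoints
("inflection points") are found with a least-squares three-segment
piecewise-linear fit of the ramp's line profile - robust to noise, unlike
derivative thresholding.  Opposed ramp pairs cancel phantom tilt: with tilt
the two apparent thicknesses become ``t / (1 +- R tan(tilt))`` and their
harmonic combination ``2 t_top t_bottom / (t_top + t_bottom)`` restores the
true thickness exactly.

Slice position is read from the crossed-wedge bars on the ACR phantom (the
45 deg geometry turns a through-plane displacement d into a bar-length
difference of 2d) and from the count of visible plane-alignment marker
channels on the large-FOV phantom, reported as a percentage of the markers
expected over the session's acquisitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import minimize

from .imageio import QAImage, QASeries
from .layouts import PhantomLayout, StructureSpec
from .geometry import DetectionError, RegistrationResult

__all__ = [
    "RampProfile",
    "RampTransition",
    "RampMeasurement",
    "AlignmentResult",
    "extract_ramp_profile",
    "thickness_from_profile",
    "measure_ramp_pair",
    "slice_position_acr",
    "marker_visibility_insight",
    "combine_alignment",
    "MeasurementError",
]

PROFILE_STEP_MM = 0.1
CNR_VISIBILITY_THRESHOLD = 3.0


class MeasurementError(RuntimeError):
    """Raised when a profile does not contain a fittable ramp."""


@dataclass(frozen=True)
class RampProfile:
    ramp_id: str
    which: str  # "top" | "bottom"
    positions_mm: np.ndarray  # along the ramp axis, phantom frame
    intensity: np.ndarray


@dataclass(frozen=True)
class RampTransition:
    start_mm: float  # inflection: end of the saturated top
    end_mm: float  # inflection: start of the saturated bottom
    length_mm: float
    thickness_mm: float  # length / slope_ratio
    estimator: str = "piecewise_linear"


@dataclass(frozen=True)
class RampMeasurement:
    zone_id: int
    ramp_id: str
    l_top: float
    l_bottom: float
    transitions: tuple[RampTransition, RampTransition]
    thickness_mm: float
    nominal_mm: float
    estimator: str = "piecewise_linear"

    @property
    def error_mm(self) -> float:
        return self.thickness_mm - self.nominal_mm


@dataclass(frozen=True)
class AlignmentResult:
    markers_expected: int = 0
    markers_visible: int = 0
    offset_mm: float | None = None  # ACR wedge displacement; sign = direction
    channel_widths_mm: dict[str, float] | None = None

    @property
    def percent_visible(self) -> float:
        if self.markers_expected == 0:
            return 0.0
        return 100.0 * self.markers_visible / self.markers_expected


# ---------------------------------------------------------------------------
# ramp profiles
# ---------------------------------------------------------------------------


def _sample(image: QAImage, reg: RegistrationResult, pts_phantom: np.ndarray) -> np.ndarray:
    pix = reg.transform.phantom_to_pixel(image, pts_phantom)
    return map_coordinates(image.pixels, [pix[:, 0], pix[:, 1]], order=1, mode="nearest")


def extract_ramp_profile(
    image: QAImage,
    layout: PhantomLayout,
    reg: RegistrationResult,
    ramp_id: str,
    which: str = "top",
) -> RampProfile:
    """Line profile along one ramp of a pair, averaged across its width.

    Sampled at 0.1 mm by bilinear interpolation over 60% of the strip width;
    covers the saturated-top, transition, and saturated-bottom segments.
    """
    s = layout.structure(ramp_id)
    if s.kind != "ramp_pair":
        raise DetectionError(f"{ramp_id} is not a ramp pair")
    g = s.geometry
    cx, cy = s.center
    sign = +1 if which == "top" else -1
    off = sign * g["strip_sep_mm"] / 2.0
    u = np.arange(-g["extent_mm"] / 2, g["extent_mm"] / 2 + 1e-9, PROFILE_STEP_MM)
    lanes = np.linspace(-0.3, 0.3, 5) * g["strip_width_mm"]
    prof = np.zeros_like(u)
    for w in lanes:
        if g["axis"] == "x":
            pts = np.column_stack([cx + u, np.full_like(u, cy + off + w)])
        else:
            pts = np.column_stack([np.full_like(u, cx + off + w), cy + u])
        prof += _sample(image, reg, pts)
    return RampProfile(ramp_id, which, u, prof / len(lanes))


def _piecewise_sse(u: np.ndarray, y: np.ndarray, b1: float, b2: float) -> tuple[float, float, float]:
    """Closed-form LS levels for a plateau/linear/plateau model at breakpoints."""
    g = np.clip((u - b1) / max(b2 - b1, 1e-6), 0.0, 1.0)
    G = np.column_stack([np.ones_like(g), g])
    coef, *_ = np.linalg.lstsq(G, y, rcond=None)
    resid = y - G @ coef
    return float(resid @ resid), float(coef[0]), float(coef[1])


def thickness_from_profile(
    profile: RampProfile,
    slope_ratio: float = 10.0,
) -> RampTransition:
    """Transition length and thickness of one ramp via the three-segment fit.

    The breakpoints of the least-squares plateau/linear/plateau model are the
    profile's inflection points; their separation divided by the slope ratio
    is the slice thickness sampled by this ramp.
    """
    if slope_ratio <= 0:
        raise ValueError("slope_ratio must be positive")
    u, y = profile.positions_mm, profile.intensity
    span = u[-1] - u[0]
    # coarse grid over breakpoint pairs
    grid = np.linspace(u[0] + 0.02 * span, u[-1] - 0.02 * span, 41)
    best = None
    for i, b1 in enumerate(grid):
        for b2 in grid[i + 1 :]:
            sse, a, b = _piecewise_sse(u, y, b1, b2)
            if best is None or sse < best[0]:
                best = (sse, b1, b2, a, b)
    _, b1, b2, a, b = best
    res = minimize(
        lambda p: _piecewise_sse(u, y, min(p[0], p[1] - 1e-3), max(p[1], p[0] + 1e-3))[0],
        x0=[b1, b2],
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-9},
    )
    b1, b2 = sorted(res.x)
    sse, a, b = _piecewise_sse(u, y, b1, b2)
    # sanity: the fit must describe a real transition between two plateaus
    contrast = abs(b)
    if contrast < 0.1 * (np.ptp(y) + 1e-9) or not (u[0] < b1 < b2 < u[-1]):
        raise MeasurementError(f"no plateau/transition/plateau shape in {profile.ramp_id}")
    L = b2 - b1
    return RampTransition(float(b1), float(b2), float(L), float(L / slope_ratio))


def measure_ramp_pair(
    image: QAImage,
    layout: PhantomLayout,
    reg: RegistrationResult,
    ramp_id: str,
    nominal_mm: float,
) -> RampMeasurement:
    """Tilt-corrected slice thickness from an opposed ramp pair.

    The harmonic combination ``2 t_top t_bot / (t_top + t_bot)`` of the two
    per-ramp estimates is exact for linear ramps under pure phantom tilt.
    """
    s = layout.structure(ramp_id)
    ratio = float(s.geometry["slope_ratio"])
    tr_top = thickness_from_profile(extract_ramp_profile(image, layout, reg, ramp_id, "top"), ratio)
    tr_bot = thickness_from_profile(extract_ramp_profile(image, layout, reg, ramp_id, "bottom"), ratio)
    t_top, t_bot = tr_top.thickness_mm, tr_bot.thickness_mm
    thickness = 2.0 * t_top * t_bot / (t_top + t_bot)
    return RampMeasurement(
        zone_id=s.zone_id,
        ramp_id=ramp_id,
        l_top=tr_top.length_mm,
        l_bottom=tr_bot.length_mm,
        transitions=(tr_top, tr_bot),
        thickness_mm=float(thickness),
        nominal_mm=float(nominal_mm),
    )


def thickness_fwhm(profile: RampProfile, slope_ratio: float = 10.0) -> RampTransition:
    """Alternative estimator: transition length from the 25%-75% span scaled.

    Provided in the manual-QA style as a cross-check on the piecewise fit;
    for an ideal trapezoid both agree exactly.
    """
    u, y = profile.positions_mm, profile.intensity
    lo, hi = float(y.min()), float(y.max())
    if hi - lo <= 0:
        raise MeasurementError("flat profile")
    norm = (y - lo) / (hi - lo)
    above75 = u[norm >= 0.75]
    above25 = u[norm >= 0.25]
    if len(above75) == 0 or len(above25) == 0:
        raise MeasurementError("profile lacks plateaus")
    # descending profile: 75% and 25% crossings bracket half the transition
    L = 2.0 * abs(above25.max() - above75.max())
    return RampTransition(float(above75.max()), float(above25.max()), float(L), float(L / slope_ratio), estimator="fwhm")


# ---------------------------------------------------------------------------
# slice / laser position
# ---------------------------------------------------------------------------


def _bar_length(image: QAImage, reg: RegistrationResult, cx: float, cy: float, width: float, search_mm: float) -> float:
    """Length of a dark vertical bar via 50% edge crossings along its axis."""
    u = np.arange(-search_mm, search_mm, 0.05)
    lanes = np.linspace(-0.3, 0.3, 3) * width
    prof = np.zeros_like(u)
    for w in lanes:
        pts = np.column_stack([np.full_like(u, cx + w), cy + u])
        prof += _sample(image, reg, pts)
    prof /= len(lanes)
    plateau = float(np.percentile(prof, 95))
    bar = float(prof.min())
    if plateau - bar < 0.3 * plateau:
        raise DetectionError("wedge bar not found")
    half = (plateau + bar) / 2.0
    below = prof < half
    idx = np.nonzero(below)[0]
    i0, i1 = idx[0], idx[-1]
    # linear interpolation at both ends
    lo = u[i0 - 1] + (prof[i0 - 1] - half) / (prof[i0 - 1] - prof[i0]) * 0.05 if i0 > 0 else u[i0]
    hi = u[i1] + (prof[i1] - half) / (prof[i1] - prof[i1 + 1]) * 0.05 if i1 + 1 < len(u) else u[i1]
    return float(hi - lo)


def slice_position_acr(image: QAImage, layout: PhantomLayout, reg: RegistrationResult) -> AlignmentResult:
    """Slice-position offset from the crossed-wedge bar-length difference.

    ``offset = (right bar - left bar) / 2``; the sign gives the displacement
    direction (positive = right bar longer).
    """
    wedges = [s for s in layout.structures if s.kind == "wedge_pair"]
    if not wedges:
        raise DetectionError("layout has no wedge pair")
    g = wedges[0].geometry
    cx, cy = wedges[0].center
    search = g["base_length_mm"]
    left = _bar_length(image, reg, cx - g["bar_offset_mm"], cy, g["bar_width_mm"], search)
    right = _bar_length(image, reg, cx + g["bar_offset_mm"], cy, g["bar_width_mm"], search)
    return AlignmentResult(offset_mm=float((right - left) / 2.0))


def _channel_metrics(image: QAImage, reg: RegistrationResult, s: StructureSpec) -> tuple[float, float]:
    """(contrast-to-noise ratio, measured width mm) of one alignment channel."""
    g = s.geometry
    cx, cy = s.center
    along_x = g["axis"] == "x"
    w = np.arange(-6.0, 6.0, 0.05)  # across the channel
    lanes = np.linspace(-0.3, 0.3, 5) * g["length_mm"]
    prof = np.zeros_like(w)
    for a in lanes:
        if along_x:
            pts = np.column_stack([np.full_like(w, cx + a), cy + w])
        else:
            pts = np.column_stack([cx + w, np.full_like(w, cy + a)])
        prof += _sample(image, reg, pts)
    prof /= len(lanes)
    flank = np.abs(w) > g["width_mm"] / 2 + 2.0
    plateau = float(np.mean(prof[flank]))
    noise = float(np.std(prof[flank]))
    core = np.abs(w) <= g["width_mm"] / 2
    depth = plateau - float(np.mean(prof[core]))
    cnr = depth / max(noise, 0.01 * plateau, 1e-9)
    # measured width: extent below half-depth
    half = plateau - 0.5 * max(plateau - prof.min(), 1e-9)
    below = w[prof < half]
    width = float(below.max() - below.min()) if len(below) else 0.0
    return cnr, width


def marker_visibility_insight(
    series: QASeries,
    layout: PhantomLayout,
    reg: RegistrationResult,
) -> AlignmentResult:
    """Visibility of the plane-alignment marker channels in one acquisition.

    A marker counts as visible when its channel's contrast-to-noise ratio is
    at least 3 inside the nominal window.  Zero visible markers is a valid
    result (the metric is reported, not raised).  Aggregate multiple
    acquisitions with :func:`combine_alignment`.
    """
    channels = [s for s in layout.structures if s.kind == "alignment_channel"]
    image = series[layout.analysis_slices["alignment"]]
    visible = 0
    widths = {}
    for s in channels:
        cnr, width = _channel_metrics(image, reg, s)
        if cnr >= CNR_VISIBILITY_THRESHOLD:
            visible += 1
            widths[s.id] = width
    return AlignmentResult(markers_expected=len(channels), markers_visible=visible, channel_widths_mm=widths)


def combine_alignment(results: list[AlignmentResult]) -> AlignmentResult:
    """Pool marker counts over a session's acquisitions."""
    widths = {}
    for r in results:
        widths.update(r.channel_widths_mm or {})
    return AlignmentResult(
        markers_expected=sum(r.markers_expected for r in results),
        markers_visible=sum(r.markers_visible for r in results),
        channel_widths_mm=widths,
    )
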