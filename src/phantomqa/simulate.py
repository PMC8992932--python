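"""Synthetic phantom-image renderer with parameterized degradations.

Renders multi-slice series from a :class:`~phantomqa.layouts.PhantomLayout`
and records the ground truth needed to test every analyzer: true landmark
displacements under the applied distortion field, true slice thickness and
per-ramp transition lengths under phantom tilt, true pattern modulation,
marker visibility states, noise level and bias field.

Rendering pipeline (per slice)
------------------------------
1. Evaluate the scene analytically on a 4x supersampled pixel grid.  Each
   supersample center is mapped image -> phantom frame by inverting the rigid
   pose and then the distortion field (fixed-point iteration), so distortion
   is applied by exact inverse mapping.
2. Through-plane structures (ramp pairs) are rendered with their in-plane
   projected profile: a rectangular slice profile intersecting a plate of
   slope ratio R gives a linear transition of length R x thickness; a phantom
   tilt t makes the two opposed ramps of a pair asymmetric,
   ``L = R x thickness / (1 +- R tan t)``, which keeps the harmonic
   combination of the pair exact.
3. Convolve with a Gaussian PSF of the configured FWHM.
4. Multiply by the (coil-like) bias field, evaluated in the image frame.
5. Block-average down to the output grid, scale to a nominal signal level,
   add noise (Gaussian by default, Rician optional), and round to the
   integer grid used by the DICOM writer so that in-memory and on-disk
   pixel values are identical.

All randomness is driven by ``SimConfig.seed``; the same seed reproduces
bit-identical series.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
from scipy.ndimage import gaussian_filter

from .imageio import QAImage, QASeries
from .layouts import PhantomLayout, StructureSpec, get_layout
from .transforms import RigidTransform

__all__ = [
    "DistortionField",
    "BiasField",
    "SimConfig",
    "GroundTruth",
    "render_series",
    "render_uniform_slab",
    "SimulationError",
]

SUPERSAMPLE = 4  # fixed supersampling factor of the rasterizer

ROD_LEVEL = 0.05  # relative intensity inside a dark grid rod
CHANNEL_LEVEL = 0.10  # relative intensity inside an alignment channel
WEDGE_LEVEL = 0.08  # relative intensity inside a wedge bar


class SimulationError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass(frozen=True)
class DistortionField:
    """Smooth global geometric distortion, phantom frame, displacements in mm.

    ``displacement(p) = (A - I) p + k * |p|^2 * p_hat`` where ``A`` is an
    affine 2x2 matrix (identity by default; encodes scale/shear errors) and
    the radial term with coefficient ``radial_k`` (1/mm) models the
    barrel/pincushion behaviour that dominates at the image periphery.
    """

    affine: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 0.0), (0.0, 1.0))
    radial_k: float = 0.0

    @property
    def is_identity(self) -> bool:
        return self.radial_k == 0.0 and tuple(map(tuple, self.affine)) == (
            (1.0, 0.0),
            (0.0, 1.0),
        )

    def displacement(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        a = np.asarray(self.affine) - np.eye(2)
        d = pts @ a.T
        if self.radial_k != 0.0:
            r = np.hypot(pts[..., 0], pts[..., 1])
            d = d + self.radial_k * r[..., None] * pts
        return d

    def apply(self, pts: np.ndarray) -> np.ndarray:
        """True point -> apparent (distorted) position."""
        return np.asarray(pts, dtype=float) + self.displacement(pts)

    def invert(self, pts: np.ndarray, n_iter: int = 4) -> np.ndarray:
        """Apparent position -> true point, by fixed-point iteration."""
        q = np.asarray(pts, dtype=float)
        p = q.copy()
        for _ in range(n_iter):
            p = q - self.displacement(p)
        return p


@dataclass(frozen=True)
class BiasField:
    """Multiplicative intensity gradient, image frame, ``b(u, v) >= 0``.

    ``b = 1 + gx*u + gy*v + g2*(u^2 + v^2)`` with coefficients in 1/mm and
    1/mm^2.  A phased-array coil on a large FOV is well approximated by the
    linear terms.
    """

    gx: float = 0.0
    gy: float = 0.0
    g2: float = 0.0

    @property
    def is_flat(self) -> bool:
        return self.gx == self.gy == self.g2 == 0.0

    def evaluate(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        return 1.0 + self.gx * u + self.gy * v + self.g2 * (u * u + v * v)


_DEFAULTS = {
    # matrix, pixel spacing (mm), slice thickness (mm), slice gap (mm)
    "INSIGHT": ((300, 300), (1.0, 1.0), 3.0, 2.0),
    "ACR": ((256, 256), (0.98, 0.98), 5.0, 5.0),
}


@dataclass
class SimConfig:
    """Everything needed to render one synthetic phantom series."""

    layout: str | PhantomLayout = "INSIGHT"
    matrix: tuple[int, int] | None = None
    pixel_spacing: tuple[float, float] | None = None
    slice_thickness: float | None = None
    slice_gap: float | None = None
    n_slices: int | None = None
    orientation: str = "axial"
    rotation_deg: float = 0.0
    offset_mm: tuple[float, float] = (0.0, 0.0)
    tilt_deg: float = 0.0
    distortion: DistortionField = field(default_factory=DistortionField)
    blur_fwhm: float = 0.0
    noise_sigma: float = 0.0
    noise_model: str = "gaussian"
    bias: BiasField = field(default_factory=BiasField)
    modulation: float | Mapping[str, float] = 1.0
    hidden_markers: tuple[str, ...] = ()
    slice_offset_mm: float = 0.0
    signal_level: float = 1000.0
    seed: int = 0

    def resolve(self) -> "ResolvedConfig":
        layout = self.layout if isinstance(self.layout, PhantomLayout) else get_layout(self.layout)
        matrix, spacing, thickness, gap = _DEFAULTS[layout.name]
        cfg = ResolvedConfig(
            base=self,
            layout=layout,
            matrix=tuple(self.matrix or matrix),
            pixel_spacing=tuple(self.pixel_spacing or spacing),
            slice_thickness=float(self.slice_thickness if self.slice_thickness is not None else thickness),
            slice_gap=float(self.slice_gap if self.slice_gap is not None else gap),
            n_slices=int(self.n_slices if self.n_slices is not None else layout.n_slices),
        )
        cfg.validate()
        return cfg

    def modulation_for(self, pattern_id: str) -> float:
        if isinstance(self.modulation, Mapping):
            return float(self.modulation.get(pattern_id, 1.0))
        return float(self.modulation)


@dataclass
class ResolvedConfig:
    base: SimConfig
    layout: PhantomLayout
    matrix: tuple[int, int]
    pixel_spacing: tuple[float, float]
    slice_thickness: float
    slice_gap: float
    n_slices: int

    def validate(self) -> None:
        b = self.base
        if b.blur_fwhm < 0 or b.noise_sigma < 0:
            raise SimulationError("blur_fwhm and noise_sigma must be non-negative")
        mods = (
            list(b.modulation.values()) if isinstance(b.modulation, Mapping) else [b.modulation]
        )
        if any(not (0.0 <= m <= 1.0) for m in mods):
            raise SimulationError("modulation must lie in [0, 1]")
        if self.slice_thickness <= 0:
            raise SimulationError("slice thickness must be positive")
        if b.noise_model not in ("gaussian", "rician"):
            raise SimulationError(f"unknown noise model {b.noise_model!r}")
        if b.orientation not in ("axial", "sagittal"):
            raise SimulationError(f"unsupported orientation {b.orientation!r}")
        # every structure, padded by its extent, must land inside the matrix
        pose = RigidTransform(b.rotation_deg, *b.offset_mm)
        half_u = self.matrix[1] * self.pixel_spacing[1] / 2.0
        half_v = self.matrix[0] * self.pixel_spacing[0] / 2.0
        for s in self.layout.structures:
            ext = _structure_extent(s)
            cx, cy = s.center
            corners = [(cx + sx * ext, cy + sy * ext) for sx in (-1, 1) for sy in (-1, 1)]
            img = pose.phantom_to_image_mm(np.array(corners))
            if np.any(np.abs(img[:, 0]) > half_u) or np.any(np.abs(img[:, 1]) > half_v):
                raise SimulationError(f"structure {s.id} falls outside the image matrix")

    def slice_positions(self) -> np.ndarray:
        step = self.slice_thickness + self.slice_gap
        return (np.arange(self.n_slices) - (self.n_slices - 1) / 2.0) * step


def _structure_extent(s: StructureSpec) -> float:
    g = s.geometry
    if s.kind == "grid_line":
        return g["rod_diameter_mm"] / 2.0
    if s.kind in ("periodic_pattern", "hole_array"):
        return max(g["size"]) / 2.0
    if s.kind == "ramp_pair":
        return g["extent_mm"] / 2.0
    if s.kind == "wedge_pair":
        return g["base_length_mm"]
    if s.kind == "alignment_channel":
        return g["length_mm"] / 2.0
    if s.kind == "uniformity_well":
        return g["radius_mm"]
    return 0.0


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """The simulator's record of what it actually rendered."""

    layout_name: str
    pose: tuple[float, float, float]  # angle_deg, tx, ty
    slice_thickness: float
    tilt_deg: float
    ramp_lengths: dict[str, tuple[float, float]]  # ramp id -> (L_top, L_bottom) mm
    grid_displacements: dict[str, tuple[float, float]]  # node id -> distortion (mm)
    marker_visible: dict[str, bool]
    modulation: dict[str, float]
    noise_sigma: float
    blur_fwhm: float
    bias: tuple[float, float, float]

    def displaced_node(self, layout: PhantomLayout, node_id: str) -> np.ndarray:
        """Apparent phantom-frame position of a grid landmark."""
        p = np.asarray(layout.structure(node_id).center, dtype=float)
        return p + np.asarray(self.grid_displacements[node_id])

    def path_length(self, layout: PhantomLayout, path_id: str) -> float:
        """Analytic apparent length of a measurement path under the distortion."""
        path = layout.path(path_id)
        if path.kind == "grid":
            a = self.displaced_node(layout, path.endpoints[0])
            b = self.displaced_node(layout, path.endpoints[1])
        else:
            r = layout.signal_region["radius"]
            th = math.radians(path.angle_deg)
            e = np.array([math.cos(th), math.sin(th)]) * r
            a = e + np.asarray(self.grid_displacements[f"edge:{path_id}:a"])
            b = -e + np.asarray(self.grid_displacements[f"edge:{path_id}:b"])
        return float(np.hypot(*(a - b)))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["pose"] = tuple(d["pose"])
        d["bias"] = tuple(d["bias"])
        d["ramp_lengths"] = {k: tuple(v) for k, v in d["ramp_lengths"].items()}
        d["grid_displacements"] = {k: tuple(v) for k, v in d["grid_displacements"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# scene evaluation
# ---------------------------------------------------------------------------


def _coverage(signed_dist: np.ndarray, h: float) -> np.ndarray:
    """Antialiased inside-coverage from a signed distance (negative = inside).

    A linear ramp of one supersample width keeps rendered edges unbiased:
    binary inside/outside tests at supersample centers would quantize edge
    coverage and shift half-maximum edge positions by up to half a
    supersample pixel.
    """
    return np.clip(0.5 - signed_dist / h, 0.0, 1.0)


def _signal_coverage(layout: PhantomLayout, X: np.ndarray, Y: np.ndarray, h: float) -> np.ndarray:
    reg = layout.signal_region
    if reg["shape"] == "circle":
        sd = np.hypot(X, Y) - reg["radius"]
    else:
        hx, hy = reg["half_size"]
        sd = np.maximum(np.abs(X) - hx, np.abs(Y) - hy)
    return _coverage(sd, h)


def ramp_transition_lengths(thickness: float, slope_ratio: float, tilt_deg: float) -> tuple[float, float]:
    """Apparent transition lengths (L_top, L_bottom) of an opposed ramp pair.

    With tilt t the projected lengths become ``R*thickness / (1 +- R tan t)``,
    so the per-ramp thickness estimates are ``thickness / (1 +- R tan t)`` and
    their harmonic mean recovers the true thickness exactly.
    """
    c = slope_ratio * math.tan(math.radians(tilt_deg))
    if abs(c) >= 1.0:
        raise SimulationError("tilt too large for the configured ramp slope")
    base = slope_ratio * thickness
    return base / (1.0 + c), base / (1.0 - c)


def _blend(I: np.ndarray, cov: np.ndarray, level: float) -> None:
    np.copyto(I, I * (1.0 - cov) + level * cov)


_DISTORTION_MARGIN_MM = 8.0  # window padding for displaced structures


def _make_windower(cfg: ResolvedConfig):
    """Map a phantom-frame bounding box to a supersampled-array window."""
    b = cfg.base
    pose = RigidTransform(b.rotation_deg, *b.offset_mm)
    nr, nc = cfg.matrix
    sr, sc = cfg.pixel_spacing
    ss = SUPERSAMPLE
    r0, c0 = (nr - 1) / 2.0, (nc - 1) / 2.0

    def window(cx: float, cy: float, ext: float) -> tuple[slice, slice]:
        pad = ext + _DISTORTION_MARGIN_MM
        corners = np.array([(cx + sx * pad, cy + sy * pad) for sx in (-1, 1) for sy in (-1, 1)])
        img = pose.phantom_to_image_mm(corners)
        u_lo, u_hi = img[:, 0].min(), img[:, 0].max()
        v_lo, v_hi = img[:, 1].min(), img[:, 1].max()
        # fractional pixel -> supersample index: rr = (p + 0.5) * ss - 0.5
        rr_lo = int(np.floor(((r0 - v_hi / sr) + 0.5) * ss - 0.5))
        rr_hi = int(np.ceil(((r0 - v_lo / sr) + 0.5) * ss - 0.5)) + 1
        cc_lo = int(np.floor(((c0 + u_lo / sc) + 0.5) * ss - 0.5))
        cc_hi = int(np.ceil(((c0 + u_hi / sc) + 0.5) * ss - 0.5)) + 1
        return slice(max(rr_lo, 0), min(rr_hi, nr * ss)), slice(max(cc_lo, 0), min(cc_hi, nc * ss))

    return window


def _render_structure(I_full: np.ndarray, s: StructureSpec, X_full: np.ndarray, Y_full: np.ndarray, cfg: ResolvedConfig, h: float, windower) -> None:
    g = s.geometry
    b = cfg.base
    cx, cy = s.center
    win = windower(cx, cy, _structure_extent(s))
    I, X, Y = I_full[win], X_full[win], Y_full[win]
    if I.size == 0:
        return
    if s.kind == "grid_line":
        sd = np.hypot(X - cx, Y - cy) - g["rod_diameter_mm"] / 2.0
        _blend(I, _coverage(sd, h), ROD_LEVEL)
    elif s.kind == "periodic_pattern":
        sx, sy = g["size"]
        mask = (np.abs(X - cx) <= sx / 2) & (np.abs(Y - cy) <= sy / 2)
        u = (X - cx) if g["direction"] == "fe" else (Y - cy)
        m = b.modulation_for(s.id)
        I[mask] = 1.0 + m * np.cos(2.0 * np.pi * u[mask] / g["period_mm"])
    elif s.kind == "ramp_pair":
        l_top, l_bot = ramp_transition_lengths(cfg.slice_thickness, g["slope_ratio"], b.tilt_deg)
        along_x = g["axis"] == "x"
        u = (X - cx) if along_x else (Y - cy)
        w = (Y - cy) if along_x else (X - cx)
        low = g.get("low_level", 0.12)
        for sign, L in ((+1, l_top), (-1, l_bot)):
            off = sign * g["strip_sep_mm"] / 2.0
            strip = (np.abs(u) <= g["extent_mm"] / 2) & (np.abs(w - off) <= g["strip_width_mm"] / 2)
            frac = np.clip((u[strip] + L / 2.0) / L, 0.0, 1.0)
            I[strip] = 1.0 - (1.0 - low) * frac
    elif s.kind == "wedge_pair":
        d = b.slice_offset_mm
        for sign, length in ((-1, g["base_length_mm"] - d), (+1, g["base_length_mm"] + d)):
            bx = cx + sign * g["bar_offset_mm"]
            sd = np.maximum(np.abs(X - bx) - g["bar_width_mm"] / 2, np.abs(Y - cy) - length / 2)
            _blend(I, _coverage(sd, h), WEDGE_LEVEL)
    elif s.kind == "alignment_channel":
        if s.id in b.hidden_markers:
            return
        along_x = g["axis"] == "x"
        u = (X - cx) if along_x else (Y - cy)
        w = (Y - cy) if along_x else (X - cx)
        sd = np.maximum(np.abs(u) - g["length_mm"] / 2, np.abs(w) - g["width_mm"] / 2)
        _blend(I, _coverage(sd, h), CHANNEL_LEVEL)
    elif s.kind == "hole_array":
        sx, sy = g["size"]
        sd = np.maximum(np.abs(X - cx) - sx / 2, np.abs(Y - cy) - sy / 2)
        _blend(I, _coverage(sd, h), g.get("background_level", 0.1))
        n, pitch = int(g["n"]), g["pitch_mm"]
        hr = g["hole_diameter_mm"] / 2.0
        offs = (np.arange(n) - (n - 1) / 2.0) * pitch
        for ox in offs:
            for oy in offs:
                _blend(I, _coverage(np.hypot(X - cx - ox, Y - cy - oy) - hr, h), 1.0)
        rx, ry = g["ref_hole_offset"]
        rr = g["ref_hole_diameter_mm"] / 2.0
        _blend(I, _coverage(np.hypot(X - cx - rx, Y - cy - ry) - rr, h), 1.0)
    # uniformity_well: deliberately nothing - the well IS uniform signal


def _supersampled_phantom_coords(cfg: ResolvedConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Phantom-frame coordinates of every supersample center, plus image mm."""
    b = cfg.base
    nr, nc = cfg.matrix
    sr, sc = cfg.pixel_spacing
    ss = SUPERSAMPLE
    rr = (np.arange(nr * ss) + 0.5) / ss - 0.5  # fractional pixel rows
    cc = (np.arange(nc * ss) + 0.5) / ss - 0.5
    r0, c0 = (nr - 1) / 2.0, (nc - 1) / 2.0
    v = (r0 - rr) * sr
    u = (cc - c0) * sc
    U, V = np.meshgrid(u, v)
    pose = RigidTransform(b.rotation_deg, *b.offset_mm)
    pts = np.column_stack([U.ravel(), V.ravel()])
    ph = pose.image_mm_to_phantom(pts)
    if not b.distortion.is_identity:
        ph = b.distortion.invert(ph)
    X = ph[:, 0].reshape(U.shape)
    Y = ph[:, 1].reshape(U.shape)
    return X, Y, U, V


def _finalize(field01: np.ndarray, U: np.ndarray, V: np.ndarray, cfg: ResolvedConfig, rng: np.random.Generator) -> np.ndarray:
    b = cfg.base
    ss = SUPERSAMPLE
    if b.blur_fwhm > 0:
        sig = b.blur_fwhm / 2.354820045
        field01 = gaussian_filter(
            field01, sigma=(sig / (cfg.pixel_spacing[0] / ss), sig / (cfg.pixel_spacing[1] / ss))
        )
    if not b.bias.is_flat:
        field01 = field01 * b.bias.evaluate(U, V)
    nr, nc = cfg.matrix
    out = field01.reshape(nr, ss, nc, ss).mean(axis=(1, 3)) * b.signal_level
    if b.noise_sigma > 0:
        sigma = b.noise_sigma * b.signal_level
        if b.noise_model == "gaussian":
            out = out + rng.normal(0.0, sigma, out.shape)
        else:
            out = np.hypot(out + rng.normal(0.0, sigma, out.shape), rng.normal(0.0, sigma, out.shape))
    return np.clip(np.round(out), 0, 65535)


def render_series(config: SimConfig) -> tuple[QASeries, GroundTruth]:
    """Render a full synthetic series and its ground-truth record."""
    cfg = config.resolve()
    b = cfg.base
    layout = cfg.layout
    X, Y, U, V = _supersampled_phantom_coords(cfg)
    h = max(cfg.pixel_spacing) / SUPERSAMPLE  # antialiasing ramp width
    base = _signal_coverage(layout, X, Y, h)

    windower = _make_windower(cfg)
    images = []
    positions = cfg.slice_positions()
    for i in range(cfg.n_slices):
        I = base.copy()
        for s in layout.structures_on_slice(i):
            _render_structure(I, s, X, Y, cfg, h, windower)
        rng = np.random.default_rng(int(b.seed) * 1000003 + i)
        pixels = _finalize(I, U, V, cfg, rng)
        images.append(
            QAImage(
                pixels=pixels,
                pixel_spacing=cfg.pixel_spacing,
                slice_position=float(positions[i]),
                orientation=b.orientation,
            )
        )

    # ground truth
    displacements: dict[str, tuple[float, float]] = {}
    for s in layout.structures:
        if s.kind == "grid_line":
            d = b.distortion.displacement(np.array([s.center]))[0]
            displacements[s.id] = (float(d[0]), float(d[1]))
    for p in layout.paths:
        if p.kind == "edge":
            r = layout.signal_region["radius"]
            th = math.radians(p.angle_deg)
            e = np.array([math.cos(th), math.sin(th)]) * r
            da = b.distortion.displacement(np.array([e]))[0]
            db = b.distortion.displacement(np.array([-e]))[0]
            displacements[f"edge:{p.path_id}:a"] = (float(da[0]), float(da[1]))
            displacements[f"edge:{p.path_id}:b"] = (float(db[0]), float(db[1]))
    ramp_lengths = {
        s.id: ramp_transition_lengths(cfg.slice_thickness, s.geometry["slope_ratio"], b.tilt_deg)
        for s in layout.structures
        if s.kind == "ramp_pair"
    }
    truth = GroundTruth(
        layout_name=layout.name,
        pose=(b.rotation_deg, b.offset_mm[0], b.offset_mm[1]),
        slice_thickness=cfg.slice_thickness,
        tilt_deg=b.tilt_deg,
        ramp_lengths=ramp_lengths,
        grid_displacements=displacements,
        marker_visible={
            s.id: s.id not in b.hidden_markers
            for s in layout.structures
            if s.kind == "alignment_channel"
        },
        modulation={
            s.id: b.modulation_for(s.id)
            for s in layout.structures
            if s.kind == "periodic_pattern"
        },
        noise_sigma=b.noise_sigma,
        blur_fwhm=b.blur_fwhm,
        bias=(b.bias.gx, b.bias.gy, b.bias.g2),
    )
    series = QASeries(
        images=images,
        slice_thickness=cfg.slice_thickness,
        slice_gap=cfg.slice_gap,
        weighting="synthetic",
    )
    return series, truth


def render_uniform_slab(config: SimConfig) -> QAImage:
    """Structure-free signal slab with bias and noise only."""
    cfg = config.resolve()
    b = cfg.base
    X, Y, U, V = _supersampled_phantom_coords(cfg)
    I = _signal_coverage(cfg.layout, X, Y, max(cfg.pixel_spacing) / SUPERSAMPLE)
    rng = np.random.default_rng(int(b.seed) * 1000003)
    pixels = _finalize(I, U, V, cfg, rng)
    return QAImage(pixels=pixels, pixel_spacing=cfg.pixel_spacing, orientation=b.orientation)
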