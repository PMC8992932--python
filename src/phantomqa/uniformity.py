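"""Intensity-uniformity metrics.

Two methods, matching the two phantoms:

* Percent integral uniformity (PIU) for the ACR phantom's large uniform
  region: find the 1 cm^2 circular ROIs with the greatest and lowest mean
  signal and report ``PIU = 100 * (1 - (SI_high - SI_low)/(SI_high + SI_low))``.
  The manual window/level hunt for the extreme ROIs is automated as an
  exhaustive search: a circular mean filter is evaluated at every pixel
  whose ROI fits inside the (eroded) uniform region.

* The multi-ROI method for the large-FOV phantom, which lacks a single
  large uniform region: the average of the standard deviations of four
  15 cm^2 circular ROIs in uniform signal-producing regions, expressed as a
  percent of the average signal intensity.

Both metrics are ratios and therefore invariant under global intensity
scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.signal import fftconvolve

from .imageio import QAImage
from .layouts import PhantomLayout
from .geometry import RegistrationResult

__all__ = [
    "UniformityResult",
    "compute_piu",
    "multi_roi_uniformity",
    "acr_uniformity",
    "insight_uniformity",
    "piu_search_bruteforce",
]

PIU_ROI_AREA_CM2 = 1.0
MULTI_ROI_AREA_CM2 = 15.0
_MIN_MASK_AREA_CM2 = 10.0


@dataclass(frozen=True)
class UniformityResult:
    method: str  # "PIU" | "multiROI"
    si_high: float | None = None
    si_low: float | None = None
    piu: float | None = None
    roi_stats: tuple[tuple[str, float, float], ...] = ()  # (roi id, mean, std)
    avg_std_percent: float | None = None
    warning: str | None = None


def _disk_kernel(pixel_spacing: tuple[float, float], area_cm2: float) -> np.ndarray:
    """Boolean disk of the requested area; radius rounded to 0.1 mm."""
    radius = round(math.sqrt(area_cm2 * 100.0 / math.pi), 1)
    sr, sc = pixel_spacing
    nr = int(radius / sr)  # tight bounding box: no all-False outer ring
    nc = int(radius / sc)
    rr, cc = np.mgrid[-nr : nr + 1, -nc : nc + 1]
    return (rr * sr) ** 2 + (cc * sc) ** 2 <= radius**2


def compute_piu(image: QAImage, uniform_region_mask: np.ndarray) -> UniformityResult:
    """Percent integral uniformity over a uniform-region mask.

    The circular 1 cm^2 mean filter is evaluated (via FFT convolution) at
    every pixel whose full ROI lies inside the mask; the extreme means give
    SI_high and SI_low.
    """
    mask = np.asarray(uniform_region_mask, dtype=bool)
    sr, sc = image.pixel_spacing
    if mask.sum() * sr * sc < _MIN_MASK_AREA_CM2 * 100.0:
        raise ValueError("uniform region mask smaller than 10 cm^2")
    kernel = _disk_kernel(image.pixel_spacing, PIU_ROI_AREA_CM2)
    valid = binary_erosion(mask, structure=kernel)
    if not valid.any():
        raise ValueError("no ROI position fits inside the mask")
    means = fftconvolve(image.pixels, kernel[::-1, ::-1].astype(float), mode="same") / kernel.sum()
    vals = means[valid]
    si_high = float(vals.max())
    si_low = float(vals.min())
    piu = 100.0 * (1.0 - (si_high - si_low) / (si_high + si_low))
    return UniformityResult(method="PIU", si_high=si_high, si_low=si_low, piu=piu)


def piu_search_bruteforce(image: QAImage, uniform_region_mask: np.ndarray) -> tuple[float, float]:
    """Reference implementation of the extreme-ROI search (per-pixel loops).

    Independent oracle for :func:`compute_piu`; quadratic time, use on small
    images only.
    """
    mask = np.asarray(uniform_region_mask, dtype=bool)
    kernel = _disk_kernel(image.pixel_spacing, PIU_ROI_AREA_CM2)
    kr, kc = (np.array(kernel.shape) - 1) // 2
    hi, lo = -np.inf, np.inf
    nr, nc = image.shape
    for r in range(nr):
        for c in range(nc):
            rs, cs = r - kr, c - kc
            if rs < 0 or cs < 0 or rs + kernel.shape[0] > nr or cs + kernel.shape[1] > nc:
                continue
            sub = mask[rs : rs + kernel.shape[0], cs : cs + kernel.shape[1]]
            if not np.all(sub[kernel]):
                continue
            m = float(image.pixels[rs : rs + kernel.shape[0], cs : cs + kernel.shape[1]][kernel].mean())
            hi, lo = max(hi, m), min(lo, m)
    return hi, lo


def multi_roi_uniformity(
    image: QAImage,
    rois: list[tuple[str, tuple[float, float], float]],
) -> UniformityResult:
    """Average standard deviation over circular ROIs as percent of mean signal.

    ``rois`` is a list of (roi id, (row, col) center in pixels, radius mm).
    ROIs that overlap visible structure (detected by edge density) trigger a
    quality warning but are still reported.
    """
    sr, sc = image.pixel_spacing
    rr, cc = np.mgrid[0 : image.shape[0], 0 : image.shape[1]]
    stats = []
    warnings = []
    for roi_id, (r0, c0), radius in rois:
        m = ((rr - r0) * sr) ** 2 + ((cc - c0) * sc) ** 2 <= radius**2
        if not m.any():
            raise ValueError(f"ROI {roi_id} lies outside the image")
        vals = image.pixels[m]
        stats.append((roi_id, float(vals.mean()), float(vals.std())))
        # structure check: rods/plates produce pixels far off the ROI median,
        # which plain noise (a few percent of signal) essentially never does
        med = float(np.median(vals))
        if med > 0 and float(np.mean(np.abs(vals - med) > 0.15 * med)) > 0.02:
            warnings.append(roi_id)
    mean_of_means = float(np.mean([s[1] for s in stats]))
    avg_std = float(np.mean([s[2] for s in stats]))
    return UniformityResult(
        method="multiROI",
        roi_stats=tuple(stats),
        avg_std_percent=100.0 * avg_std / mean_of_means,
        warning=(
            f"ROIs overlapping structure: {', '.join(warnings)}" if warnings else None
        ),
    )


def acr_uniformity(image: QAImage, layout: PhantomLayout, reg: RegistrationResult, margin_mm: float = 10.0) -> UniformityResult:
    """PIU over the large uniform region, a margin inside the phantom outline.

    The margin keeps the extreme-ROI search away from the partial-volume
    boundary pixels, as a human operator would.
    """
    radius = layout.signal_region["radius"] - margin_mm
    rr, cc = np.mgrid[0 : image.shape[0], 0 : image.shape[1]]
    sr, sc = image.pixel_spacing
    center = reg.transform.phantom_to_pixel(image, np.zeros((1, 2)))[0]
    mask = ((rr - center[0]) * sr) ** 2 + ((cc - center[1]) * sc) ** 2 <= radius**2
    return compute_piu(image, mask)


def insight_uniformity(image: QAImage, layout: PhantomLayout, reg: RegistrationResult) -> UniformityResult:
    """Multi-ROI uniformity at the layout's four uniform wells."""
    wells = [s for s in layout.structures if s.kind == "uniformity_well"]
    radius = math.sqrt(MULTI_ROI_AREA_CM2 * 100.0 / math.pi)
    rois = []
    for s in wells:
        pix = reg.transform.phantom_to_pixel(image, np.asarray(s.center, dtype=float)[None, :])[0]
        rois.append((s.id, (float(pix[0]), float(pix[1])), radius))
    return multi_roi_uniformity(image, rois)
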