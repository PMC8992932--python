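"""Rigid in-plane mapping between the phantom frame and image pixels.

The phantom pose in an image is a rotation ``angle_deg`` (counter-clockwise)
plus a translation ``(tx, ty)`` of the phantom origin relative to the image
center, both in mm of the physical image plane.  Image-plane mm coordinates
``(u, v)`` have ``+u`` along increasing column and ``+v`` along decreasing
row (so the phantom's anterior axis points "up" in the displayed array).
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np

__all__ = ["RigidTransform"]


@dataclass(frozen=True)
class RigidTransform:
    angle_deg: float = 0.0
    tx: float = 0.0
    ty: float = 0.0

    def _rot(self) -> np.ndarray:
        a = math.radians(self.angle_deg)
        return np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])

    # -- phantom mm <-> image-plane mm ------------------------------------
    def phantom_to_image_mm(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return pts @ self._rot().T + np.array([self.tx, self.ty])

    def image_mm_to_phantom(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return (pts - np.array([self.tx, self.ty])) @ self._rot()

    # -- image-plane mm <-> pixel indices ----------------------------------
    @staticmethod
    def image_mm_to_pixel(image, pts_mm: np.ndarray) -> np.ndarray:
        """(u, v) mm -> (row, col) float pixel indices, pixel-center convention."""
        pts_mm = np.atleast_2d(np.asarray(pts_mm, dtype=float))
        r0, c0 = image.center_pixel()
        sr, sc = image.pixel_spacing
        rows = r0 - pts_mm[:, 1] / sr
        cols = c0 + pts_mm[:, 0] / sc
        return np.column_stack([rows, cols])

    @staticmethod
    def pixel_to_image_mm(image, pix: np.ndarray) -> np.ndarray:
        pix = np.atleast_2d(np.asarray(pix, dtype=float))
        r0, c0 = image.center_pixel()
        sr, sc = image.pixel_spacing
        u = (pix[:, 1] - c0) * sc
        v = (r0 - pix[:, 0]) * sr
        return np.column_stack([u, v])

    # -- composites --------------------------------------------------------
    def phantom_to_pixel(self, image, pts: np.ndarray) -> np.ndarray:
        return self.image_mm_to_pixel(image, self.phantom_to_image_mm(pts))

    def pixel_to_phantom(self, image, pix: np.ndarray) -> np.ndarray:
        return self.image_mm_to_phantom(self.pixel_to_image_mm(image, pix))
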