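"""Region-of-interest specifications and rasterization.

ROIs are declared in pixel coordinates (0-based row/col) as rectangles,
circles, or explicit boolean masks, and rasterized onto a frame shape on
demand.  Pixel membership for circles uses the pixel-center convention
shared with the rest of the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import err


@dataclass(frozen=True)
class RoiSpec:
    """A region of interest.

    ``shape`` is one of:

    * ``"rectangle"`` -- params ``(row0, col0, height, width)`` in pixels;
    * ``"circle"``    -- params ``(row_center, col_center, radius)`` in
      pixels (fractional values allowed);
    * ``"mask"``      -- params is a boolean ``H x W`` array.
    """

    shape: str
    params: tuple | np.ndarray

    @staticmethod
    def rectangle(row0: int, col0: int, height: int, width: int) -> "RoiSpec":
        return RoiSpec("rectangle", (row0, col0, height, width))

    @staticmethod
    def circle(row_center: float, col_center: float, radius: float) -> "RoiSpec":
        return RoiSpec("circle", (row_center, col_center, radius))

    @staticmethod
    def mask(mask: np.ndarray) -> "RoiSpec":
        return RoiSpec("mask", np.asarray(mask, dtype=bool))

    def rasterize(self, frame_shape: tuple[int, int]) -> np.ndarray:
        """Boolean membership mask of this ROI on ``frame_shape``.

        Raises ``empty_roi`` if no pixel falls inside the region after
        rasterization.
        """
        h, w = frame_shape
        if self.shape == "rectangle":
            r0, c0, rh, rw = self.params
            if rh <= 0 or rw <= 0:
                raise err("empty_roi", "rectangle with non-positive extent")
            if r0 < 0 or c0 < 0 or r0 + rh > h or c0 + rw > w:
                raise err("empty_roi", "rectangle extends outside the image")
            m = np.zeros(frame_shape, dtype=bool)
            m[int(r0): int(r0 + rh), int(c0): int(c0 + rw)] = True
        elif self.shape == "circle":
            rc, cc, rad = self.params
            if rad <= 0:
                raise err("empty_roi", "circle with non-positive radius")
            rows = np.arange(h)[:, None] + 0.5
            cols = np.arange(w)[None, :] + 0.5
            m = (rows - (rc + 0.5)) ** 2 + (cols - (cc + 0.5)) ** 2 <= rad ** 2
        elif self.shape == "mask":
            m = np.asarray(self.params, dtype=bool)
            if m.shape != tuple(frame_shape):
                raise err("empty_roi", f"mask shape {m.shape} != frame {frame_shape}")
            m = m.copy()
        else:
            raise err("invalid_config", f"unknown ROI shape {self.shape!r}")
        if not m.any():
            raise err("empty_roi")
        return m


def circle_roi_um(x_um: float, y_um: float, radius_um: float, pixel_size: float) -> RoiSpec:
    """Circle ROI from physical coordinates (x=col, y=row, in um)."""
    return RoiSpec.circle(
        y_um / pixel_size - 0.5, x_um / pixel_size - 0.5, radius_um / pixel_size
    )


def annulus_mask(
    frame_shape: tuple[int, int],
    center_um: tuple[float, float],
    r_inner_um: float,
    r_outer_um: float,
    pixel_size: float,
) -> np.ndarray:
    """Boolean annulus ``r_inner <= r <= r_outer`` around a physical center."""
    h, w = frame_shape
    x = (np.arange(w)[None, :] + 0.5) * pixel_size
    y = (np.arange(h)[:, None] + 0.5) * pixel_size
    r = np.hypot(x - center_um[0], y - center_um[1])
    return (r >= r_inner_um) & (r <= r_outer_um)


def disc_mask(
    frame_shape: tuple[int, int],
    center_um: tuple[float, float],
    radius_um: float,
    pixel_size: float,
) -> np.ndarray:
    """Boolean disc ``r <= radius`` around a physical center."""
    return annulus_mask(frame_shape, center_um, 0.0, radius_um, pixel_size)
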