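"""Low-level raster geometry shared across modules.

Coordinate convention (package-wide): pixel centers sit at integer
coordinates, origin at the top-left pixel center, x increases rightward
(columns), y increases downward (rows), 0-based. Polygons live in the same
frame.
"""

from __future__ import annotations

import numpy as np

__all__ = ["polygon_mask", "rotation_matrix_deg"]


def polygon_mask(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a simple polygon: pixel is set iff its center lies inside
    the polygon under the even-odd rule.

    Parameters
    ----------
    vertices : (N, 2) array of (x, y) vertex coordinates, N >= 3.
    shape : (height, width) of the output mask.

    Returns
    -------
    bool array of ``shape``.
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise ValueError(
            f"degenerate polygon: need >=3 (x, y) vertices, got shape {verts.shape}"
        )
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    xs = np.arange(w, dtype=float)
    ys = np.arange(h, dtype=float)

    x1 = verts[:, 0]
    y1 = verts[:, 1]
    x2 = np.roll(x1, -1)
    y2 = np.roll(y1, -1)

    # Even-odd ray casting: horizontal ray toward -x from each pixel center.
    # The half-open test (y1 > yc) != (y2 > yc) counts each crossing once.
    for ex1, ey1, ex2, ey2 in zip(x1, y1, x2, y2):
        if ey1 == ey2:
            continue  # horizontal edge never crosses a horizontal ray
        crossing_rows = (ey1 > ys) != (ey2 > ys)
        if not crossing_rows.any():
            continue
        yc = ys[crossing_rows]
        x_int = ex1 + (yc - ey1) * (ex2 - ex1) / (ey2 - ey1)
        mask[crossing_rows] ^= xs[None, :] < x_int[:, None]
    return mask


def rotation_matrix_deg(angle_deg: float) -> np.ndarray:
    """2x2 rotation matrix for the (x, y) frame with y pointing down.

    Positive angles rotate x toward y (clockwise on screen).
    """
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s], [s, c]])
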