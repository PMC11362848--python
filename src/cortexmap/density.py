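"""Objects-per-mm² density heatmaps from centroid lists.

A centroid list becomes an integer per-pixel count map; convolving it with a
binary disk kernel and dividing by the kernel's physical area yields a local
density in objects per mm² — a single isolated object reads as one object
per kernel area on the plateau around it. Near the frame border the in-image
kernel fraction shrinks; by default each pixel is renormalized by that
fraction so rim densities stay locally unbiased (the renormalization trades
exact global mass conservation, which holds in the interior-kernel regime,
for an unbiased level estimate at the rim).

Multi-resolution bookkeeping lives in :class:`PipelineScales`: segmentation
happens on a working grid (typically the scan downsampled 0.5×0.5), density
maps are aggregated onto a coarse map grid (e.g. another 0.0125×0.0125) by
block-mean, which preserves the map-wide mean density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import oaconvolve

__all__ = [
    "DensityMap",
    "PipelineScales",
    "disk_kernel",
    "centroid_count_map",
    "density_from_centroids",
    "downsample_map",
]

MARKERS = ("nuclei", "NeuN", "Abeta", "pTau", "Iba1")


@dataclass(frozen=True)
class PipelineScales:
    """Pixel geometry of the working and map grids.

    ``um_per_px`` is the physical pixel size on the grid the count map lives
    on (explicit config: the printed scales of scanner exports are not always
    self-consistent, so nothing is inferred). ``map_pixel_um`` defaults to
    ``um_per_px / map_downsample``.
    """

    um_per_px: float = 0.92
    kernel_radius_px: int = 200
    primary_downsample: float = 0.5
    map_downsample: float = 0.0125
    map_pixel_um: float | None = None

    def __post_init__(self):
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if self.kernel_radius_px < 1:
            raise ValueError("kernel_radius_px must be >= 1")
        for name in ("primary_downsample", "map_downsample"):
            f = getattr(self, name)
            if not 0.0 < f <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {f}")

    @property
    def map_pixel_um_side(self) -> float:
        if self.map_pixel_um is not None:
            return float(self.map_pixel_um)
        return self.um_per_px / self.map_downsample

    @property
    def map_pixel_area_um2(self) -> float:
        """Area of one map pixel; a 73 µm side gives 5329 µm²."""
        return self.map_pixel_um_side**2

    @property
    def kernel_pixel_count(self) -> int:
        return int(disk_kernel(self.kernel_radius_px).sum())

    @property
    def kernel_area_mm2(self) -> float:
        """Physical area of the disk kernel on the working grid."""
        return self.kernel_pixel_count * (self.um_per_px * 1e-3) ** 2


@dataclass
class DensityMap:
    """2D grid of local object densities (objects per mm²)."""

    values: np.ndarray  # float (H, W), >= 0, finite
    um_per_px: float
    kernel_radius_px: int
    marker: str = "nuclei"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.isfinite(v).all():
            raise ValueError("densities must be finite")
        if (v < 0).any():
            raise ValueError("densities must be >= 0")
        self.values = v

    @property
    def pixel_area_mm2(self) -> float:
        return (self.um_per_px * 1e-3) ** 2

    @property
    def total_objects(self) -> float:
        """Mean density × total map area; equals the centroid count when all
        kernel mass lies inside the frame."""
        return float(self.values.sum() * self.pixel_area_mm2)


def disk_kernel(radius_px: int) -> np.ndarray:
    """Binary disk rasterized by the center-in-circle test dx²+dy² <= r²."""
    if radius_px < 1:
        raise ValueError("kernel radius must be >= 1 px")
    r = int(radius_px)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (xx * xx + yy * yy) <= r * r


def centroid_count_map(centroids, shape: tuple[int, int]) -> np.ndarray:
    """Integer raster of per-pixel centroid counts (sum = len(centroids))."""
    h, w = shape
    counts = np.zeros((h, w), dtype=np.int64)
    pts = np.asarray(centroids, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return counts
    cols = np.rint(pts[:, 0]).astype(int)
    rows = np.rint(pts[:, 1]).astype(int)
    bad = (cols < 0) | (cols >= w) | (rows < 0) | (rows >= h)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(f"centroid {tuple(pts[i])} outside raster of shape {shape}")
    np.add.at(counts, (rows, cols), 1)
    return counts


def density_from_centroids(
    count_map: np.ndarray,
    scales: PipelineScales,
    marker: str = "nuclei",
    renormalize_edges: bool = True,
) -> DensityMap:
    """Disk-kernel density estimate in objects per mm².

    The count map is convolved with a binary disk of ``kernel_radius_px``
    and divided by the kernel's physical area (pixel count × pixel area).
    With ``renormalize_edges`` the divisor at each pixel uses only the
    in-frame kernel fraction, so densities near the border are not biased
    low by the zero padding.
    """
    counts = np.asarray(count_map, dtype=float)
    kernel = disk_kernel(scales.kernel_radius_px).astype(float)
    if kernel.shape[0] > counts.shape[0] or kernel.shape[1] > counts.shape[1]:
        raise ValueError(
            f"kernel of {kernel.shape} exceeds the {counts.shape} map"
        )
    conv = oaconvolve(counts, kernel, mode="same")
    conv = np.clip(conv, 0.0, None)  # FFT round-off can dip epsilon-negative
    px_area_mm2 = (scales.um_per_px * 1e-3) ** 2
    k_px = kernel.sum()
    if renormalize_edges:
        frac = oaconvolve(np.ones_like(counts), kernel, mode="same") / k_px
        frac = np.clip(frac, 1.0 / k_px, 1.0)
        dens = conv / (frac * k_px * px_area_mm2)
    else:
        dens = conv / (k_px * px_area_mm2)
    return DensityMap(
        values=dens,
        um_per_px=scales.um_per_px,
        kernel_radius_px=scales.kernel_radius_px,
        marker=marker,
    )


def _block_means(values: np.ndarray, block: int) -> np.ndarray:
    """Exact block means including partial edge blocks (no zero-padding bias)."""
    h, w = values.shape
    row_idx = np.arange(0, h, block)
    col_idx = np.arange(0, w, block)
    sums = np.add.reduceat(np.add.reduceat(values, row_idx, axis=0), col_idx, axis=1)
    rlen = np.diff(np.append(row_idx, h))
    clen = np.diff(np.append(col_idx, w))
    return sums / np.outer(rlen, clen)


def downsample_map(dmap: DensityMap, factor: float) -> DensityMap:
    """Block-mean aggregation by ``factor`` in (0, 1); mean density preserved.

    ``factor`` must be (close to) the reciprocal of an integer block size,
    e.g. 0.5 or 0.0125. Edge blocks shorter than the block size are averaged
    over their actual extent.
    """
    if not 0.0 < factor < 1.0:
        raise ValueError(f"downsample factor must lie in (0, 1), got {factor}")
    block = int(round(1.0 / factor))
    if abs(1.0 / factor - block) > 1e-9 * block:
        raise ValueError(f"factor {factor} is not a reciprocal integer block size")
    h, w = dmap.values.shape
    if h < 1 or w < 1 or (h + block - 1) // block < 1 or (w + block - 1) // block < 1:
        raise ValueError("downsampled map would be smaller than 1x1")
    return DensityMap(
        values=_block_means(dmap.values, block),
        um_per_px=dmap.um_per_px * block,
        kernel_radius_px=dmap.kernel_radius_px,
        marker=dmap.marker,
    )
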