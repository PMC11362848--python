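"""File formats: slide rasters, centroid tables, label maps, density maps.

Images are exchanged as PNG (8-bit) or TIFF (8-bit RGB in, 32-bit float
density out); centroids and stain-reference pixel marks as tiny CSVs with a
``class,x,y`` header; density maps additionally get an 8-bit grayscale PNG
preview for eyeballing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .density import DensityMap
from .synthetic import SlideImage

__all__ = [
    "read_slide",
    "write_slide",
    "write_centroids_csv",
    "read_centroids_csv",
    "read_stain_reference_csv",
    "write_label_map_png",
    "write_density_tiff",
    "read_density_tiff",
    "write_density_preview_png",
]

#: indexed-PNG palette for label maps (background, unstained, hema, immuno)
_LABEL_PALETTE = [255, 255, 255, 230, 220, 210, 70, 60, 130, 130, 80, 40]


def read_slide(path, um_per_px: float, marker: str = "") -> SlideImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        rgb = tifffile.imread(path)
    else:
        rgb = np.asarray(Image.open(path).convert("RGB"))
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"{path} is not an RGB raster (shape {rgb.shape})")
    return SlideImage(rgb=rgb.astype(np.uint8), um_per_px=um_per_px, marker=marker)


def write_slide(image: SlideImage, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.rgb, photometric="rgb")
    else:
        Image.fromarray(image.rgb).save(path)


def write_centroids_csv(path, **centroids_by_class) -> None:
    """Write one row per centroid: ``class,x,y``; e.g.
    ``write_centroids_csv(p, nucleus=arr1, particle=arr2)``."""
    frames = []
    for cls, pts in centroids_by_class.items():
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        frames.append(pd.DataFrame({"class": cls, "x": pts[:, 0], "y": pts[:, 1]}))
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["class", "x", "y"]
    )
    out.to_csv(path, index=False, float_format="%.3f")


def read_centroids_csv(path) -> dict:
    df = pd.read_csv(path)
    return {
        cls: sub[["x", "y"]].to_numpy(dtype=float)
        for cls, sub in df.groupby("class", sort=True)
    }


def read_stain_reference_csv(path) -> tuple[list, list]:
    """Operator-marked stain pixels as (immuno_coords, hema_coords).

    CSV columns ``class,x,y`` with class ∈ {immunostain, hematoxylin}.
    """
    df = pd.read_csv(path)
    known = {"immunostain", "hematoxylin"}
    bad = set(df["class"].unique()) - known
    if bad:
        raise ValueError(f"unknown stain classes {sorted(bad)}; expected {sorted(known)}")
    sel = lambda c: df.loc[df["class"] == c, ["x", "y"]].to_numpy(dtype=int).tolist()
    return sel("immunostain"), sel("hematoxylin")


def write_label_map_png(labels: np.ndarray, path) -> None:
    img = Image.fromarray(np.asarray(labels, dtype=np.uint8), mode="P")
    img.putpalette(_LABEL_PALETTE)
    img.save(path)


def write_density_tiff(dmap: DensityMap, path) -> None:
    tifffile.imwrite(
        path,
        dmap.values.astype(np.float32),
        metadata={
            "um_per_px": dmap.um_per_px,
            "kernel_radius_px": dmap.kernel_radius_px,
            "marker": dmap.marker,
            "units": "objects per mm^2",
        },
    )


def read_density_tiff(path) -> DensityMap:
    with tifffile.TiffFile(path) as tf:
        values = tf.asarray().astype(float)
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    return DensityMap(
        values=values,
        um_per_px=float(meta.get("um_per_px", 1.0)),
        kernel_radius_px=int(meta.get("kernel_radius_px", 1)),
        marker=str(meta.get("marker", "nuclei")),
    )


def write_density_preview_png(dmap: DensityMap, path) -> None:
    v = dmap.values
    hi = v.max()
    scaled = (255 * (v / hi)).astype(np.uint8) if hi > 0 else np.zeros_like(v, np.uint8)
    Image.fromarray(scaled, mode="L").save(path)
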