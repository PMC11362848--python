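"""Rigid serial-section alignment, annotation masks and cortex vectors.

Serial sections of one tissue block share a tissue outline up to a small
rotation and shift; the tissue-on-background masks therefore serve as the
registration backbone. :func:`rigid_register` recovers the rigid transform
(rotation + translation about the image center) that best overlays a moving
mask onto a fixed (reference, typically NeuN) mask by minimizing the mean
squared difference of smoothed masks, initialized from the mask centroids
and principal-axis angles with a small multi-start over rotations.

Annotation polygons (cortex, tumor, slide outline) become binary masks by
the pixel-center even-odd rule, and the aligned density maps restricted to
cortex ∧ tissue are flattened into a per-pixel table, one row per cortical
map pixel with one density column per marker.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import affine_transform, gaussian_filter
from scipy.optimize import minimize

from ._geometry import polygon_mask, rotation_matrix_deg
from .density import DensityMap

__all__ = [
    "RigidTransform",
    "RegistrationResult",
    "AnnotationSet",
    "InsufficientBackboneError",
    "GridMismatchError",
    "rigid_register",
    "apply_transform",
    "polygon_to_mask",
    "extract_cortex_vectors",
    "CORTEX_TABLE_COLUMNS",
    "MARKER_COLUMN",
]


class InsufficientBackboneError(RuntimeError):
    """A registration mask has too little foreground to serve as backbone."""


class GridMismatchError(ValueError):
    """Maps passed to extraction do not share one coregistered grid."""


@dataclass(frozen=True)
class RigidTransform:
    """p' = R(p − c) + c + t in (x, y) pixel coordinates (y down).

    Positive rotation turns x toward y (clockwise on screen). The rotation
    is normalized to (−180, 180].
    """

    rotation_deg: float
    tx_px: float
    ty_px: float
    center: tuple = (0.0, 0.0)

    def __post_init__(self):
        rot = (self.rotation_deg + 180.0) % 360.0 - 180.0
        if rot == -180.0:
            rot = 180.0
        object.__setattr__(self, "rotation_deg", float(rot))

    @classmethod
    def identity(cls, center=(0.0, 0.0)) -> "RigidTransform":
        return cls(0.0, 0.0, 0.0, center=tuple(center))

    def _Ab(self) -> tuple[np.ndarray, np.ndarray]:
        A = rotation_matrix_deg(self.rotation_deg)
        c = np.asarray(self.center, dtype=float)
        b = c + np.array([self.tx_px, self.ty_px]) - A @ c
        return A, b

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        A, b = self._Ab()
        return pts @ A.T + b

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``first``, then ``self``."""
        A1, b1 = first._Ab()
        A2, b2 = self._Ab()
        A = A2 @ A1
        b = A2 @ b1 + b2
        return self._from_matrix(A, b, self.center)

    def invert(self) -> "RigidTransform":
        A, b = self._Ab()
        return self._from_matrix(A.T, -A.T @ b, self.center)

    @staticmethod
    def _from_matrix(A: np.ndarray, b: np.ndarray, center) -> "RigidTransform":
        rot = float(np.degrees(np.arctan2(A[1, 0], A[0, 0])))
        c = np.asarray(center, dtype=float)
        t = A @ c + b - c
        return RigidTransform(rot, float(t[0]), float(t[1]), center=tuple(c))


@dataclass(frozen=True)
class RegistrationResult:
    transform: RigidTransform
    overlap_before: float  # Dice of the unaligned masks
    overlap_after: float  # Dice after applying the transform


@dataclass
class AnnotationSet:
    """Labeled annotation polygons in slide coordinates.

    ``polygons`` is a list of (label, (N, 2) vertex array) pairs with labels
    from {"cortex", "tumor", "slide-outline"}; ``scale_to_map`` converts the
    vertex coordinates onto the target map grid.
    """

    polygons: list
    scale_to_map: float = 1.0

    def __post_init__(self):
        cleaned = []
        for label, verts in self.polygons:
            v = np.asarray(verts, dtype=float)
            if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
                raise ValueError(
                    f"degenerate '{label}' polygon: need >= 3 vertices, got {v.shape}"
                )
            cleaned.append((str(label), v))
        self.polygons = cleaned
        if self.scale_to_map <= 0:
            raise ValueError("scale_to_map must be positive")


def _mask_moments(mask: np.ndarray) -> tuple[np.ndarray, float]:
    """Centroid (x, y) and principal-axis angle (deg) of a binary mask."""
    rows, cols = np.nonzero(mask)
    c = np.array([cols.mean(), rows.mean()])
    x = cols - c[0]
    y = rows - c[1]
    # axis angle from second moments; defined modulo 180°
    theta = 0.5 * np.degrees(np.arctan2(2.0 * (x * y).mean(), (x * x).mean() - (y * y).mean()))
    return c, float(theta)


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    s = a.sum() + b.sum()
    return float(2.0 * np.logical_and(a, b).sum() / s) if s else 1.0


def apply_transform(data, t: RigidTransform, return_valid: bool = False):
    """Resample a density map or raster under the rigid transform ``t``.

    Density maps (and float rasters) use bilinear interpolation, boolean
    masks nearest-neighbor; pixels drawn from outside the frame become 0. A
    validity mask (True where the sample came from inside the frame) is
    returned when requested.
    """
    if isinstance(data, DensityMap):
        warped, valid = apply_transform(data.values, t, return_valid=True)
        out = replace(data, values=np.clip(warped, 0.0, None))
        return (out, valid) if return_valid else out

    arr = np.asarray(data)
    is_bool = arr.dtype == bool
    A, b = t.invert()._Ab()  # output pixel p samples input at T^{-1}(p)
    # scipy indexes (row, col) = (y, x): build the index-space matrix/offset.
    M = np.array([[A[1, 1], A[1, 0]], [A[0, 1], A[0, 0]]])
    off = np.array([b[1], b[0]])
    order = 0 if is_bool else 1
    warped = affine_transform(
        arr.astype(float), M, offset=off, order=order, mode="constant", cval=0.0
    )
    if return_valid:
        valid = (
            affine_transform(
                np.ones(arr.shape, dtype=float), M, offset=off, order=0, mode="constant", cval=0.0
            )
            > 0.5
        )
    out = warped > 0.5 if is_bool else warped
    return (out, valid) if return_valid else out


def rigid_register(
    moving_mask: np.ndarray,
    fixed_mask: np.ndarray,
    n_start_angles: int = 8,
    start_angle_range_deg: float = 20.0,
    smooth_sigma_px: float = 2.0,
) -> RegistrationResult:
    """Recover the rigid transform overlaying ``moving_mask`` onto
    ``fixed_mask`` (mean squares on smoothed binary masks).

    The search is initialized from the centroid difference combined with the
    principal-axis angle difference (both orientations of the 180°-ambiguous
    axis) plus ``n_start_angles`` evenly spaced rotations; the two best
    starts are refined with Powell's method. The returned transform is the
    best candidate encountered including the identity, so the achieved
    overlap never falls below the unaligned overlap.
    """
    mov = np.asarray(moving_mask, dtype=bool)
    fix = np.asarray(fixed_mask, dtype=bool)
    if mov.shape != fix.shape:
        raise ValueError(f"mask shapes differ: {mov.shape} vs {fix.shape}")
    for name, m in (("moving", mov), ("fixed", fix)):
        if m.mean() < 1e-3:
            raise InsufficientBackboneError(
                f"insufficient backbone: {name} mask has {m.mean():.2%} foreground (< 0.1%)"
            )

    h, w = fix.shape
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    mov_s = gaussian_filter(mov.astype(float), smooth_sigma_px)
    fix_s = gaussian_filter(fix.astype(float), smooth_sigma_px)

    def cost(params) -> float:
        t = RigidTransform(params[0], params[1], params[2], center=center)
        return float(np.mean((apply_transform(mov_s, t) - fix_s) ** 2))

    c_mov, th_mov = _mask_moments(mov)
    c_fix, th_fix = _mask_moments(fix)
    dt = c_fix - c_mov
    d_theta = (th_fix - th_mov + 90.0) % 180.0 - 90.0

    starts = [(0.0, 0.0, 0.0), (d_theta, dt[0], dt[1]), (d_theta + 180.0, dt[0], dt[1])]
    for a in np.linspace(-start_angle_range_deg, start_angle_range_deg, n_start_angles):
        starts.append((float(a), dt[0], dt[1]))
    ranked = sorted(starts, key=cost)

    best_params, best_cost = ranked[0], cost(ranked[0])
    for p0 in ranked[:2]:
        res = minimize(
            cost,
            np.asarray(p0, dtype=float),
            method="Powell",
            options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 2000},
        )
        if res.fun < best_cost:
            best_params, best_cost = tuple(res.x), float(res.fun)

    candidates = [
        RigidTransform(p[0], p[1], p[2], center=center) for p in (best_params, (0.0, 0.0, 0.0))
    ]
    scored = [(_dice(apply_transform(mov, t), fix), t) for t in candidates]
    scored.sort(key=lambda s: -s[0])
    return RegistrationResult(
        transform=scored[0][1],
        overlap_before=_dice(mov, fix),
        overlap_after=scored[0][0],
    )


def polygon_to_mask(ann: AnnotationSet, label: str, shape: tuple[int, int]) -> np.ndarray:
    """Binary mask of all polygons carrying ``label``: a pixel is set iff its
    center lies inside any such polygon (even-odd rule), after scaling the
    vertices by ``scale_to_map``."""
    mask = np.zeros(shape, dtype=bool)
    for lab, verts in ann.polygons:
        if lab == label:
            mask |= polygon_mask(verts * ann.scale_to_map, shape)
    return mask


#: Fixed column order of the cortex pixel table; marker → column name.
MARKER_COLUMN = {
    "nuclei": "tumor_cell_density",
    "NeuN": "neun_density",
    "Abeta": "abeta_density",
    "pTau": "ptau_density",
    "Iba1": "iba1_density",
}
CORTEX_TABLE_COLUMNS = [
    "pixel_id",
    "tumor_cell_density",
    "neun_density",
    "abeta_density",
    "ptau_density",
    "iba1_density",
]


def extract_cortex_vectors(
    maps: dict,
    cortex_mask: np.ndarray,
    tissue_mask: np.ndarray,
) -> pd.DataFrame:
    """Per-pixel density table over cortex ∧ tissue.

    ``maps`` maps marker names (keys of :data:`MARKER_COLUMN`) to coregistered
    :class:`DensityMap` objects on the same grid as the two masks. One row
    per pixel with tissue=1 and cortex=1; markers without a map yield absent
    columns (never zeros). ``pixel_id`` is the row-major flat index.
    """
    cortex = np.asarray(cortex_mask, dtype=bool)
    tissue = np.asarray(tissue_mask, dtype=bool)
    if cortex.shape != tissue.shape:
        raise GridMismatchError(
            f"cortex mask {cortex.shape} vs tissue mask {tissue.shape}"
        )
    sel = cortex & tissue
    flat = np.flatnonzero(sel)
    data = {"pixel_id": flat}
    for marker, dmap in maps.items():
        if marker not in MARKER_COLUMN:
            raise KeyError(f"unknown marker '{marker}'; expected one of {list(MARKER_COLUMN)}")
        if dmap.values.shape != cortex.shape:
            raise GridMismatchError(
                f"marker '{marker}' map shape {dmap.values.shape} does not match "
                f"mask grid {cortex.shape}"
            )
        data[MARKER_COLUMN[marker]] = dmap.values.ravel()[flat]
    cols = [c for c in CORTEX_TABLE_COLUMNS if c in data]
    return pd.DataFrame(data, columns=cols)
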