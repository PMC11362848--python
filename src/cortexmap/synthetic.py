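"""Synthetic brightfield IHC slides and cohort tables with exported ground truth.

The generator emulates the inputs of a whole-slide immunohistochemistry
quantification pipeline: a pale glass background, a tissue region of lower
blue intensity, hematoxylin-stained nuclei (blue-purple disks) and
DAB-immunostained particles (brown disks: plaques, tangles or microglia
depending on the marker), per-blob color jitter standing in for per-slide
staining variability, serial sections related by small rigid transforms, and
cortex polygons. Every rendered object is recorded in a :class:`GroundTruth`
so downstream stages can be scored against known truth.

Blobs are anti-aliased filled disks with a softened (approximately Gaussian)
edge; their centroids are therefore analytically known. Placement is uniform
inside the tissue polygon by rejection sampling with a bounded pairwise
overlap, optionally biased by a linear left-right gradient (used to build
spatially coupled marker pairs).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely import affinity
from shapely.geometry import Polygon, box

from ._geometry import polygon_mask, rotation_matrix_deg

__all__ = [
    "SlideImage",
    "SlideSpec",
    "StainSpec",
    "GroundTruth",
    "PlacementError",
    "OutOfFrameError",
    "generate_slide",
    "generate_serial_section",
    "generate_cohort",
    "default_tissue_polygon",
    "DEFAULT_HEMATOXYLIN_RGB",
    "DEFAULT_IMMUNOSTAIN_RGB",
    "DEFAULT_BACKGROUND_RGB",
    "DEFAULT_TISSUE_RGB",
    "ADNC_CATEGORIES",
]

# Typical brightfield hues (configurable, not calibrated claims).
DEFAULT_HEMATOXYLIN_RGB = (70.0, 60.0, 130.0)
DEFAULT_IMMUNOSTAIN_RGB = (130.0, 80.0, 40.0)  # DAB brown
DEFAULT_BACKGROUND_RGB = (245.0, 243.0, 240.0)
# Unstained tissue: slightly absorbing, blue channel clearly below background
# so the mean-blue tissue threshold separates tissue from glass.
DEFAULT_TISSUE_RGB = (232.0, 222.0, 210.0)

MAX_PAIRWISE_OVERLAP = 0.30  # fraction of the smaller disk's area
MAX_PLACEMENT_ATTEMPTS = 10_000  # per blob


class PlacementError(RuntimeError):
    """Requested blob count cannot be placed without exceeding the overlap cap."""

    def __init__(self, placed: int, requested: int):
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"could only place {placed} of {requested} blobs within "
            f"{MAX_PLACEMENT_ATTEMPTS} attempts at max pairwise overlap "
            f"{MAX_PAIRWISE_OVERLAP:.0%}"
        )


class OutOfFrameError(RuntimeError):
    """A rigid transform moves too much tissue outside the image frame."""


@dataclass
class SlideImage:
    """RGB raster with physical scale and stain metadata."""

    rgb: np.ndarray  # uint8, (H, W, 3)
    um_per_px: float
    marker: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]


@dataclass(frozen=True)
class StainSpec:
    """Stain colors and jitter for one slide rendering."""

    hematoxylin_rgb: tuple = DEFAULT_HEMATOXYLIN_RGB
    immunostain_rgb: tuple = DEFAULT_IMMUNOSTAIN_RGB
    background_rgb: tuple = DEFAULT_BACKGROUND_RGB
    tissue_rgb: tuple = DEFAULT_TISSUE_RGB
    color_jitter_sd: float = 6.0


def default_tissue_polygon(width_px: int, height_px: int, margin_frac: float = 0.12) -> Polygon:
    """Convex octagonal tissue outline inset from the frame by ``margin_frac``."""
    w, h = width_px, height_px
    mx, my = margin_frac * w, margin_frac * h
    cut_x, cut_y = 0.22 * w, 0.22 * h
    pts = [
        (mx + cut_x, my),
        (w - mx - cut_x, my),
        (w - mx, my + cut_y),
        (w - mx, h - my - cut_y),
        (w - mx - cut_x, h - my),
        (mx + cut_x, h - my),
        (mx, h - my - cut_y),
        (mx, my + cut_y),
    ]
    return Polygon(pts)


@dataclass
class SlideSpec:
    """Full parameterization of one synthetic slide."""

    width_px: int = 1024
    height_px: int = 1024
    um_per_px: float = 0.92
    background_rgb: tuple = DEFAULT_BACKGROUND_RGB
    tissue_rgb: tuple = DEFAULT_TISSUE_RGB
    hematoxylin_rgb: tuple = DEFAULT_HEMATOXYLIN_RGB
    immunostain_rgb: tuple = DEFAULT_IMMUNOSTAIN_RGB
    nucleus_count: int = 300
    nucleus_radius_px: tuple = (4.0, 7.0)
    particle_count: int = 60
    particle_radius_px: tuple = (5.0, 9.0)
    color_jitter_sd: float = 6.0
    tissue_polygon: Polygon | None = None
    cortex_polygon: Polygon | None = None
    seed: int = 0
    marker: str = ""
    # Linear placement bias along x: weight ∝ 1 + g·(x/W − 1/2), g ∈ [−2, 2].
    # 0 = uniform. Used to construct spatially coupled serial markers.
    nucleus_gradient: float = 0.0
    particle_gradient: float = 0.0
    # Extra center-to-center clearance beyond r1+r2. 0 allows touching blobs
    # (which merge in segmentation); set > 0 for well-separated layouts.
    min_gap_px: float = 0.0

    def __post_init__(self):
        if self.tissue_polygon is None:
            self.tissue_polygon = default_tissue_polygon(self.width_px, self.height_px)
        if self.cortex_polygon is None:
            # Cortex defaults to the tissue outline shrunk toward its centroid.
            self.cortex_polygon = affinity.scale(
                self.tissue_polygon, xfact=0.85, yfact=0.85, origin="centroid"
            )
        self.validate()

    def validate(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("width_px and height_px must be positive")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        for name in ("nucleus_radius_px", "particle_radius_px"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} must satisfy 1 <= lo <= hi, got ({lo}, {hi})")
        for name in ("background_rgb", "tissue_rgb", "hematoxylin_rgb", "immunostain_rgb"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or (v < 0).any() or (v > 255).any():
                raise ValueError(f"{name} must be a 3-vector with components in [0, 255]")
        if self.nucleus_count < 0 or self.particle_count < 0:
            raise ValueError("blob counts must be >= 0")
        if self.color_jitter_sd < 0:
            raise ValueError("color_jitter_sd must be >= 0")
        if not (-2.0 <= self.nucleus_gradient <= 2.0 and -2.0 <= self.particle_gradient <= 2.0):
            raise ValueError("placement gradients must lie in [-2, 2]")

    @property
    def stain_spec(self) -> StainSpec:
        return StainSpec(
            hematoxylin_rgb=tuple(self.hematoxylin_rgb),
            immunostain_rgb=tuple(self.immunostain_rgb),
            background_rgb=tuple(self.background_rgb),
            tissue_rgb=tuple(self.tissue_rgb),
            color_jitter_sd=self.color_jitter_sd,
        )


@dataclass
class GroundTruth:
    """Everything the generator knows about what it rendered."""

    nucleus_centroids: np.ndarray  # (N, 2) of (x, y)
    particle_centroids: np.ndarray  # (M, 2)
    nucleus_radii: np.ndarray
    particle_radii: np.ndarray
    tissue_polygon: Polygon
    cortex_polygon: Polygon
    tissue_mask: np.ndarray  # bool (H, W)
    rigid_transform_to_reference: tuple = (0.0, 0.0, 0.0)  # (rotation deg, tx, ty)

    def validate(self, shape: tuple[int, int]) -> None:
        h, w = shape
        for pts in (self.nucleus_centroids, self.particle_centroids):
            if len(pts) and (
                (pts[:, 0] < 0).any()
                or (pts[:, 0] > w - 1).any()
                or (pts[:, 1] < 0).any()
                or (pts[:, 1] > h - 1).any()
            ):
                raise ValueError("centroid outside the image frame")
        rot = self.rigid_transform_to_reference[0]
        if not (-180.0 < rot <= 180.0):
            raise ValueError("transform rotation must lie in (-180, 180]")


# ---------------------------------------------------------------------------
# placement


def _lens_overlap_fraction(d, r1, r2):
    """Overlap area of two disks as a fraction of the smaller disk's area."""
    d = np.asarray(d, dtype=float)
    r_small = np.minimum(r1, r2)
    r_big = np.maximum(r1, r2)
    out = np.zeros_like(d)
    contained = d <= (r_big - r_small)
    out[contained] = 1.0
    sel = (~contained) & (d < r1 + r2)
    if sel.any():
        ds = d[sel]
        rs1 = np.broadcast_to(np.asarray(r1, dtype=float), d.shape)[sel]
        rs2 = np.broadcast_to(np.asarray(r2, dtype=float), d.shape)[sel]
        a1 = rs1**2 * np.arccos(np.clip((ds**2 + rs1**2 - rs2**2) / (2 * ds * rs1), -1, 1))
        a2 = rs2**2 * np.arccos(np.clip((ds**2 + rs2**2 - rs1**2) / (2 * ds * rs2), -1, 1))
        a3 = 0.5 * np.sqrt(
            np.maximum(
                (-ds + rs1 + rs2) * (ds + rs1 - rs2) * (ds - rs1 + rs2) * (ds + rs1 + rs2), 0.0
            )
        )
        lens = a1 + a2 - a3
        out[sel] = lens / (np.pi * np.minimum(rs1, rs2) ** 2)
    return out


def _place_blobs(
    rng: np.random.Generator,
    count: int,
    radius_range: tuple,
    polygon: Polygon,
    width: int,
    gradient: float,
    existing_centers: list,
    existing_radii: list,
    min_gap_px: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample ``count`` disk centers uniformly (optionally with a
    linear x-gradient) inside ``polygon`` with bounded pairwise overlap."""
    import shapely

    minx, miny, maxx, maxy = polygon.bounds
    centers: list = []
    radii: list = []
    lo, hi = radius_range
    for i in range(count):
        placed = False
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            x = rng.uniform(minx, maxx)
            y = rng.uniform(miny, maxy)
            if gradient != 0.0:
                wgt = 1.0 + gradient * (x / width - 0.5)
                wmax = 1.0 + abs(gradient) * 0.5
                if rng.uniform(0.0, wmax) > wgt:
                    continue
            if not shapely.contains_xy(polygon, x, y):
                continue
            r = rng.uniform(lo, hi)
            all_centers = existing_centers + centers
            if all_centers:
                arr = np.asarray(all_centers)
                rr = np.asarray(existing_radii + radii)
                d = np.hypot(arr[:, 0] - x, arr[:, 1] - y)
                if min_gap_px > 0 and (d < rr + r + min_gap_px).any():
                    continue
                near = d < rr + r  # only overlapping pairs matter
                if near.any() and (
                    _lens_overlap_fraction(d[near], rr[near], r) > MAX_PAIRWISE_OVERLAP
                ).any():
                    continue
            centers.append((x, y))
            radii.append(r)
            placed = True
            break
        if not placed:
            raise PlacementError(placed=i, requested=count)
    if not centers:
        return np.zeros((0, 2)), np.zeros((0,))
    return np.asarray(centers, dtype=float), np.asarray(radii, dtype=float)


# ---------------------------------------------------------------------------
# rendering


def _render(
    shape: tuple[int, int],
    stain: StainSpec,
    tissue_poly: Polygon,
    centers: np.ndarray,
    radii: np.ndarray,
    classes: np.ndarray,  # 0 = nucleus (hematoxylin), 1 = particle (immunostain)
    rng: np.random.Generator,
) -> np.ndarray:
    h, w = shape
    img = np.empty((h, w, 3), dtype=float)
    img[:] = np.asarray(stain.background_rgb, dtype=float)
    tmask = polygon_mask(np.asarray(tissue_poly.exterior.coords)[:-1], shape)
    img[tmask] = np.asarray(stain.tissue_rgb, dtype=float)

    base_colors = (
        np.asarray(stain.hematoxylin_rgb, dtype=float),
        np.asarray(stain.immunostain_rgb, dtype=float),
    )
    for (cx, cy), r, cls in zip(centers, radii, classes):
        color = np.clip(
            base_colors[int(cls)] + rng.normal(0.0, stain.color_jitter_sd, size=3), 0, 255
        )
        pad = int(np.ceil(r)) + 3
        x0, x1 = max(0, int(np.floor(cx)) - pad), min(w, int(np.ceil(cx)) + pad + 1)
        y0, y1 = max(0, int(np.floor(cy)) - pad), min(h, int(np.ceil(cy)) + pad + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dist = np.hypot(xx - cx, yy - cy)
        alpha = np.clip(r + 0.5 - dist, 0.0, 1.0)  # 1-px anti-aliased rim
        alpha = gaussian_filter(alpha, sigma=0.5)  # Gaussian edge softening
        patch = img[y0:y1, x0:x1]
        patch[:] = alpha[..., None] * color + (1.0 - alpha[..., None]) * patch
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_slide(spec: SlideSpec) -> tuple[SlideImage, GroundTruth]:
    """Render one synthetic IHC slide and its ground truth.

    Deterministic for a fixed ``spec`` (a single RNG stream is seeded from
    ``spec.seed``). Raises :class:`PlacementError` when the requested blob
    count cannot be placed under the overlap cap.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height_px, spec.width_px)

    nuc_centers, nuc_radii = _place_blobs(
        rng,
        spec.nucleus_count,
        spec.nucleus_radius_px,
        spec.tissue_polygon,
        spec.width_px,
        spec.nucleus_gradient,
        [],
        [],
        spec.min_gap_px,
    )
    part_centers, part_radii = _place_blobs(
        rng,
        spec.particle_count,
        spec.particle_radius_px,
        spec.tissue_polygon,
        spec.width_px,
        spec.particle_gradient,
        list(map(tuple, nuc_centers)),
        list(nuc_radii),
        spec.min_gap_px,
    )

    centers = np.vstack([nuc_centers, part_centers])
    radii = np.concatenate([nuc_radii, part_radii])
    classes = np.concatenate(
        [np.zeros(len(nuc_centers), dtype=int), np.ones(len(part_centers), dtype=int)]
    )
    img = _render(shape, spec.stain_spec, spec.tissue_polygon, centers, radii, classes, rng)

    gt = GroundTruth(
        nucleus_centroids=nuc_centers,
        particle_centroids=part_centers,
        nucleus_radii=nuc_radii,
        particle_radii=part_radii,
        tissue_polygon=spec.tissue_polygon,
        cortex_polygon=spec.cortex_polygon,
        tissue_mask=polygon_mask(
            np.asarray(spec.tissue_polygon.exterior.coords)[:-1], shape
        ),
    )
    gt.validate(shape)
    return SlideImage(rgb=img, um_per_px=spec.um_per_px, marker=spec.marker), gt


def _apply_rigid_xy(points: np.ndarray, rotation_deg: float, tx: float, ty: float,
                    center: tuple) -> np.ndarray:
    if len(points) == 0:
        return points.reshape(0, 2)
    R = rotation_matrix_deg(rotation_deg)
    c = np.asarray(center, dtype=float)
    return (points - c) @ R.T + c + np.array([tx, ty])


def generate_serial_section(
    reference: tuple[SlideImage, GroundTruth],
    stain_swap: StainSpec,
    transform: tuple,
    seed: int,
    marker: str = "",
    keep_particles: bool = True,
) -> tuple[SlideImage, GroundTruth]:
    """Re-render a reference slide as an adjacent serial section.

    The tissue outline and blob layout of the reference are re-rendered with
    the new stain colors (fresh jitter from ``seed``) and moved by the given
    rigid ``(rotation_deg, tx, ty)`` about the image center, emulating how a
    neighboring section lands on its own glass slide. The returned ground
    truth records the transform. Blobs whose centers leave the frame are
    dropped; if more than 10% of the tissue leaves the frame the section is
    rejected.
    """
    ref_img, ref_gt = reference
    rot, tx, ty = transform
    h, w = ref_img.shape
    if abs(rot) > 20.0:
        raise ValueError(f"|rotation| must be <= 20 deg, got {rot}")
    if abs(tx) > 0.1 * w or abs(ty) > 0.1 * h:
        raise ValueError(f"|tx|, |ty| must be <= 10% of image size, got ({tx}, {ty})")

    center = ((w - 1) / 2.0, (h - 1) / 2.0)

    def move_poly(poly: Polygon) -> Polygon:
        # shapely's rotate applies [[cos,-sin],[sin,cos]] to coordinates,
        # identical to rotation_matrix_deg, so centroids and polygons agree.
        moved = affinity.rotate(poly, rot, origin=center, use_radians=False)
        return affinity.translate(moved, xoff=tx, yoff=ty)

    tissue_moved = move_poly(ref_gt.tissue_polygon)
    frame = box(-0.5, -0.5, w - 0.5, h - 0.5)
    retained = tissue_moved.intersection(frame).area / ref_gt.tissue_polygon.area
    if retained < 0.9:
        raise OutOfFrameError(
            f"transform keeps only {retained:.1%} of the tissue in frame (need >= 90%)"
        )

    nuc = _apply_rigid_xy(ref_gt.nucleus_centroids, rot, tx, ty, center)
    part = (
        _apply_rigid_xy(ref_gt.particle_centroids, rot, tx, ty, center)
        if keep_particles
        else np.zeros((0, 2))
    )
    part_radii = ref_gt.particle_radii if keep_particles else np.zeros((0,))

    def in_frame(pts):
        if len(pts) == 0:
            return np.zeros((0,), dtype=bool)
        return (pts[:, 0] >= 0) & (pts[:, 0] <= w - 1) & (pts[:, 1] >= 0) & (pts[:, 1] <= h - 1)

    keep_n = in_frame(nuc)
    keep_p = in_frame(part)
    nuc, nuc_radii = nuc[keep_n], ref_gt.nucleus_radii[keep_n]
    part, part_radii = part[keep_p], part_radii[keep_p]

    rng = np.random.default_rng(seed)
    centers = np.vstack([nuc, part])
    radii = np.concatenate([nuc_radii, part_radii])
    classes = np.concatenate([np.zeros(len(nuc), dtype=int), np.ones(len(part), dtype=int)])
    img = _render((h, w), stain_swap, tissue_moved, centers, radii, classes, rng)

    gt = GroundTruth(
        nucleus_centroids=nuc,
        particle_centroids=part,
        nucleus_radii=nuc_radii,
        particle_radii=part_radii,
        tissue_polygon=tissue_moved,
        cortex_polygon=move_poly(ref_gt.cortex_polygon),
        tissue_mask=polygon_mask(np.asarray(tissue_moved.exterior.coords)[:-1], (h, w)),
        rigid_transform_to_reference=(float(rot), float(tx), float(ty)),
    )
    gt.validate((h, w))
    return SlideImage(rgb=img, um_per_px=ref_img.um_per_px, marker=marker), gt


# ---------------------------------------------------------------------------
# cohort

ADNC_CATEGORIES = ("AT", "T", "A", "vascular_only", "none")

#: Conditional score distributions used to fill in the non-category columns.
#: Chosen once from the cohort's printed marginals (tumor location, CERAD and
#: Braak group counts, APP/DAI prevalence, capillary CAA rate); they define
#: the study conditions the generator emulates.
_LOBE_P = {"temporal": 0.385, "frontal": 0.244, "parietal": 0.127, "occipital": 0.117, "NA": 0.127}
_CERAD_GIVEN_ABETA = {"0": 38 / 65, "A": 6 / 65, "B": 8 / 65, "C": 13 / 65}
_BRAAK_GIVEN_PTAU = {"I-II": 9 / 78, "III-IV": 50 / 78, "V-VI": 19 / 78}
_APP_TUMOR_P = {"absent": 0.50, "sparse": 0.15, "moderate": 0.18, "abundant": 0.17}
_APP_NEURON_P = {"absent": 0.0, "sparse": 0.02, "moderate": 0.09, "abundant": 0.89}
_DAI_P = {"absent": 0.05, "sparse": 0.35, "moderate": 0.33, "frequent": 0.27}

COHORT_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "lobe",
    "hemisphere",
    "adnc_category",
    "cerad",
    "braak_group",
    "caa_vessel",
    "caa_capillary",
    "infiltration",
    "app_tumor",
    "app_neuron",
    "dai",
    "survival_days",
    "mgmt_methylated",
]


def _pick(rng, table: dict) -> str:
    keys = list(table)
    p = np.asarray([table[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def generate_cohort(
    n_patients: int,
    prevalence: dict,
    age_model: tuple = (67.0, 12.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Draw an i.i.d. synthetic patient cohort.

    ``prevalence`` maps ADNC categories (any of ``AT``, ``T``, ``A``,
    ``vascular_only``) to probabilities; the remainder is category ``none``.
    Ages are normal(mean, sd) clipped to [0, 120]. Deterministic per seed.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    probs = {k: float(prevalence.get(k, 0.0)) for k in ADNC_CATEGORIES if k != "none"}
    bad = set(prevalence) - set(ADNC_CATEGORIES)
    if bad:
        raise ValueError(f"unknown ADNC categories in prevalence map: {sorted(bad)}")
    if any(p < 0 for p in probs.values()) or sum(probs.values()) > 1.0 + 1e-12:
        raise ValueError("prevalence probabilities must be >= 0 and sum to <= 1")
    probs["none"] = max(0.0, 1.0 - sum(probs.values()))

    rng = np.random.default_rng(seed)
    mean_age, sd_age = age_model
    rows = []
    for i in range(n_patients):
        cat = _pick(rng, probs)
        age = float(np.clip(rng.normal(mean_age, sd_age), 0.0, 120.0))
        has_abeta = cat in ("AT", "A")
        has_ptau = cat in ("AT", "T")
        cerad = _pick(rng, _CERAD_GIVEN_ABETA) if has_abeta else "0"
        braak = _pick(rng, _BRAAK_GIVEN_PTAU) if has_ptau else "0"
        rows.append(
            {
                "patient_id": f"P{i:04d}",
                "age": round(age, 1),
                "sex": "F" if rng.random() < 0.367 else "M",  # F:M ratio 0.58
                "lobe": _pick(rng, _LOBE_P),
                "hemisphere": (
                    "NA" if rng.random() < 0.2 else ("R" if rng.random() < 0.561 else "L")
                ),
                "adnc_category": cat,
                "cerad": cerad,
                "braak_group": braak,
                "caa_vessel": cat == "vascular_only" or rng.random() < 0.05,
                "caa_capillary": rng.random() < 0.083,
                "infiltration": ("low", "medium", "high")[rng.choice(3)],
                "app_tumor": _pick(rng, _APP_TUMOR_P),
                "app_neuron": _pick(rng, _APP_NEURON_P),
                "dai": _pick(rng, _DAI_P),
                "survival_days": float(np.rint(rng.exponential(300.0 / np.log(2.0)))),
                "mgmt_methylated": bool(rng.random() < 0.45),
            }
        )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)
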