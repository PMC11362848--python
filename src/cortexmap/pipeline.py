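"""End-to-end pipeline: slides → classification → densities → registration →
cortex table → statistics.

A run is driven by one YAML config (:class:`RunConfig`), is deterministic
given config + seed, writes every stage product under the output directory,
and records a manifest (config hash, outputs with content hashes, recovered
transforms, QC notes). Completed stages whose outputs are present and whose
config hash matches are skipped on rerun.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import io as cio
from .annotations import read_annotation_xml, read_geojson
from .density import DensityMap, PipelineScales, centroid_count_map, density_from_centroids, downsample_map
from .registration import (
    MARKER_COLUMN,
    RigidTransform,
    apply_transform,
    extract_cortex_vectors,
    polygon_to_mask,
    rigid_register,
)
from .stains import ClassifierParams, classify_pixels, estimate_stain_vectors, segment_nuclei, segment_particles, tissue_mask
from .stats import ALPHA, density_correlation

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "SlideEntry",
    "PipelineError",
    "run_pipeline",
    "load_config",
    "make_synthetic_study",
]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class SlideEntry:
    marker: str
    image: str
    stain_reference: str


@dataclass
class RunConfig:
    slides: list
    out_dir: str
    annotations: str | None = None
    um_per_px: float = 0.92
    seed: int = 0
    alpha: float = ALPHA
    reference_marker: str = "NeuN"
    registration: bool = True
    registration_level: str = "map"  # masks are aligned on the coarse map grid
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    scales: PipelineScales = field(default_factory=PipelineScales)
    correlations: list = field(default_factory=lambda: [["abeta_density", "tumor_cell_density"]])

    def validate(self) -> None:
        if not self.slides:
            raise PipelineError("validation: no slides configured")
        markers = [s.marker for s in self.slides]
        if len(set(markers)) != len(markers):
            raise PipelineError(f"validation: duplicate markers in {markers}")
        if self.registration and self.reference_marker not in markers:
            raise PipelineError(
                f"validation: registration requires the reference marker "
                f"'{self.reference_marker}', slides provide only {markers}"
            )
        for s in self.slides:
            for path in (s.image, s.stain_reference):
                if not Path(path).exists():
                    raise PipelineError(f"validation: missing input file {path}")
        if self.annotations and not Path(self.annotations).exists():
            raise PipelineError(f"validation: missing annotation file {self.annotations}")

    def config_hash(self) -> str:
        blob = json.dumps(_to_plain(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML document; relative paths resolve
    against the config file's directory."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    base = path.parent

    def resolve(p):
        return str((base / p).resolve()) if p and not Path(p).is_absolute() else p

    slides = [
        SlideEntry(
            marker=s["marker"],
            image=resolve(s["image"]),
            stain_reference=resolve(s["stain_reference"]),
        )
        for s in doc.get("slides", [])
    ]
    return RunConfig(
        slides=slides,
        out_dir=resolve(doc.get("out_dir", "out")),
        annotations=resolve(doc.get("annotations")),
        um_per_px=float(doc.get("um_per_px", 0.92)),
        seed=int(doc.get("seed", 0)),
        alpha=float(doc.get("alpha", ALPHA)),
        reference_marker=doc.get("reference_marker", "NeuN"),
        registration=bool(doc.get("registration", True)),
        classifier=ClassifierParams(**doc.get("classifier", {})),
        scales=PipelineScales(um_per_px=float(doc.get("um_per_px", 0.92)),
                              **doc.get("scales", {})),
        correlations=doc.get("correlations", [["abeta_density", "tumor_cell_density"]]),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _block_mean_mask(mask: np.ndarray, block: int) -> np.ndarray:
    from .density import _block_means

    return _block_means(mask.astype(float), block) > 0.5


class _Manifest:
    def __init__(self, path: Path, config_hash: str):
        self.path = path
        self.data = {"config_hash": config_hash, "stages": {}, "qc": [], "transforms": {}}
        if path.exists():
            old = json.loads(path.read_text())
            if old.get("config_hash") == config_hash:
                self.data = old

    def stage_done(self, name: str) -> bool:
        rec = self.data["stages"].get(name)
        if not rec:
            return False
        for f, digest in rec["outputs"].items():
            p = Path(f)
            if not p.exists() or _sha256(p) != digest:
                return False
        return True

    def record(self, name: str, outputs: list, info: dict | None = None) -> None:
        self.data["stages"][name] = {
            "outputs": {str(p): _sha256(Path(p)) for p in outputs},
            "info": info or {},
        }
        self.save()

    def save(self) -> None:
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


def make_synthetic_study(
    work_dir,
    seed: int = 0,
    size_px: int = 1536,
    kernel_radius_px: int = 100,
    map_downsample: float = 0.125,
    coupling_gradient: float = 1.2,
    transform: tuple = (2.0, 8.0, -5.0),
) -> RunConfig:
    """Materialize a two-marker serial-section study with known ground truth.

    Writes a NeuN reference slide and an Abeta serial section (same tissue
    outline, its own cell layout, moved by ``transform``) plus stain-mark
    CSVs and a cortex GeoJSON under ``work_dir``, and returns a ready
    RunConfig. Tumor-cell placement density rises left to right while the
    Abeta particle density falls (strength ``coupling_gradient``), emulating
    plaque loss in heavily infiltrated cortex, so the extracted pixel table
    carries a negative Abeta–tumor-density coupling by construction.
    """
    from .annotations import AnnotationSet, write_geojson
    from .synthetic import SlideSpec, StainSpec, generate_serial_section, generate_slide

    work = Path(work_dir)
    work.mkdir(parents=True, exist_ok=True)
    spec_neun = SlideSpec(
        width_px=size_px, height_px=size_px, um_per_px=1.0,
        nucleus_count=int(900 * (size_px / 1536) ** 2),
        particle_count=int(250 * (size_px / 1536) ** 2),
        nucleus_gradient=coupling_gradient, particle_gradient=-coupling_gradient,
        min_gap_px=2.0, seed=seed, marker="NeuN",
    )
    neun_img, neun_gt = generate_slide(spec_neun)
    spec_abeta = SlideSpec(
        width_px=size_px, height_px=size_px, um_per_px=1.0,
        nucleus_count=spec_neun.nucleus_count,
        particle_count=int(200 * (size_px / 1536) ** 2),
        nucleus_gradient=coupling_gradient, particle_gradient=-coupling_gradient,
        min_gap_px=2.0, seed=seed + 1, marker="Abeta",
        tissue_polygon=spec_neun.tissue_polygon, cortex_polygon=spec_neun.cortex_polygon,
    )
    abeta_ref = generate_slide(spec_abeta)
    abeta_img, abeta_gt = generate_serial_section(
        abeta_ref, StainSpec(), transform, seed=seed + 2, marker="Abeta"
    )

    cio.write_slide(neun_img, work / "neun.png")
    cio.write_slide(abeta_img, work / "abeta.png")
    for gt, name in ((neun_gt, "neun"), (abeta_gt, "abeta")):
        marks = pd.DataFrame(
            [
                {"class": "hematoxylin", "x": int(round(x)), "y": int(round(y))}
                for x, y in gt.nucleus_centroids[:10]
            ]
            + [
                {"class": "immunostain", "x": int(round(x)), "y": int(round(y))}
                for x, y in gt.particle_centroids[:10]
            ]
        )
        marks.to_csv(work / f"{name}_stain_marks.csv", index=False)
        cio.write_centroids_csv(
            work / f"{name}_ground_truth.csv",
            nucleus=gt.nucleus_centroids,
            particle=gt.particle_centroids,
        )
    ann = AnnotationSet(
        polygons=[("cortex", np.asarray(neun_gt.cortex_polygon.exterior.coords)[:-1])]
    )
    write_geojson(ann, work / "annotations.geojson")

    return RunConfig(
        slides=[
            SlideEntry("NeuN", str(work / "neun.png"), str(work / "neun_stain_marks.csv")),
            SlideEntry("Abeta", str(work / "abeta.png"), str(work / "abeta_stain_marks.csv")),
        ],
        out_dir=str(work / "run"),
        annotations=str(work / "annotations.geojson"),
        um_per_px=1.0,
        seed=seed,
        scales=PipelineScales(
            um_per_px=1.0, kernel_radius_px=kernel_radius_px, map_downsample=map_downsample
        ),
        correlations=[["abeta_density", "tumor_cell_density"]],
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the run manifest as a dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json", config.config_hash())
    scales = config.scales
    block = int(round(1.0 / scales.map_downsample))

    density_paths: dict[str, dict[str, Path]] = {}
    map_tissue_paths: dict[str, Path] = {}

    for entry in config.slides:
        stage = f"quantify:{entry.marker}"
        cent_csv = out / f"{entry.marker}_centroids.csv"
        label_png = out / f"{entry.marker}_labels.png"
        tmask_png = out / f"{entry.marker}_map_tissue.png"
        dens = {
            "nuclei": out / f"{entry.marker}_nuclei_density.tiff",
            "particles": out / f"{entry.marker}_particle_density.tiff",
        }
        density_paths[entry.marker] = dens
        map_tissue_paths[entry.marker] = tmask_png
        outputs = [cent_csv, label_png, tmask_png, *dens.values()]
        if manifest.stage_done(stage):
            logger.info("skipping completed stage %s", stage)
            continue
        try:
            image = cio.read_slide(entry.image, config.um_per_px, marker=entry.marker)
            immuno_px, hema_px = cio.read_stain_reference_csv(entry.stain_reference)
            ref = estimate_stain_vectors(image, immuno_px, hema_px)
            tmask = tissue_mask(image, config.classifier)
            labels = classify_pixels(image, ref, config.classifier, tissue=tmask)
            nuclei = segment_nuclei(image, ref, config.classifier, labels, tmask)
            particles = segment_particles(image, ref, config.classifier, labels, tmask)
            if len(nuclei) == 0:
                manifest.data["qc"].append(f"{entry.marker}: empty nucleus segmentation")
            if len(particles) == 0:
                manifest.data["qc"].append(f"{entry.marker}: empty particle segmentation")

            cio.write_centroids_csv(cent_csv, nucleus=nuclei, particle=particles)
            cio.write_label_map_png(labels.labels, label_png)

            for kind, cents in (("nuclei", nuclei), ("particles", particles)):
                counts = centroid_count_map(cents, image.shape)
                dmap = density_from_centroids(counts, scales, marker=kind)
                dmap = downsample_map(dmap, scales.map_downsample)
                cio.write_density_tiff(dmap, dens[kind])
                cio.write_density_preview_png(dmap, dens[kind].with_suffix(".png"))

            map_tissue = _block_mean_mask(tmask, block)
            Image.fromarray(map_tissue.astype(np.uint8) * 255, mode="L").save(tmask_png)
        except Exception as exc:  # noqa: BLE001 - stage context matters more
            raise PipelineError(f"stage {stage} failed on {entry.image}: {exc}") from exc
        manifest.record(
            stage,
            outputs,
            info={"n_nuclei": int(len(nuclei)), "n_particles": int(len(particles))},
        )

    # --- registration to the reference marker (map level) -----------------
    transforms: dict[str, RigidTransform] = {}
    if config.registration:
        ref_mask = np.asarray(Image.open(map_tissue_paths[config.reference_marker])) > 127
        for entry in config.slides:
            if entry.marker == config.reference_marker:
                transforms[entry.marker] = RigidTransform.identity()
                continue
            stage = f"register:{entry.marker}"
            mov_mask = np.asarray(Image.open(map_tissue_paths[entry.marker])) > 127
            try:
                result = rigid_register(mov_mask, ref_mask)
            except Exception as exc:
                raise PipelineError(
                    f"stage {stage} failed on {map_tissue_paths[entry.marker]}: {exc}"
                ) from exc
            transforms[entry.marker] = result.transform
            manifest.data["transforms"][entry.marker] = {
                "rotation_deg": result.transform.rotation_deg,
                "tx_px": result.transform.tx_px,
                "ty_px": result.transform.ty_px,
                "center": list(result.transform.center),
                "overlap_before": result.overlap_before,
                "overlap_after": result.overlap_after,
            }
            manifest.save()
    else:
        transforms = {e.marker: RigidTransform.identity() for e in config.slides}

    # --- cortex mask and pixel table --------------------------------------
    ref_map_tissue = np.asarray(Image.open(map_tissue_paths[config.reference_marker])) > 127
    map_shape = ref_map_tissue.shape

    if config.annotations:
        reader = read_annotation_xml if str(config.annotations).endswith(".xml") else read_geojson
        ann = reader(config.annotations, scale_to_map=scales.map_downsample)
        cortex = polygon_to_mask(ann, "cortex", map_shape)
    else:
        cortex = np.ones(map_shape, dtype=bool)
        manifest.data["qc"].append("no annotations: whole frame treated as cortex")

    maps: dict[str, DensityMap] = {}
    for entry in config.slides:
        t = transforms[entry.marker]
        for kind, path in density_paths[entry.marker].items():
            dmap = cio.read_density_tiff(path)
            if entry.marker != config.reference_marker and config.registration:
                dmap = apply_transform(dmap, t)
            if entry.marker == config.reference_marker and kind == "nuclei":
                maps["nuclei"] = dmap  # tumor cells: hematoxylin channel of the reference
            elif kind == "particles" and entry.marker in MARKER_COLUMN:
                maps[entry.marker] = dmap

    table = extract_cortex_vectors(maps, cortex, ref_map_tissue)
    table_csv = out / "cortex_table.csv"
    table.to_csv(table_csv, index=False, float_format="%.6f")
    manifest.record("extract", [table_csv], info={"n_pixels": int(len(table))})

    # --- statistics --------------------------------------------------------
    stats_rows = []
    for var_x, var_y in config.correlations:
        if var_x not in table.columns or var_y not in table.columns:
            manifest.data["qc"].append(f"correlation {var_x}~{var_y} skipped: column missing")
            continue
        res, hist, xe, ye = density_correlation(table, var_x, var_y)
        np.savetxt(out / f"hist_{var_x}__{var_y}.csv", hist, delimiter=",", fmt="%.1f")
        stats_rows.append(
            {
                "var_x": var_x,
                "var_y": var_y,
                "method": res.method,
                "estimate": res.estimate,
                "p_value": res.p_value,
                "n": res.n,
                "significant": res.p_value < config.alpha,
            }
        )
    stats_csv = out / "correlations.csv"
    pd.DataFrame(stats_rows).to_csv(stats_csv, index=False, float_format="%.6g")
    manifest.record("stats", [stats_csv], info={"alpha": config.alpha})

    manifest.save()
    return manifest.data
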