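"""Rigid registration, transform algebra, polygon rasterization and cortex
pixel-table extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortexmap.annotations import AnnotationSet, read_annotation_xml, read_geojson, write_geojson
from cortexmap.density import DensityMap
from cortexmap.registration import (
    GridMismatchError,
    InsufficientBackboneError,
    RigidTransform,
    apply_transform,
    extract_cortex_vectors,
    polygon_to_mask,
    rigid_register,
)
from cortexmap.synthetic import SlideSpec, generate_slide


@pytest.fixture(scope="module")
def tissue_mask_256():
    spec = SlideSpec(width_px=256, height_px=256, nucleus_count=0, particle_count=0, seed=1)
    _, gt = generate_slide(spec)
    return gt.tissue_mask


class TestRigidTransformAlgebra:
    @settings(derandomize=True, max_examples=50)
    @given(
        rot=st.floats(-170, 170),
        tx=st.floats(-50, 50),
        ty=st.floats(-50, 50),
    )
    def test_compose_with_inverse_is_identity(self, rot, tx, ty):
        t = RigidTransform(rot, tx, ty, center=(100.0, 80.0))
        resid = t.compose(t.invert())
        assert abs(resid.rotation_deg) <= 1e-6
        assert abs(resid.tx_px) <= 1e-6 and abs(resid.ty_px) <= 1e-6

    def test_rotation_normalized_to_half_open_interval(self):
        assert RigidTransform(270.0, 0, 0).rotation_deg == -90.0
        assert RigidTransform(-180.0, 0, 0).rotation_deg == 180.0

    def test_points_round_trip(self):
        t = RigidTransform(12.0, 5.0, -3.0, center=(10.0, 10.0))
        pts = np.array([[1.0, 2.0], [30.0, 4.0]])
        back = t.invert().apply_points(t.apply_points(pts))
        assert np.allclose(back, pts, atol=1e-9)


class TestApplyTransform:
    def test_identity_unchanged(self, tissue_mask_256):
        out = apply_transform(tissue_mask_256, RigidTransform.identity())
        assert np.array_equal(out, tissue_mask_256)

    def test_integer_translation_exact_on_mask(self, tissue_mask_256):
        t = RigidTransform(0.0, 7.0, -4.0)
        out = apply_transform(tissue_mask_256, t)
        assert np.array_equal(out[10:-10, 10:-10], tissue_mask_256[14:-6, 3:-17])

    def test_forward_then_inverse_recovers_density(self):
        rng = np.random.default_rng(0)
        from scipy.ndimage import gaussian_filter

        values = gaussian_filter(rng.exponential(size=(128, 128)), 3)
        dmap = DensityMap(values, um_per_px=1.0, kernel_radius_px=5)
        t = RigidTransform(8.0, 6.0, -3.0, center=(63.5, 63.5))
        round_trip = apply_transform(apply_transform(dmap, t), t.invert())
        inner = np.s_[20:-20, 20:-20]
        err = np.abs(round_trip.values[inner] - dmap.values[inner]).mean()
        assert err <= 0.01 * dmap.values.max()

    def test_validity_mask_marks_out_of_frame(self):
        arr = np.ones((32, 32))
        _, valid = apply_transform(arr, RigidTransform(0.0, 10.0, 0.0), return_valid=True)
        assert not valid[:, :9].any() and valid[:, 12:].all()


class TestRigidRegister:
    def test_self_registration_is_identity(self, tissue_mask_256):
        res = rigid_register(tissue_mask_256, tissue_mask_256)
        assert abs(res.transform.rotation_deg) <= 0.1
        assert np.hypot(res.transform.tx_px, res.transform.ty_px) <= 0.5
        assert res.overlap_after >= 0.999

    def test_recovers_known_transform(self, tissue_mask_256):
        center = (127.5, 127.5)
        t = RigidTransform(5.0, 10.0, -7.0, center=center)
        moving = apply_transform(tissue_mask_256, t)
        res = rigid_register(moving, tissue_mask_256)
        resid = res.transform.compose(t)
        assert abs(resid.rotation_deg) <= 0.5
        assert np.hypot(resid.tx_px, resid.ty_px) <= 1.0

    def test_alignment_never_reduces_overlap(self, tissue_mask_256):
        rng = np.random.default_rng(7)
        for _ in range(5):
            t = RigidTransform(rng.uniform(-10, 10), rng.uniform(-15, 15),
                               rng.uniform(-15, 15), center=(127.5, 127.5))
            moving = apply_transform(tissue_mask_256, t)
            res = rigid_register(moving, tissue_mask_256)
            assert res.overlap_after >= res.overlap_before

    def test_empty_backbone_rejected(self, tissue_mask_256):
        empty = np.zeros_like(tissue_mask_256)
        with pytest.raises(InsufficientBackboneError, match="insufficient backbone"):
            rigid_register(empty, tissue_mask_256)


class TestPolygonToMask:
    def test_rectangle_spans_exactly_100_pixel_centers(self):
        # pixel centers 3..12 in both axes lie inside; 2.6/12.4 avoid edges
        verts = np.array([[2.6, 2.6], [12.4, 2.6], [12.4, 12.4], [2.6, 12.4]])
        ann = AnnotationSet(polygons=[("cortex", verts)])
        mask = polygon_to_mask(ann, "cortex", (16, 16))
        assert mask.sum() == 100
        assert mask[3:13, 3:13].all()

    def test_empty_set_and_full_frame(self):
        ann = AnnotationSet(polygons=[])
        assert not polygon_to_mask(ann, "cortex", (8, 8)).any()
        full = AnnotationSet(
            polygons=[("cortex", np.array([[-1, -1], [8, -1], [8, 8], [-1, 8]]))]
        )
        assert polygon_to_mask(full, "cortex", (8, 8)).all()

    def test_scale_to_map_applied(self):
        verts = np.array([[20.8, 20.8], [99.2, 20.8], [99.2, 99.2], [20.8, 99.2]])
        ann = AnnotationSet(polygons=[("cortex", verts)], scale_to_map=0.125)
        mask = polygon_to_mask(ann, "cortex", (16, 16))
        assert mask.sum() == 100  # same rectangle after 1/8 scaling

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            AnnotationSet(polygons=[("cortex", np.array([[0, 0], [1, 1]]))])


class TestAnnotationIO:
    def test_geojson_round_trip(self, tmp_path):
        verts = np.array([[1.5, 2.5], [10.0, 2.0], [9.0, 11.0]])
        ann = AnnotationSet(polygons=[("cortex", verts), ("tumor", verts + 20)])
        path = tmp_path / "ann.geojson"
        write_geojson(ann, path)
        back = read_geojson(path)
        assert [lab for lab, _ in back.polygons] == ["cortex", "tumor"]
        assert np.allclose(back.polygons[0][1], verts)

    def test_minimal_scanner_xml(self, tmp_path):
        xml = """<annotations><ndpviewstate><title>cortex</title>
        <annotation><pointlist>
        <point><x>1.0</x><y>2.0</y></point>
        <point><x>5.0</x><y>2.0</y></point>
        <point><x>3.0</x><y>6.0</y></point>
        </pointlist></annotation></ndpviewstate></annotations>"""
        path = tmp_path / "ann.xml"
        path.write_text(xml)
        ann = read_annotation_xml(path)
        assert ann.polygons[0][0] == "cortex"
        assert np.allclose(ann.polygons[0][1], [[1, 2], [5, 2], [3, 6]])


class TestExtractCortexVectors:
    def _dmap(self, values):
        return DensityMap(np.asarray(values, dtype=float), um_per_px=8.0, kernel_radius_px=4)

    def test_row_count_equals_mask_conjunction(self):
        rng = np.random.default_rng(2)
        cortex = rng.random((40, 40)) < 0.5
        tissue = rng.random((40, 40)) < 0.7
        maps = {"nuclei": self._dmap(rng.random((40, 40)))}
        table = extract_cortex_vectors(maps, cortex, tissue)
        assert len(table) == int((cortex & tissue).sum())
        assert list(table.columns) == ["pixel_id", "tumor_cell_density"]

    def test_empty_cortex_yields_empty_table(self):
        maps = {"nuclei": self._dmap(np.ones((8, 8)))}
        table = extract_cortex_vectors(maps, np.zeros((8, 8), bool), np.ones((8, 8), bool))
        assert len(table) == 0

    def test_missing_markers_are_absent_not_zero(self):
        maps = {"NeuN": self._dmap(np.ones((8, 8))), "Abeta": self._dmap(np.ones((8, 8)))}
        table = extract_cortex_vectors(maps, np.ones((8, 8), bool), np.ones((8, 8), bool))
        assert "ptau_density" not in table.columns
        assert list(table.columns) == ["pixel_id", "neun_density", "abeta_density"]

    def test_grid_mismatch_names_marker(self):
        maps = {"pTau": self._dmap(np.ones((9, 8)))}
        with pytest.raises(GridMismatchError, match="pTau"):
            extract_cortex_vectors(maps, np.ones((8, 8), bool), np.ones((8, 8), bool))

    def test_mean_cortex_density_matches_ground_truth(self, small_slide, small_analysis):
        """Disk-kernel nuclei density averaged over cortex approximates the
        true nuclei count per cortex area within 10%."""
        import shapely

        from cortexmap._geometry import polygon_mask
        from cortexmap.density import PipelineScales, centroid_count_map, density_from_centroids

        image, gt = small_slide
        scales = PipelineScales(um_per_px=image.um_per_px, kernel_radius_px=60)
        counts = centroid_count_map(small_analysis["nuclei"], image.shape)
        dmap = density_from_centroids(counts, scales)
        cortex = polygon_mask(
            np.asarray(gt.cortex_polygon.exterior.coords)[:-1], image.shape
        )
        table = extract_cortex_vectors({"nuclei": dmap}, cortex, gt.tissue_mask)
        mean_density = table["tumor_cell_density"].mean()  # per mm^2
        inside = shapely.contains_xy(
            gt.cortex_polygon, gt.nucleus_centroids[:, 0], gt.nucleus_centroids[:, 1]
        )
        area_mm2 = cortex.sum() * (image.um_per_px * 1e-3) ** 2
        truth = inside.sum() / area_mm2
        assert abs(mean_density - truth) / truth <= 0.10
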