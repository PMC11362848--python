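"""Stain estimation, tissue masking, pixel classification and segmentation,
checked against synthetic ground truth and exhaustive small-raster oracles."""

import numpy as np
import pytest

from cortexmap.stains import (
    ClassifierParams,
    DegenerateImageError,
    PixelLabel,
    StainReference,
    classify_pixels,
    estimate_stain_vectors,
    segment_nuclei,
    segment_particles,
    tissue_mask,
)
from cortexmap.synthetic import (
    DEFAULT_HEMATOXYLIN_RGB,
    DEFAULT_IMMUNOSTAIN_RGB,
    DEFAULT_TISSUE_RGB,
)


def _flood_fill_centroids(binary: np.ndarray) -> set:
    """Exhaustive 8-connected component centroids (independent BFS oracle)."""
    visited = np.zeros_like(binary, dtype=bool)
    h, w = binary.shape
    out = set()
    for r0 in range(h):
        for c0 in range(w):
            if binary[r0, c0] and not visited[r0, c0]:
                stack, comp = [(r0, c0)], []
                visited[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    comp.append((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and binary[rr, cc] and not visited[rr, cc]:
                                visited[rr, cc] = True
                                stack.append((rr, cc))
                comp = np.asarray(comp, dtype=float)
                out.add((round(comp[:, 1].mean(), 6), round(comp[:, 0].mean(), 6)))
    return out


class TestEstimateStainVectors:
    def test_constant_and_two_point_means(self):
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        img[:] = (130, 80, 40)
        img[0, 0] = (100, 100, 100)
        img[0, 1] = (120, 80, 60)
        ref = estimate_stain_vectors(img, immuno_px=[(2, 2)] * 10, hema_px=[(0, 0), (1, 0)])
        assert np.allclose(ref.immunostain_rgb, (130, 80, 40))
        assert np.allclose(ref.hematoxylin_rgb, (110, 90, 80))
        assert ref.source_pixel_count == (10, 2)

    def test_errors_name_the_offence(self):
        img = np.full((4, 4, 3), 100, dtype=np.uint8)
        with pytest.raises(ValueError, match=r"\(9, 0\)"):
            estimate_stain_vectors(img, [(9, 0)], [(0, 0)])
        with pytest.raises(ValueError, match="no immunostain"):
            estimate_stain_vectors(img, [], [(0, 0)])

    def test_recovers_generator_stains_within_jitter(self, small_slide, small_spec):
        image, gt = small_slide
        hema_px = [(int(round(x)), int(round(y))) for x, y in gt.nucleus_centroids[:10]]
        immuno_px = [(int(round(x)), int(round(y))) for x, y in gt.particle_centroids[:10]]
        ref = estimate_stain_vectors(image, immuno_px, hema_px)
        sd = small_spec.color_jitter_sd
        assert np.linalg.norm(ref.hematoxylin_rgb - np.asarray(DEFAULT_HEMATOXYLIN_RGB)) < 2 * sd
        assert np.linalg.norm(ref.immunostain_rgb - np.asarray(DEFAULT_IMMUNOSTAIN_RGB)) < 2 * sd


class TestTissueMask:
    def test_matches_ground_truth_polygon(self, small_slide, small_analysis):
        _, gt = small_slide
        mask = small_analysis["tissue"]
        inter = np.logical_and(mask, gt.tissue_mask).sum()
        union = np.logical_or(mask, gt.tissue_mask).sum()
        assert inter / union >= 0.95

    def test_constant_blue_is_degenerate(self):
        img = np.full((16, 16, 3), 200, dtype=np.uint8)
        with pytest.raises(DegenerateImageError, match="degenerate threshold"):
            tissue_mask(img)

    def test_open_close_preserves_large_disk_interior(self):
        # erosion followed by dilation on a convex disk only nibbles a
        # <=1 px boundary band (checked against the distance transform).
        from scipy.ndimage import distance_transform_edt

        img = np.zeros((64, 64, 3), dtype=np.uint8)
        img[:] = 255
        yy, xx = np.mgrid[:64, :64]
        inside = (xx - 32) ** 2 + (yy - 32) ** 2 <= 20**2
        img[inside] = (100, 100, 100)
        mask = tissue_mask(img, ClassifierParams(tissue_morph_radius_px=3))
        changed = mask != inside
        dist_to_edge = distance_transform_edt(inside)
        assert not changed[dist_to_edge > 1.5].any()


class TestClassifyPixels:
    def test_reference_directions_and_scale_invariance(self, stain_ref):
        img = np.empty((8, 3, 3), dtype=float)
        img[:] = DEFAULT_TISSUE_RGB
        img[4:] = 250.0  # bright background half drives the blue-mean split
        img[0, 0] = stain_ref.hematoxylin_rgb
        img[0, 1] = np.asarray(stain_ref.immunostain_rgb) * 0.5  # angle is scale-free
        img[0, 2] = DEFAULT_TISSUE_RGB
        params = ClassifierParams(tissue_morph_radius_px=0)
        labels = classify_pixels(img, stain_ref, params).labels
        assert labels[0, 0] == PixelLabel.HEMATOXYLIN
        assert labels[0, 1] == PixelLabel.IMMUNOSTAIN
        assert labels[0, 2] == PixelLabel.UNSTAINED
        assert labels[5, 0] == PixelLabel.BACKGROUND

    def test_global_intensity_scaling_leaves_labels_unchanged(self, small_slide, stain_ref):
        image, _ = small_slide
        base = classify_pixels(image.rgb.astype(float), stain_ref).labels
        for k in (0.6, 0.3):
            scaled = classify_pixels(image.rgb.astype(float) * k, stain_ref).labels
            assert np.array_equal(scaled, base)

    def test_label_partition_is_exhaustive(self, small_slide, small_analysis):
        image, _ = small_slide
        counts = small_analysis["labels"].counts()
        assert sum(counts.values()) == image.rgb.shape[0] * image.rgb.shape[1]

    def test_blob_cores_classified_correctly(self, small_slide, small_analysis):
        image, gt = small_slide
        labels = small_analysis["labels"].labels
        for pts, radii, want in (
            (gt.nucleus_centroids, gt.nucleus_radii, PixelLabel.HEMATOXYLIN),
            (gt.particle_centroids, gt.particle_radii, PixelLabel.IMMUNOSTAIN),
        ):
            hits = total = 0
            for (x, y), r in zip(pts, radii):
                xi, yi = int(round(x)), int(round(y))
                core = labels[yi - 1 : yi + 2, xi - 1 : xi + 2]
                hits += int((core == want).sum())
                total += core.size
            assert hits / total >= 0.95

    def test_zero_norm_pixel_is_unstained(self, stain_ref):
        img = np.empty((8, 2, 3), dtype=float)
        img[:] = DEFAULT_TISSUE_RGB
        img[4:] = 255.0
        img[0, 0] = (0, 0, 0)  # pure black tissue pixel
        params = ClassifierParams(tissue_morph_radius_px=0)
        labels = classify_pixels(img, stain_ref, params).labels
        assert labels[0, 0] == PixelLabel.UNSTAINED


class TestSegmentation:
    def test_empty_slide_yields_empty_lists(self, stain_ref):
        from cortexmap.synthetic import SlideSpec, generate_slide

        image, _ = generate_slide(
            SlideSpec(width_px=128, height_px=128, nucleus_count=0, particle_count=0, seed=0)
        )
        assert len(segment_nuclei(image, stain_ref)) == 0
        assert len(segment_particles(image, stain_ref)) == 0

    def test_recovers_counts_and_centroids(self, small_slide, small_analysis, small_spec):
        from scipy.spatial import cKDTree

        _, gt = small_slide
        nuclei = small_analysis["nuclei"]
        particles = small_analysis["particles"]
        assert abs(len(nuclei) - small_spec.nucleus_count) <= 0.05 * small_spec.nucleus_count
        assert abs(len(particles) - small_spec.particle_count) <= 0.05 * small_spec.particle_count
        d, _ = cKDTree(gt.nucleus_centroids).query(nuclei)
        assert d.mean() <= 2.0

    def test_small_raster_matches_flood_fill_oracle(self, stain_ref):
        """On rasters <= 32x32 the centroids equal an exhaustive BFS oracle."""
        img = np.empty((32, 24, 3), dtype=float)
        img[:] = DEFAULT_TISSUE_RGB
        img[:14, :] = 252.0  # bright background half fixes the blue-mean split
        for x, y in [(5, 18), (14, 27), (19, 20)]:
            img[y - 1 : y + 2, x - 1 : x + 2] = DEFAULT_HEMATOXYLIN_RGB
        params = ClassifierParams(erosion_radius_px=0, tissue_morph_radius_px=0)
        got = segment_nuclei(img, stain_ref, params)
        # independent binary reconstruction of the thresholded set
        tmask = img[:, :, 2] < img[:, :, 2].mean()
        absorb = 255.0 - img
        s = 255.0 - np.asarray(DEFAULT_HEMATOXYLIN_RGB)
        proj = absorb @ (s / np.linalg.norm(s))
        norm = (proj - proj[tmask].min()) / (proj[tmask].max() - proj[tmask].min())
        lab = classify_pixels(img, stain_ref, params).labels
        binary = tmask & (lab == PixelLabel.HEMATOXYLIN) & (norm >= 0.30)
        want = _flood_fill_centroids(binary)
        assert {(round(x, 6), round(y, 6)) for x, y in got} == want

    def test_merged_blobs_yield_one_centroid(self, stain_ref):
        img = np.empty((32, 24, 3), dtype=float)
        img[:] = DEFAULT_TISSUE_RGB
        img[:14, :] = 252.0
        img[20:25, 6:11] = DEFAULT_HEMATOXYLIN_RGB
        img[20:25, 10:15] = DEFAULT_HEMATOXYLIN_RGB  # touching squares
        params = ClassifierParams(erosion_radius_px=0, tissue_morph_radius_px=0)
        assert len(segment_nuclei(img, stain_ref, params)) == 1

    @pytest.mark.parametrize("which", ["nuclei", "particles"])
    def test_count_monotone_in_projection_threshold(self, small_slide, stain_ref, which):
        image, _ = small_slide
        counts = []
        for thr in (0.2, 0.3, 0.4, 0.6):
            if which == "nuclei":
                params = ClassifierParams(hema_projection_threshold=thr)
                counts.append(len(segment_nuclei(image, stain_ref, params)))
            else:
                params = ClassifierParams(immuno_projection_threshold=thr)
                counts.append(len(segment_particles(image, stain_ref, params)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ClassifierParams(hema_projection_threshold=0.0)
        with pytest.raises(ValueError):
            StainReference(immunostain_rgb=(0, 0, 0), hematoxylin_rgb=(1, 1, 1))
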