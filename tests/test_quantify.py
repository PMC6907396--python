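"""Region adjacency, per-tile morphometrics, prism profiles, evaluation."""

import numpy as np
import pytest

from tilewalk import (
    IntensityVolume,
    LabelVolume,
    build_rag,
    columnar_prism_phantom,
    evaluate_segmentation,
    hexagonal_tiling_phantom,
    neighbor_histogram,
    prism_profiles,
    tile_stats,
)
from tilewalk.phantoms import hex_interior_labels


class TestRag:
    def test_face_contact_counting(self):
        data = np.zeros((2, 2, 4), dtype=np.int32)
        data[:, :, :2] = 1
        data[:, :, 2:] = 2  # 2x2 = 4 face-adjacent pairs
        rag = build_rag(LabelVolume(data))
        assert rag.number_of_edges() == 1
        assert rag.edges[1, 2]["contact_count"] == 4

    def test_min_contact_threshold(self):
        data = np.zeros((2, 2, 4), dtype=np.int32)
        data[:, :, :2] = 1
        data[:, :, 2:] = 2
        rag = build_rag(LabelVolume(data), min_contact=5)
        assert rag.number_of_edges() == 0
        assert set(rag.nodes) == {1, 2}  # nodes survive without edges

    def test_diagonal_contact_not_counted(self):
        data = np.zeros((1, 2, 2), dtype=np.int32)
        data[0, 0, 0] = 1
        data[0, 1, 1] = 2
        rag = build_rag(LabelVolume(data))
        assert rag.number_of_edges() == 0

    def test_background_never_a_node(self):
        data = np.zeros((2, 2, 2), dtype=np.int32)
        data[0, 0, 0] = 3
        rag = build_rag(LabelVolume(data))
        assert set(rag.nodes) == {3}


class TestHexNeighborCounts:
    def test_interior_tiles_have_six_neighbors(self):
        bundle = hexagonal_tiling_phantom(n_rows=5, n_cols=5, tile_radius=8,
                                          slab_thickness=8, seed=0)
        assert bundle.truth.n_labels == 25
        rag = build_rag(bundle.truth)
        interior = hex_interior_labels(5, 5)
        assert len(interior) == 9
        degs = [rag.degree(int(l)) for l in interior]
        assert degs == [6] * 9

    def test_interior_mean_exactly_six(self):
        bundle = hexagonal_tiling_phantom(n_rows=5, n_cols=5, tile_radius=8,
                                          slab_thickness=8, seed=0)
        rag = build_rag(bundle.truth)
        stats = tile_stats(bundle.truth, bundle.image, rag)
        interior = set(hex_interior_labels(5, 5).tolist())
        hist, mean = neighbor_histogram([s for s in stats if s.label in interior])
        assert mean == 6.0
        assert set(hist) == {6}

    def test_3x3_grid_single_interior(self):
        assert len(hex_interior_labels(3, 3)) == 1


class TestTileStats:
    def test_cube_volume_and_intensity(self):
        data = np.zeros((4, 4, 4), dtype=np.int32)
        data[1:3, 1:3, 1:3] = 1
        img = np.zeros((4, 4, 4))
        img[1:3, 1:3, 1:3] = [[[10, 20], [10, 20]], [[10, 20], [10, 20]]]
        labels = LabelVolume(data)
        stats = tile_stats(labels, IntensityVolume(img), build_rag(labels))
        (s,) = stats
        assert s.voxel_count == 8
        assert s.volume == 8.0
        assert s.mean_intensity == pytest.approx(15.0)
        assert s.centroid == pytest.approx((1.5, 1.5, 1.5))

    def test_spacing_scales_volume(self):
        data = np.ones((2, 2, 2), dtype=np.int32)
        labels = LabelVolume(data, spacing=(2.0, 1.0, 0.5))
        stats = tile_stats(labels, IntensityVolume(np.zeros((2, 2, 2))), build_rag(labels))
        assert stats[0].volume == pytest.approx(8 * 1.0)

    def test_sphere_extents_isotropic(self):
        zz, yy, xx = np.mgrid[:20, :20, :20]
        sphere = ((zz - 10) ** 2 + (yy - 10) ** 2 + (xx - 10) ** 2) <= 64
        labels = LabelVolume(sphere.astype(np.int32))
        stats = tile_stats(labels, IntensityVolume(np.zeros(labels.shape)), build_rag(labels))
        e = stats[0].principal_extents
        assert e[0] == pytest.approx(e[2], rel=0.1)
        assert e[0] >= e[1] >= e[2]

    def test_partition_conservation(self):
        rng = np.random.default_rng(3)
        data = rng.integers(0, 5, size=(6, 6, 6)).astype(np.int32)
        labels = LabelVolume(data)
        stats = tile_stats(labels, IntensityVolume(np.zeros(labels.shape)), build_rag(labels))
        assert sum(s.voxel_count for s in stats) == int((data > 0).sum())

    def test_shape_mismatch_rejected(self):
        labels = LabelVolume(np.ones((2, 2, 2), dtype=np.int32))
        with pytest.raises(ValueError):
            tile_stats(labels, IntensityVolume(np.zeros((3, 3, 3))), build_rag(labels))


class TestNeighborHistogram:
    def test_counts_fractions_mean(self):
        from tilewalk.quantify import TileStats

        def ts(n):
            return TileStats(1, 1, 1.0, n, 0.0, (0, 0, 0), (0, 0, 0))

        hist, mean = neighbor_histogram([ts(6), ts(6), ts(5), ts(7)])
        assert hist == {5: (1, 0.25), 6: (2, 0.5), 7: (1, 0.25)}
        assert mean == 6.0
        assert sum(f for _, f in hist.values()) == pytest.approx(1.0)

    def test_single_tile(self):
        from tilewalk.quantify import TileStats

        hist, mean = neighbor_histogram(
            [TileStats(1, 1, 1.0, 4, 0.0, (0, 0, 0), (0, 0, 0))]
        )
        assert mean == 4.0


class TestPrismProfiles:
    def test_constant_cylinder_flat_profile(self):
        zz = np.zeros((40, 24, 24), dtype=np.int32)
        yy, xx = np.mgrid[:24, :24]
        disk = ((yy - 12) ** 2 + (xx - 12) ** 2) <= 100
        zz[:, disk] = 1
        (p,) = prism_profiles(LabelVolume(zz))
        assert np.all(np.abs(p.radius - p.radius.mean()) <= 1.0)
        assert abs(p.slope) < 0.02

    def test_truncated_cone_slope(self):
        # radius shrinks linearly 12 -> 6 over 60 slices: slope -0.1/slice
        nz = 60
        data = np.zeros((nz, 30, 30), dtype=np.int32)
        yy, xx = np.mgrid[:30, :30]
        for z in range(nz):
            r = 12.0 - 6.0 * z / (nz - 1)
            data[z, ((yy - 15) ** 2 + (xx - 15) ** 2) <= r * r] = 1
        (p,) = prism_profiles(LabelVolume(data))
        assert p.slope == pytest.approx(-0.1, rel=0.1)
        assert p.growth_class == "shrinking"

    def test_phantom_growth_classes_match_truth(self):
        bundle = columnar_prism_phantom(shape=(48, 96, 96), n_seeds=30,
                                        coarsening_rate=8.0, seed=4)
        profiles = prism_profiles(bundle.truth)
        classes = bundle.params["growth_class"]
        usable = [p for p in profiles if np.isfinite(p.slope)]
        agree = sum(p.growth_class == classes[p.label] for p in usable)
        assert agree / len(usable) >= 0.95

    def test_short_labels_get_nan_slope(self):
        data = np.zeros((5, 4, 4), dtype=np.int32)
        data[:, :2, :2] = 1
        data[2, 3, 3] = 2  # present in a single slice
        profiles = {p.label: p for p in prism_profiles(LabelVolume(data))}
        assert np.isfinite(profiles[1].slope)
        assert np.isnan(profiles[2].slope)


class TestEvaluation:
    def test_identity_is_perfect(self):
        rng = np.random.default_rng(0)
        data = rng.integers(0, 4, size=(5, 5, 5)).astype(np.int32)
        lab = LabelVolume(data)
        rep = evaluate_segmentation(lab, lab)
        assert rep.n_matched_one_to_one == lab.n_labels
        assert rep.n_split == 0
        assert rep.n_merged == 0

    def test_split_detection(self):
        truth = np.zeros((2, 2, 4), dtype=np.int32)
        truth[..., :] = 1
        pred = truth.copy()
        pred[..., 2:] = 2
        rep = evaluate_segmentation(LabelVolume(pred), LabelVolume(truth))
        assert rep.n_split == 1
        assert rep.n_matched_one_to_one == 0

    def test_merge_detection(self):
        truth = np.zeros((2, 2, 4), dtype=np.int32)
        truth[..., :2] = 1
        truth[..., 2:] = 2
        pred = np.ones_like(truth)
        rep = evaluate_segmentation(LabelVolume(pred), LabelVolume(truth))
        assert rep.n_merged >= 1

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate_segmentation(
                LabelVolume(np.ones((2, 2, 2), dtype=np.int32)),
                LabelVolume(np.ones((3, 3, 3), dtype=np.int32)),
            )
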