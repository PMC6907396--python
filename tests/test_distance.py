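"""Random-walk and Euclidean distance transforms.

The analytic RWDT cases are hand-solved linear systems: a single voxel with
all neighbors absorbing gives h = 1; two face-adjacent foreground voxels in
open background solve h = 1 + h/6, i.e. h = 1.2; the 1x1x3 bar gives, by
symmetry, ends 21/17 and center 24/17.
"""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from tilewalk import (
    BinaryMask,
    DistanceMap,
    WalkSpec,
    euclidean_distance,
    minmax_normalize,
    monte_carlo_walk_length,
    random_walk_distance,
    ensemble_rwdt,
    IntensityVolume,
)
from tilewalk.distance import BackgroundUnreachableError


def random_mask(shape, fill, seed):
    rng = np.random.default_rng(seed)
    return BinaryMask(rng.random(shape) < fill)


def brute_force_edt(mask: BinaryMask) -> np.ndarray:
    """All-pairs oracle: min distance from each fg voxel center to any bg center."""
    fg = np.argwhere(mask.data)
    bg = np.argwhere(~mask.data)
    out = np.zeros(mask.shape)
    d = cdist(fg, bg).min(axis=1)
    out[tuple(fg.T)] = d
    return out


class TestRandomWalkDistance:
    def test_single_voxel_absorbs_in_one_step(self, single_voxel_mask):
        d = random_walk_distance(single_voxel_mask)
        assert d.data[1, 1, 1] == pytest.approx(1.0, abs=1e-9)

    def test_two_adjacent_voxels(self):
        m = np.zeros((3, 3, 4), dtype=bool)
        m[1, 1, 1] = m[1, 1, 2] = True
        d = random_walk_distance(BinaryMask(m))
        assert d.data[1, 1, 1] == pytest.approx(1.2, abs=1e-9)
        assert d.data[1, 1, 2] == pytest.approx(1.2, abs=1e-9)

    def test_1x1x3_bar(self):
        m = np.zeros((3, 3, 5), dtype=bool)
        m[1, 1, 1:4] = True
        d = random_walk_distance(BinaryMask(m))
        assert d.data[1, 1, 1] == pytest.approx(21 / 17, abs=1e-9)
        assert d.data[1, 1, 2] == pytest.approx(24 / 17, abs=1e-9)
        assert d.data[1, 1, 3] == pytest.approx(21 / 17, abs=1e-9)

    def test_background_zero_foreground_at_least_one(self):
        mask = random_mask((8, 8, 8), 0.5, seed=3)
        d = random_walk_distance(mask)
        assert (d.data[~mask.data] == 0).all()
        assert (d.data[mask.data] >= 1.0 - 1e-9).all()

    def test_h_equals_one_iff_fully_absorbing_neighbors(self):
        mask = random_mask((8, 8, 8), 0.4, seed=4)
        d = random_walk_distance(mask)
        ones = np.isclose(d.data, 1.0) & mask.data
        # a voxel with h == 1 must have no foreground stencil neighbor
        from tilewalk._stencil import stencil_offsets

        for z, y, x in np.argwhere(ones):
            for dz, dy, dx in stencil_offsets(6):
                nz, ny, nx = z + dz, y + dy, x + dx
                if 0 <= nz < 8 and 0 <= ny < 8 and 0 <= nx < 8:
                    assert not mask.data[nz, ny, nx]

    def test_linear_system_residual_contract(self):
        spec = WalkSpec(solver_tolerance=1e-8)
        mask = random_mask((10, 10, 10), 0.6, seed=5)
        d = random_walk_distance(mask, spec)
        # rebuild the system and verify the advertised residual bound
        from tilewalk.distance import _walk_graph
        from scipy.sparse import diags

        fg_flat, _, deg, a_ff = _walk_graph(mask, spec)
        h = d.data.ravel()[fg_flat]
        res = np.linalg.norm((diags(deg) - a_ff) @ h - deg) / np.linalg.norm(deg)
        assert res <= spec.solver_tolerance

    def test_mirror_symmetry(self):
        mask = random_mask((6, 7, 8), 0.5, seed=6)
        d = random_walk_distance(mask)
        mirrored = BinaryMask(mask.data[:, :, ::-1].copy())
        d_m = random_walk_distance(mirrored)
        np.testing.assert_allclose(d_m.data, d.data[:, :, ::-1], atol=1e-7)

    def test_unreachable_background_raises(self):
        mask = BinaryMask(np.ones((3, 3, 3), dtype=bool))
        with pytest.raises(BackgroundUnreachableError):
            random_walk_distance(mask)  # reflecting border, no background

    def test_absorbing_border_makes_full_mask_solvable(self):
        mask = BinaryMask(np.ones((3, 3, 3), dtype=bool))
        d = random_walk_distance(mask, WalkSpec(border="absorbing"))
        assert d.data.min() > 0

    def test_empty_foreground_raises(self):
        with pytest.raises(ValueError):
            random_walk_distance(BinaryMask(np.zeros((3, 3, 3), dtype=bool)))

    @pytest.mark.parametrize("connectivity", [18, 26])
    def test_wider_stencils_single_voxel(self, single_voxel_mask, connectivity):
        d = random_walk_distance(single_voxel_mask, WalkSpec(connectivity=connectivity))
        assert d.data[1, 1, 1] == pytest.approx(1.0, abs=1e-9)


class TestMonteCarloOracle:
    def test_single_voxel_exact(self, single_voxel_mask):
        mean, se = monte_carlo_walk_length(single_voxel_mask, (1, 1, 1), n_walks=200, seed=0)
        assert mean == 1.0
        assert se == 0.0

    def test_two_voxel_matches_analytic(self):
        m = np.zeros((3, 3, 4), dtype=bool)
        m[1, 1, 1] = m[1, 1, 2] = True
        mean, se = monte_carlo_walk_length(BinaryMask(m), (1, 1, 1), n_walks=50_000, seed=1)
        assert abs(mean - 1.2) <= 3 * se

    def test_deterministic_under_seed(self, single_voxel_mask):
        m = random_mask((6, 6, 6), 0.5, seed=7)
        vox = tuple(np.argwhere(m.data)[0])
        r1 = monte_carlo_walk_length(m, vox, n_walks=500, seed=42)
        r2 = monte_carlo_walk_length(m, vox, n_walks=500, seed=42)
        assert r1 == r2

    def test_agrees_with_solver_on_random_masks(self):
        rng = np.random.default_rng(11)
        for i in range(3):
            mask = random_mask((10, 10, 10), 0.3 + 0.2 * i, seed=20 + i)
            d = random_walk_distance(mask)
            fg = np.argwhere(mask.data)
            probes = fg[rng.choice(len(fg), size=4, replace=False)]
            for vox in probes:
                vox = tuple(int(c) for c in vox)
                mean, se = monte_carlo_walk_length(mask, vox, n_walks=20_000,
                                                   seed=int(rng.integers(2**31)))
                assert abs(d.data[vox] - mean) <= 3 * max(se, 1e-12) + 1e-9


class TestEuclideanDistance:
    def test_single_voxel(self, single_voxel_mask):
        d = euclidean_distance(single_voxel_mask)
        assert d.data[1, 1, 1] == pytest.approx(1.0)

    def test_3x3_plate(self):
        m = np.zeros((3, 5, 5), dtype=bool)
        m[1, 1:4, 1:4] = True
        d = euclidean_distance(BinaryMask(m))
        assert d.data[1, 2, 2] == pytest.approx(1.0)  # background one slice above
        m2 = np.zeros((1, 5, 5), dtype=bool)
        m2[0, 1:4, 1:4] = True
        d2 = euclidean_distance(BinaryMask(m2))
        assert d2.data[0, 2, 2] == pytest.approx(2.0)
        assert d2.data[0, 1, 1] == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        for seed in range(5):
            mask = random_mask((20, 20, 20), 0.3 + 0.1 * seed, seed=seed)
            if mask.data.all() or not mask.data.any():
                continue
            d = euclidean_distance(mask)
            np.testing.assert_allclose(d.data, brute_force_edt(mask), atol=1e-9)

    def test_spacing_scales_distances(self):
        m = np.zeros((5, 3, 3), dtype=bool)
        m[2, 1, 1] = True
        mask = BinaryMask(m, spacing=(3.0, 1.0, 1.0))
        d = euclidean_distance(mask, use_spacing=True)
        assert d.data[2, 1, 1] == pytest.approx(1.0)  # in-plane neighbor closest

    def test_all_foreground_raises(self):
        with pytest.raises(ValueError):
            euclidean_distance(BinaryMask(np.ones((2, 2, 2), dtype=bool)))

    def test_empty_foreground_all_zero(self):
        d = euclidean_distance(BinaryMask(np.zeros((2, 2, 2), dtype=bool)))
        assert (d.data == 0).all()


class TestNormalizeAndEnsemble:
    def test_minmax_affine(self):
        m = BinaryMask(np.array([[[True, True, True, False]]]))
        dmap = DistanceMap(np.array([[[2.0, 4.0, 6.0, 0.0]]]), m)
        out = minmax_normalize(dmap)
        np.testing.assert_allclose(out.data[0, 0], [0.0, 0.5, 1.0, 0.0])

    def test_minmax_idempotent(self):
        m = BinaryMask(np.array([[[True, True, True, False]]]))
        dmap = DistanceMap(np.array([[[0.0, 0.5, 1.0, 0.0]]]), m)
        out = minmax_normalize(dmap)
        np.testing.assert_allclose(out.data, dmap.data)

    def test_constant_foreground_maps_to_one(self):
        m = BinaryMask(np.array([[[True, True, False]]]))
        dmap = DistanceMap(np.array([[[3.0, 3.0, 0.0]]]), m)
        out = minmax_normalize(dmap)
        np.testing.assert_allclose(out.data[0, 0], [1.0, 1.0, 0.0])

    def test_single_threshold_reduces_to_normalized_rwdt(self):
        from tilewalk import threshold_mask

        rng = np.random.default_rng(0)
        img = np.full((6, 10, 10), 50.0)
        img[2:5, 2:8, 2:8] = 200.0
        vol = IntensityVolume(img)
        ens = ensemble_rwdt(vol, [125.0])
        direct = minmax_normalize(random_walk_distance(threshold_mask(vol, 125.0)))
        np.testing.assert_allclose(ens.data, direct.data, atol=1e-12)

    def test_identical_masks_average_to_single_result(self):
        img = np.full((6, 10, 10), 50.0)
        img[2:5, 2:8, 2:8] = 200.0
        vol = IntensityVolume(img)
        two = ensemble_rwdt(vol, [100.0, 125.0])  # same mask at both thresholds
        one = ensemble_rwdt(vol, [125.0])
        np.testing.assert_allclose(two.data, one.data, atol=1e-12)

    def test_threshold_fragile_bridge_dips(self):
        # two blocks joined by a bridge that exists only at the lower
        # threshold: the averaged map must dip at the bridge below both
        # tile interiors
        img = np.full((5, 7, 13), 0.0)
        img[1:4, 2:5, 1:6] = 200.0
        img[1:4, 2:5, 7:12] = 200.0
        img[2, 3, 6] = 100.0  # bridge voxel, disappears at t=150
        vol = IntensityVolume(img)
        ens = ensemble_rwdt(vol, [50.0, 150.0])
        bridge = ens.data[2, 3, 6]
        left = ens.data[2, 3, 3]
        right = ens.data[2, 3, 9]
        assert bridge < left
        assert bridge < right

    def test_strictly_increasing_thresholds_required(self):
        vol = IntensityVolume(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            ensemble_rwdt(vol, [1.0, 1.0])
        with pytest.raises(ValueError):
            ensemble_rwdt(vol, [])


def test_rwdt_more_noise_robust_than_edt():
    """Pore noise barely changes RWDT ranks but degrades EDT ranks."""
    from scipy.stats import spearmanr

    from tilewalk import inject_pore_noise, voronoi_tiling_phantom

    bundle = voronoi_tiling_phantom(shape=(12, 64, 64), n_tiles=6,
                                    slab_thickness=8, seed=2)
    noisy = inject_pore_noise(bundle.mask, 0.01, seed=9)
    shared = bundle.mask.data & noisy.data
    rw_c = random_walk_distance(bundle.mask)
    rw_n = random_walk_distance(noisy)
    ed_c = euclidean_distance(bundle.mask)
    ed_n = euclidean_distance(noisy)
    rw_rho = spearmanr(rw_c.data[shared], rw_n.data[shared]).statistic
    ed_rho = spearmanr(ed_c.data[shared], ed_n.data[shared]).statistic
    assert rw_rho >= 0.95
    assert ed_rho < rw_rho
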