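import numpy as np
import pytest

from _oracles import brute_ball_fraction, brute_min_distance
from conftest import make_mask
from packfrac.geometry import VoxelSpec
from packfrac.metrics import (
    NeighborhoodParams,
    biovolume,
    centroid_voxels,
    manders_overlap,
    min_distance_to_mask,
    neighborhood_biovolume_fraction,
    shell_mean_intensity,
    summarize_distances,
)
from packfrac.segmentation import dissect_grid


class TestNeighborhoodFraction:
    def test_all_foreground_gives_unity_everywhere(self):
        mask = make_mask(np.ones((16, 16, 16), bool))
        cubes = dissect_grid(mask, cube_edge_um=2.0)
        tab = neighborhood_biovolume_fraction(mask, cubes, NeighborhoodParams(6.0, 2.0))
        assert (tab.neighborhood_fraction == 1.0).all()

    def test_isolated_cube_analytic_ratio(self):
        # an isolated 0.8 um cube in a big empty image: fraction ~ cube/ball
        voxel = VoxelSpec(dx=0.2, dy=0.2, dz=0.2, shape=(80, 80, 80))
        arr = np.zeros(voxel.shape, dtype=bool)
        arr[40:44, 40:44, 40:44] = True  # one full 0.8 um cube
        mask = make_mask(arr, dx=0.2, dy=0.2, dz=0.2)
        cubes = dissect_grid(mask, cube_edge_um=0.8)
        assert cubes.n_cubes == 1
        tab = neighborhood_biovolume_fraction(mask, cubes)
        expected = 0.8**3 / (4 / 3 * np.pi * 6**3)
        # one-voxel-shell tolerance on the discrete ball volume
        ball_vox = 4 / 3 * np.pi * 6**3 / 0.2**3
        shell_vox = 4 * np.pi * 6**2 * 0.2 / 0.2**3
        tol = expected * shell_vox / ball_vox
        assert tab.neighborhood_fraction[0] == pytest.approx(expected, abs=3 * tol)

    def test_empty_cube_set_empty_table(self):
        mask = make_mask(np.zeros((8, 8, 8), bool))
        cubes = dissect_grid(mask, cube_edge_um=2.0)
        tab = neighborhood_biovolume_fraction(mask, cubes, NeighborhoodParams(3.0, 2.0))
        assert len(tab) == 0

    @pytest.mark.parametrize("spacing", [(1.0, 1.0, 1.0), (0.4, 0.4, 1.0)])
    def test_matches_bruteforce_exactly_on_random_masks(self, rng, spacing):
        # identical discretization: exact equality, including anisotropy
        dx, dy, dz = spacing
        for _ in range(5):
            arr = rng.random((20, 20, 20)) < 0.3
            mask = make_mask(arr, dx=dx, dy=dy, dz=dz)
            cubes = dissect_grid(mask, cube_edge_um=2.0)
            tab = neighborhood_biovolume_fraction(mask, cubes, NeighborhoodParams(4.0, 2.0))
            centers = centroid_voxels(cubes)
            for i in rng.choice(cubes.n_cubes, size=min(25, cubes.n_cubes), replace=False):
                ref = brute_ball_fraction(arr, (dz, dy, dx), centers[i], 4.0)
                assert tab.neighborhood_fraction[i] == ref

    def test_zero_padding_denominator_mode(self):
        mask = make_mask(np.ones((10, 10, 10), bool))
        cubes = dissect_grid(mask, cube_edge_um=2.0)
        tab = neighborhood_biovolume_fraction(
            mask, cubes, NeighborhoodParams(4.0, 2.0, boundary_mode="zero_padding")
        )
        # corner cubes lose most of their ball to padding; center stays 1
        assert tab.neighborhood_fraction.min() < 0.3
        mid = tab[(tab.cx_um == 5.0) & (tab.cy_um == 5.0) & (tab.cz_um == 5.0)]
        assert np.allclose(mid.neighborhood_fraction, 1.0)

    def test_monotone_in_added_foreground(self, rng):
        base = rng.random((14, 14, 14)) < 0.2
        extra = base | (rng.random((14, 14, 14)) < 0.2)
        m1, m2 = make_mask(base), make_mask(extra)
        cubes = dissect_grid(m1, cube_edge_um=2.0)
        p = NeighborhoodParams(4.0, 2.0)
        f1 = neighborhood_biovolume_fraction(m1, cubes, p).neighborhood_fraction
        f2 = neighborhood_biovolume_fraction(m2, cubes, p).neighborhood_fraction
        assert (f2 >= f1).all()
        assert ((f1 >= 0) & (f1 <= 1)).all()

    def test_cube_fractions_agree_with_scene_oracle(self, loose_scene, loose_stack):
        # production path vs ground-truth supersampling oracle: +-0.03
        from packfrac.scene import true_local_fraction
        from packfrac.segmentation import segment_stack

        _, joint, _ = segment_stack(loose_stack, ["vibrio", "ecoli"])
        cubes = dissect_grid(joint)
        tab = neighborhood_biovolume_fraction(joint, cubes)
        rng = np.random.default_rng(1)
        idx = rng.choice(len(tab), size=20, replace=False)
        for i in idx:
            point = (tab.cx_um[i], tab.cy_um[i], tab.cz_um[i])
            oracle = true_local_fraction(loose_scene, point, 6.0)
            assert tab.neighborhood_fraction[i] == pytest.approx(oracle, abs=0.03)


class TestShellIntensity:
    def test_uniform_channel_returns_constant(self):
        arr = np.zeros((10, 10, 10), bool)
        arr[4:6, 4:6, 4:6] = True
        mask = make_mask(arr)
        assert shell_mean_intensity(mask, np.full(arr.shape, 7.5), 2.0) == 7.5

    def test_interior_excluded(self):
        arr = np.zeros((10, 10, 10), bool)
        arr[4:6, 4:6, 4:6] = True
        intensity = np.where(arr, 100.0, 0.0)
        assert shell_mean_intensity(make_mask(arr), intensity, 2.0) == 0.0

    def test_empty_target_gives_nan(self):
        mask = make_mask(np.zeros((6, 6, 6), bool))
        assert np.isnan(shell_mean_intensity(mask, np.ones((6, 6, 6)), 2.0))

    def test_embedded_species_sees_brighter_partner_shell(self):
        # partner fluorescence within 2 um is higher around embedded focal
        # cells than around peripheral ones — the protection signature
        from packfrac.geometry import CellGeom, Region, SceneGroundTruth
        from packfrac.scene import OpticsParams, generate_scene, rasterize_scene
        from packfrac.segmentation import segment_stack
        from packfrac.stack import SpeciesMask

        dense = Region(
            "emb", (0, 0, 0), (8, 16, 8), 0.9, "embedded_basal_layer",
            species=("vibrio", "ecoli"), basal_height_um=2.0,
        )
        sc = generate_scene((16, 16, 8), [dense], rng_seed=2)
        # peripheral focal cells far from the partner cluster
        sc.cells.append(CellGeom("ecoli", (13, 4, 2), (14.5, 4, 2), 0.4))
        sc.cells.append(CellGeom("ecoli", (13, 12, 4), (14.5, 12, 4), 0.4))
        voxel = VoxelSpec.for_domain(sc.domain_size)
        stack = rasterize_scene(sc, voxel, OpticsParams(noise=False), rng_seed=0)
        masks, _, _ = segment_stack(stack, ["vibrio", "ecoli"])
        xs = voxel.centers("x")
        embedded = masks["ecoli"].voxels & (xs[None, None, :] < 8.0)
        peripheral = masks["ecoli"].voxels & (xs[None, None, :] >= 8.0)
        assert embedded.any() and peripheral.any()
        vib = stack.channel("vibrio")
        s_emb = shell_mean_intensity(SpeciesMask("e", embedded, voxel), vib, 2.0)
        s_per = shell_mean_intensity(SpeciesMask("p", peripheral, voxel), vib, 2.0)
        assert s_emb > s_per


class TestDistances:
    def test_pythagorean_offset(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[1, 1, 1] = True
        b[1, 5, 4] = True  # offset (0, 4, 3) voxels at 1 um
        d = min_distance_to_mask(make_mask(a), make_mask(b))
        assert d == pytest.approx([5.0], abs=1e-12)

    def test_overlap_gives_zero(self):
        a = np.zeros((6, 6, 6), bool)
        a[2:4, 2:4, 2:4] = True
        assert min_distance_to_mask(make_mask(a), make_mask(a)).max() == 0.0

    def test_empty_other_mask_gives_inf(self):
        a = np.zeros((6, 6, 6), bool)
        a[2, 2, 2] = True
        d = min_distance_to_mask(make_mask(a), make_mask(np.zeros((6, 6, 6), bool)))
        assert np.isinf(d).all()

    @pytest.mark.parametrize("spacing", [(1.0, 1.0, 1.0), (0.5, 0.5, 1.2)])
    def test_matches_bruteforce_all_pairs(self, rng, spacing):
        dx, dy, dz = spacing
        for _ in range(10):
            a = rng.random((10, 10, 10)) < 0.05
            b = rng.random((10, 10, 10)) < 0.05
            if not (a.any() and b.any()):
                continue
            src = make_mask(a, dx=dx, dy=dy, dz=dz)
            other = make_mask(b, dx=dx, dy=dy, dz=dz)
            cubes = dissect_grid(src, cube_edge_um=2.0)
            d = min_distance_to_mask(cubes, other)
            b_vox = np.stack(np.nonzero(b), axis=1)
            lists = cubes.member_lists()
            for i in range(cubes.n_cubes):
                ref = brute_min_distance(lists[i], b_vox, (dz, dy, dx))
                assert d[i] == pytest.approx(ref, abs=1e-9)

    def test_killing_unsheltered_shifts_summaries_directionally(self, rng):
        # distances to the sheltering mask drop, to the loose mask rise, once
        # unsheltered focal objects are removed
        focal = np.zeros((10, 20, 20), bool)
        focal[2, 3, 3] = True   # near dense block
        focal[2, 16, 16] = True  # near loose block
        dense = np.zeros_like(focal)
        dense[0:6, 0:6, 0:6] = True
        loose = np.zeros_like(focal)
        loose[0:4, 14:20, 14:20] = True
        f, dn, ls = make_mask(focal), make_mask(dense), make_mask(loose)
        pre_dense = summarize_distances(min_distance_to_mask(f, dn), "median").value
        pre_loose = summarize_distances(min_distance_to_mask(f, ls), "median").value
        survivors = focal.copy()
        survivors[2, 16, 16] = False  # the unsheltered object dies
        f2 = make_mask(survivors)
        post_dense = summarize_distances(min_distance_to_mask(f2, dn), "median").value
        post_loose = summarize_distances(min_distance_to_mask(f2, ls), "median").value
        assert post_dense < pre_dense
        assert post_loose > pre_loose


class TestSummaries:
    def test_median_odd_even_and_mean(self):
        assert summarize_distances([1, 2, 3], "median").value == 2
        assert summarize_distances([1, 2, 3, 4], "median").value == 2.5
        assert summarize_distances([0, 0, 10], "mean").value == pytest.approx(10 / 3)

    def test_infinite_sentinels_excluded_and_counted(self):
        s = summarize_distances([1.0, np.inf, 3.0], "mean")
        assert s.value == 2.0 and s.n_infinite == 1 and s.n_used == 2

    def test_all_infinite_gives_nan(self):
        s = summarize_distances([np.inf, np.inf], "median")
        assert np.isnan(s.value)


class TestManders:
    def test_identical_channels_give_unity(self, rng):
        a = np.where(rng.random((8, 8, 8)) < 0.3, 200.0, 0.0)
        for variant in ("M1", "M2", "R"):
            assert manders_overlap(a, a, variant) == pytest.approx(1.0)

    def test_disjoint_supports_give_zero(self):
        a = np.zeros((6, 6, 6))
        b = np.zeros((6, 6, 6))
        a[:3] = 5.0
        b[4:] = 7.0
        for variant in ("M1", "M2", "R"):
            assert manders_overlap(a, b, variant) == 0.0

    def test_half_overlap_m1(self):
        # B covers exactly half of A's total intensity
        a = np.zeros((4, 4, 4))
        a[0] = 10.0
        a[1] = 10.0
        b = np.zeros((4, 4, 4))
        b[0] = 100.0
        assert manders_overlap(a, b, "M1") == pytest.approx(0.5)

    def test_r_symmetric(self, rng):
        a = rng.random((6, 6, 6))
        b = rng.random((6, 6, 6))
        assert manders_overlap(a, b, "R") == pytest.approx(manders_overlap(b, a, "R"))

    def test_m1_unity_when_b_covers_support(self, rng):
        a = np.where(rng.random((6, 6, 6)) < 0.4, 3.0, 0.0)
        b = np.where(a > 0, 9.0, 0.0)
        b[0, 0, 0] = 9.0  # superset is fine
        assert manders_overlap(a, b, "M1") == pytest.approx(1.0)

    def test_zero_channel_gives_nan(self):
        z = np.zeros((4, 4, 4))
        assert np.isnan(manders_overlap(z, z, "M1"))
        assert np.isnan(manders_overlap(z, z, "R"))


class TestBiovolume:
    def test_empty_and_counted(self):
        assert biovolume(make_mask(np.zeros((4, 4, 4), bool))) == 0.0
        arr = np.zeros((10, 10, 10), bool)
        arr.flat[:1000] = True
        m = make_mask(arr, dx=0.2, dy=0.2, dz=0.5)
        assert biovolume(m) == pytest.approx(20.0)

    def test_rasterized_sphere_volume(self):
        from packfrac.geometry import CellGeom, SceneGroundTruth
        from packfrac.scene import scene_occupancy

        sc = SceneGroundTruth(
            cells=[CellGeom("a", (4, 4, 4), (4, 4, 4), 2.0)], domain_size=(8, 8, 8)
        )
        voxel = VoxelSpec(dx=0.2, dy=0.2, dz=0.2, shape=(40, 40, 40))
        occ = scene_occupancy(sc, voxel)["a"]
        m = make_mask(occ, dx=0.2, dy=0.2, dz=0.2)
        assert biovolume(m) == pytest.approx(4 / 3 * np.pi * 8, rel=0.05)
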