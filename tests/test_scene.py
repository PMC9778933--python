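import numpy as np
import pytest

from packfrac.geometry import CellGeom, Region, SceneGroundTruth, VoxelSpec
from packfrac.scene import (
    OpticsParams,
    add_phage_channel,
    generate_scene,
    local_packing_field,
    rasterize_scene,
    remove_unprotected,
    scene_occupancy,
    true_local_fraction,
)


def grid_average_fraction(scene, lo, hi, pitch=0.1):
    """Region-average occupancy by independent supersampling (placement oracle)."""
    from packfrac.geometry import point_segment_distance

    axes = [np.arange(lo[i] + pitch / 2, hi[i], pitch) for i in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    occ = np.zeros(len(pts), dtype=bool)
    for c in scene.cells:
        todo = ~occ
        d = point_segment_distance(pts[todo], np.asarray(c.p0), np.asarray(c.p1))
        occ[np.flatnonzero(todo)[d <= c.radius]] = True
    return occ.mean()


class TestGenerateScene:
    def test_loose_target_recovered_by_oracle(self, loose_scene):
        frac = grid_average_fraction(loose_scene, (0, 0, 0), (12, 12, 6), pitch=0.15)
        assert frac == pytest.approx(0.45, abs=0.05)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_rsa_targets_across_band_and_seeds(self, seed):
        # spot-check the RSA band at a low and a mid target
        for target in (0.10, 0.40):
            r = Region("r", (0, 0, 0), (8, 8, 5), target, "loose_cluster")
            sc = generate_scene((8, 8, 5), [r], rng_seed=seed)
            frac = grid_average_fraction(sc, (0, 0, 0), (8, 8, 5), pitch=0.15)
            assert frac == pytest.approx(target, abs=0.05)

    def test_zero_target_places_no_cells(self):
        r = Region("r", (0, 0, 0), (5, 5, 5), 0.0, "loose_cluster")
        sc = generate_scene((5, 5, 5), [r], rng_seed=1)
        assert sc.cells == []

    def test_determinism_identical_cell_lists(self):
        r = Region("r", (0, 0, 0), (6, 6, 4), 0.3, "loose_cluster")
        a = generate_scene((6, 6, 4), [r], rng_seed=5)
        b = generate_scene((6, 6, 4), [r], rng_seed=5)
        assert a.cells == b.cells
        c = generate_scene((6, 6, 4), [r], rng_seed=6)
        assert a.cells != c.cells

    def test_all_cells_inside_domain(self, loose_scene):
        dom = np.asarray(loose_scene.domain_size)
        for c in loose_scene.cells:
            for p in (c.p0, c.p1):
                assert np.all(np.asarray(p) >= c.radius - 1e-9)
                assert np.all(np.asarray(p) <= dom - c.radius + 1e-9)

    def test_rsa_placement_rejects_above_bound(self):
        r = Region("r", (0, 0, 0), (8, 8, 5), 0.8, "dense_cluster", placement="rsa")
        with pytest.raises(ValueError, match="lattice"):
            generate_scene((8, 8, 5), [r], rng_seed=1)

    def test_overlapping_regions_rejected(self):
        a = Region("a", (0, 0, 0), (4, 4, 4), 0.3, "loose_cluster")
        b = Region("b", (2, 0, 0), (6, 4, 4), 0.3, "loose_cluster")
        with pytest.raises(ValueError, match="overlap"):
            generate_scene((8, 8, 8), [a, b], rng_seed=1)

    def test_embedded_layer_species_placement(self, embedded_scene):
        basal = embedded_scene.cells_of("ecoli")
        overlay = embedded_scene.cells_of("vibrio")
        assert basal and overlay
        assert max(max(c.p0[2], c.p1[2]) for c in basal) <= 2.0 + 1e-9
        assert min(min(c.p0[2], c.p1[2]) for c in overlay) >= 2.0 - 0.5  # caps near interface

    def test_embedded_centroids_densely_packed(self, embedded_scene):
        # the architectural core: basal cells sit in >=0.85 local packing
        fracs = [
            true_local_fraction(embedded_scene, c.centroid, 6.0)
            for c in embedded_scene.cells_of("ecoli")[::80]
        ]
        assert np.median(fracs) >= 0.85


class TestTrueLocalFraction:
    def test_full_slab_gives_unity(self):
        cells = [
            CellGeom("a", (x, y, 2.5), (x, y, 2.5), 3.0)
            for x in np.arange(0, 21, 2.0)
            for y in np.arange(0, 21, 2.0)
        ]
        sc = SceneGroundTruth(cells=cells, domain_size=(20, 20, 5))
        assert true_local_fraction(sc, (10, 10, 2.5), 2.0) == pytest.approx(1.0, abs=0.01)

    def test_empty_space_gives_zero(self, loose_scene):
        sc = SceneGroundTruth(cells=[], domain_size=(20, 20, 10))
        assert true_local_fraction(sc, (10, 10, 5), 6.0) == 0.0

    def test_single_sphere_analytic_ratio(self):
        # sphere r=1 centered at the query: fraction = (1/6)^3 of the 6-ball
        sc = SceneGroundTruth(
            cells=[CellGeom("a", (10, 10, 10), (10, 10, 10), 1.0)],
            domain_size=(20, 20, 20),
        )
        frac = true_local_fraction(sc, (10, 10, 10), 6.0)
        assert frac == pytest.approx((1 / 6) ** 3, abs=1e-3)

    def test_point_outside_domain_rejected(self, loose_scene):
        with pytest.raises(ValueError, match="outside"):
            true_local_fraction(loose_scene, (50, 0, 0), 6.0)

    def test_packing_field_agrees_with_pointwise_oracle(self, loose_scene):
        field, pitch, origin = local_packing_field(loose_scene, radius=3.0)
        rng = np.random.default_rng(0)
        for _ in range(5):
            p = rng.uniform([2, 2, 1], [10, 10, 5])
            idx = tuple(((p - origin) / pitch).astype(int))
            assert field[idx] == pytest.approx(true_local_fraction(loose_scene, p, 3.0), abs=0.05)


class TestRasterize:
    def test_sphere_voxel_volume_matches_analytic(self):
        # sphere centered on a voxel center (half-voxel offset lattice)
        sc = SceneGroundTruth(
            cells=[CellGeom("a", (3.1, 3.1, 3.1), (3.1, 3.1, 3.1), 1.0)],
            domain_size=(6, 6, 6),
        )
        voxel = VoxelSpec(dx=0.2, dy=0.2, dz=0.2, shape=(30, 30, 30))
        stack = rasterize_scene(sc, voxel, OpticsParams.ideal(), rng_seed=0)
        vol = (stack.channel("a") > 0).sum() * voxel.voxel_volume
        assert vol == pytest.approx(4 / 3 * np.pi, rel=0.05)

    def test_ideal_optics_is_scaled_occupancy(self, loose_scene):
        voxel = VoxelSpec.for_domain(loose_scene.domain_size)
        optics = OpticsParams.ideal()
        stack = rasterize_scene(loose_scene, voxel, optics, rng_seed=0)
        occ = scene_occupancy(loose_scene, voxel)
        for name in occ:
            np.testing.assert_array_equal(
                stack.channel(name), occ[name] * optics.photon_scale
            )

    def test_empty_scene_is_background_only(self):
        sc = SceneGroundTruth(cells=[], domain_size=(4, 4, 4))
        voxel = VoxelSpec.for_domain((4, 4, 4))
        stack = rasterize_scene(sc, voxel, OpticsParams(noise=False), rng_seed=0)
        for arr in stack.channels.values():
            assert np.all(arr == 5.0)

    def test_noise_determinism_bit_identical(self, loose_scene):
        voxel = VoxelSpec.for_domain(loose_scene.domain_size)
        a = rasterize_scene(loose_scene, voxel, OpticsParams(), rng_seed=9)
        b = rasterize_scene(loose_scene, voxel, OpticsParams(), rng_seed=9)
        for name in a.channels:
            np.testing.assert_array_equal(a.channel(name), b.channel(name))

    def test_undersampled_voxels_warn_not_fail(self, loose_scene):
        voxel = VoxelSpec.for_domain(loose_scene.domain_size, dx=0.5, dy=0.5, dz=1.0)
        with pytest.warns(UserWarning, match="undersampled"):
            rasterize_scene(loose_scene, voxel, OpticsParams.ideal(), rng_seed=0)

    def test_volume_conservation_under_voxelization(self, loose_scene):
        # voxelized volume cannot exceed analytic volume by >10% at fine voxels
        voxel = VoxelSpec.for_domain(loose_scene.domain_size, dx=0.1, dy=0.1, dz=0.1)
        occ = scene_occupancy(loose_scene, voxel)
        vox_vol = sum(o.sum() for o in occ.values()) * voxel.voxel_volume
        analytic = sum(c.volume for c in loose_scene.cells)
        assert vox_vol <= analytic * 1.1


class TestPhageChannel:
    def test_on_species_mask_centers_inside_cells(self, loose_scene, loose_stack):
        from packfrac.geometry import point_segment_distance

        _, centers = add_phage_channel(
            loose_stack, loose_scene, "on_species_mask", density=0.05,
            rng_seed=1, species="ecoli",
        )
        assert len(centers)
        cells = loose_scene.cells_of("ecoli")
        for p in centers:
            dmin = min(
                point_segment_distance(p[None], np.asarray(c.p0), np.asarray(c.p1))[0] - c.radius
                for c in cells
            )
            assert dmin <= 1e-9

    def test_basal_layer_centers_below_2um(self, loose_scene, loose_stack):
        _, centers = add_phage_channel(
            loose_stack, loose_scene, "basal_glass_layer", density=0.05, rng_seed=1
        )
        assert len(centers)
        assert np.all(centers[:, 2] <= 2.0)

    def test_excluded_from_dense_avoids_packed_neighborhoods(self, embedded_scene):
        voxel = VoxelSpec.for_domain(embedded_scene.domain_size)
        stack = rasterize_scene(embedded_scene, voxel, OpticsParams(noise=False), rng_seed=0)
        _, centers = add_phage_channel(
            stack, embedded_scene, "excluded_from_dense", density=0.02, rng_seed=1
        )
        field, pitch, origin = local_packing_field(embedded_scene, radius=6.0)
        for p in centers:
            idx = tuple(np.minimum(((p - origin) / pitch).astype(int), np.array(field.shape) - 1))
            assert field[idx] <= 0.7

    def test_unknown_mode_rejected(self, loose_scene, loose_stack):
        with pytest.raises(ValueError, match="unknown phage mode"):
            add_phage_channel(loose_stack, loose_scene, "everywhere", density=0.1)


def test_remove_unprotected_spares_embedded_cells(embedded_scene):
    survivors = remove_unprotected(embedded_scene, "ecoli", packing_threshold=0.7)
    # embedded basal cells live in ~0.9 packing: most survive
    assert len(survivors.cells_of("ecoli")) >= 0.8 * len(embedded_scene.cells_of("ecoli"))
    assert len(survivors.cells_of("vibrio")) == len(embedded_scene.cells_of("vibrio"))


def test_remove_unprotected_kills_loose_cells(loose_scene):
    survivors = remove_unprotected(loose_scene, "ecoli", packing_threshold=0.7)
    assert len(survivors.cells_of("ecoli")) <= 0.2 * len(loose_scene.cells_of("ecoli"))
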