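"""Region growing against an exhaustive BFS oracle, plus organ/airway masks."""

import warnings

import numpy as np
import pytest
from scipy import ndimage

from lungburden.phantom import PhantomSpec, TumorSpec, generate_phantom
from lungburden.pipeline import default_trachea_seed
from lungburden.segmentation import (
    RegionGrowParams,
    Seed,
    compute_lung_mask,
    region_grow,
    segment_airways,
    segment_tumors,
)
from lungburden.volio import LABEL_AIRWAY, LABEL_HALO, LABEL_TUMOR, VoxelVolume

from conftest import bfs_region_grow


def _random_volume(rng, shape=(5, 5, 5), lo=0, hi=100):
    return VoxelVolume(rng.integers(lo, hi, size=shape).astype(np.uint16), 1.0)


class TestRegionGrow:
    def test_uniform_volume_floods_entire_grid(self):
        vol = VoxelVolume(np.full((5, 6, 7), 1000, dtype=np.uint16), 13.0)
        res = region_grow(vol, Seed(2, 3, 3), RegionGrowParams(tolerance=10))
        assert res.mask.all()

    def test_isolated_seed_stays_alone(self):
        data = np.zeros((5, 5, 5), dtype=np.uint16)
        data[2, 2, 2] = 5000  # neighbors differ by 5000 > tolerance/2
        vol = VoxelVolume(data, 13.0)
        res = region_grow(vol, Seed(2, 2, 2), RegionGrowParams(tolerance=100))
        assert res.voxel_count == 1 and res.mask[2, 2, 2]

    def test_matches_bfs_oracle_on_random_volumes(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            vol = _random_volume(rng)
            res = region_grow(vol, Seed(2, 2, 2), RegionGrowParams(tolerance=40, connectivity=26))
            oracle = bfs_region_grow(vol.data, (2, 2, 2), 40, connectivity=26)
            assert np.array_equal(res.mask, oracle)

    def test_radius_one_voxel_confines_to_face_neighbors(self):
        rng = np.random.default_rng(3)
        vol = _random_volume(rng, lo=0, hi=30)  # wide acceptance
        res = region_grow(
            vol, Seed(2, 2, 2), RegionGrowParams(tolerance=1000, radius_um=1.0, connectivity=6)
        )
        allowed = np.zeros((5, 5, 5), dtype=bool)
        for off in [(0, 0, 0), (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
            allowed[2 + off[0], 2 + off[1], 2 + off[2]] = True
        assert (res.mask <= allowed).all()

    def test_union_is_seed_order_independent(self):
        rng = np.random.default_rng(5)
        vol = _random_volume(rng)
        p = RegionGrowParams(tolerance=60)
        seeds = [Seed(0, 0, 0), Seed(4, 4, 4), Seed(2, 2, 2)]
        a = region_grow(vol, seeds, p).mask
        b = region_grow(vol, seeds[::-1], p).mask
        assert np.array_equal(a, b)

    def test_seed_outside_grid_errors(self):
        vol = _random_volume(np.random.default_rng(0))
        with pytest.raises(ValueError, match="outside the grid"):
            region_grow(vol, Seed(9, 0, 0), RegionGrowParams(tolerance=10))

    def test_seed_outside_domain_errors(self):
        vol = _random_volume(np.random.default_rng(0))
        domain = np.zeros(vol.shape, dtype=bool)
        with pytest.raises(ValueError, match="outside the segmentation domain"):
            region_grow(vol, Seed(2, 2, 2), RegionGrowParams(tolerance=10), domain=domain)

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError, match="tolerance"):
            RegionGrowParams(tolerance=-1)

    def test_connectivity_values_validated(self):
        with pytest.raises(ValueError, match="connectivity"):
            RegionGrowParams(tolerance=1, connectivity=4)


class TestProperties:
    """Invariants of the flooding rule on random instances."""

    def test_tolerance_monotonicity(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            vol = _random_volume(rng)
            t1, t2 = sorted(rng.integers(0, 80, size=2).tolist())
            m1 = region_grow(vol, Seed(2, 2, 2), RegionGrowParams(tolerance=t1)).mask
            m2 = region_grow(vol, Seed(2, 2, 2), RegionGrowParams(tolerance=t2)).mask
            assert (m1 <= m2).all()

    def test_radius_containment_and_monotonicity(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            vol = _random_volume(rng)
            r1, r2 = sorted(rng.uniform(0.5, 5.0, size=2).tolist())
            m1 = region_grow(vol, Seed(2, 2, 2), RegionGrowParams(tolerance=60, radius_um=r1)).mask
            m2 = region_grow(vol, Seed(2, 2, 2), RegionGrowParams(tolerance=60, radius_um=r2)).mask
            assert (m1 <= m2).all()
            zz, yy, xx = np.nonzero(m1)
            d = np.sqrt((zz - 2.0) ** 2 + (yy - 2.0) ** 2 + (xx - 2.0) ** 2)
            assert (d <= r1 + 1e-12).all()

    def test_connectivity_nesting(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            vol = _random_volume(rng)
            masks = {
                c: region_grow(vol, Seed(2, 2, 2), RegionGrowParams(tolerance=50, connectivity=c)).mask
                for c in (6, 18, 26)
            }
            assert (masks[6] <= masks[18]).all() and (masks[18] <= masks[26]).all()


class TestAgainstSimpleITK:
    """Cross-check against an independent library implementation."""

    def test_face_connected_growth_matches_connected_threshold(self):
        sitk = pytest.importorskip("SimpleITK")
        rng = np.random.default_rng(21)
        for _ in range(10):
            vol = _random_volume(rng, shape=(7, 7, 7))
            tol = 44
            ref = float(vol.data[3, 3, 3])
            res = region_grow(vol, Seed(3, 3, 3), RegionGrowParams(tolerance=tol, connectivity=6))
            img = sitk.GetImageFromArray(vol.data)
            seg = sitk.ConnectedThreshold(
                img,
                seedList=[(3, 3, 3)],  # sitk uses (x, y, z)
                lower=int(np.ceil(ref - tol / 2)),
                upper=int(np.floor(ref + tol / 2)),
            )
            assert np.array_equal(res.mask, sitk.GetArrayFromImage(seg).astype(bool))


class TestLungMask:
    def test_noise_free_mask_equals_ground_truth(self, sharp_phantom):
        _, vol, labels = sharp_phantom
        mask = compute_lung_mask(vol, background_threshold=15000, closing_radius=3)
        assert np.array_equal(mask, labels.data != 0)

    def test_all_background_raises_no_specimen(self):
        vol = VoxelVolume(np.zeros((32, 32, 32), dtype=np.uint16), 13.0)
        with pytest.raises(ValueError, match="no specimen found"):
            compute_lung_mask(vol, background_threshold=500)

    def test_noisy_mask_dice_above_099(self):
        spec = PhantomSpec(
            grid_shape=(64, 64, 64),
            tumors=[TumorSpec(center=(32, 30, 30), radius=8.0)],
            noise_sigma=50.0,
            rng_seed=4,
        )
        vol, labels = generate_phantom(spec)
        mask = compute_lung_mask(vol, background_threshold=15000, closing_radius=3)
        truth = labels.data != 0
        dice = 2 * (mask & truth).sum() / (mask.sum() + truth.sum())
        assert dice >= 0.99


class TestAirways:
    def test_noise_free_airways_match_connected_lumen(self, sharp_phantom):
        spec, vol, labels = sharp_phantom
        lung = compute_lung_mask(vol, 15000, 3)
        seed = Seed(*default_trachea_seed(spec))
        res = segment_airways(vol, seed, RegionGrowParams(tolerance=16000), lung)
        lumen = labels.data == LABEL_AIRWAY
        lab, _ = ndimage.label(lumen, structure=ndimage.generate_binary_structure(3, 3))
        connected = lab == lab[seed.zyx]
        assert np.array_equal(res.mask, connected)

    def test_parenchyma_seed_warns_and_stays_small(self, sharp_phantom):
        spec, vol, labels = sharp_phantom
        lung = compute_lung_mask(vol, 15000, 3)
        seed = Seed(32, 18, 18)  # parenchyma, far from tumor and airways
        assert labels.data[seed.zyx] == 1
        with pytest.warns(UserWarning, match="air range"):
            res = segment_airways(vol, seed, RegionGrowParams(tolerance=100), lung)
        # tight tolerance from a wrong seed grabs only same-valued parenchyma,
        # never the air lumen
        assert not (res.mask & (labels.data == LABEL_AIRWAY)).any()

    def test_radius_restriction_is_strictly_contained(self, sharp_phantom):
        spec, vol, _ = sharp_phantom
        lung = compute_lung_mask(vol, 15000, 3)
        seed = Seed(*default_trachea_seed(spec))
        full = segment_airways(vol, seed, RegionGrowParams(tolerance=16000), lung).mask
        small = segment_airways(
            vol, seed, RegionGrowParams(tolerance=16000, radius_um=5 * 13.0), lung
        ).mask
        assert (small <= full).all() and small.sum() < full.sum()


class TestTumors:
    def test_noise_free_sharp_phantom_segments_exactly(self, sharp_phantom):
        spec, vol, labels = sharp_phantom
        lung = compute_lung_mask(vol, 15000, 3)
        res = segment_tumors(
            vol, [Seed(*spec.tumors[0].center)], RegionGrowParams(tolerance=16000), lung
        )
        assert np.array_equal(res.mask, labels.data == LABEL_TUMOR)

    def test_halo_with_tumor_gray_is_swallowed(self, halo_phantom):
        """Identical gray values are indistinguishable: the halo shell is
        included, which is the overestimation mechanism under study."""
        spec, vol, labels = halo_phantom
        lung = compute_lung_mask(vol, 15000, 3)
        res = segment_tumors(
            vol, [Seed(*spec.tumors[0].center)], RegionGrowParams(tolerance=16000), lung
        )
        tumor = labels.data == LABEL_TUMOR
        halo = labels.data == LABEL_HALO
        assert (tumor <= res.mask).all()
        assert (res.mask & halo).any()

    def test_zero_seeds_empty_mask(self, sharp_phantom):
        _, vol, _ = sharp_phantom
        lung = compute_lung_mask(vol, 15000, 3)
        res = segment_tumors(vol, [], RegionGrowParams(tolerance=16000), lung)
        assert res.voxel_count == 0 and res.seeds == []

    def test_exclusion_restricts_domain_before_growth(self):
        # two touching same-gray blobs; excluding the bridge must keep
        # the flood from tunneling through it
        data = np.full((33, 33, 33), 100, dtype=np.uint16)
        data[16, 10:23, 16] = 40000  # a bright rod
        vol = VoxelVolume(data, 13.0)
        lung = np.ones(vol.shape, dtype=bool)
        bridge = np.zeros(vol.shape, dtype=bool)
        bridge[16, 15:18, 16] = True
        res = segment_tumors(
            vol, [Seed(16, 11, 16)], RegionGrowParams(tolerance=10), lung, exclude=bridge
        )
        assert res.mask[16, 11, 16] and not res.mask[16, 20, 16]

    def test_per_seed_parameter_overrides_recorded(self, sharp_phantom):
        spec, vol, _ = sharp_phantom
        lung = compute_lung_mask(vol, 15000, 3)
        override = RegionGrowParams(tolerance=16000, radius_um=10 * 13.0)
        res = segment_tumors(
            vol,
            [Seed(*spec.tumors[0].center)],
            RegionGrowParams(tolerance=16000),
            lung,
            per_seed_params=[override],
        )
        assert res.params == [override]
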