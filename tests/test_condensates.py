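import numpy as np
import pytest
from scipy import ndimage, stats

from nucmech import condensates as cond
from nucmech import morpho, synthgen
from nucmech.imgio import VoxelImage


def _ball_mask(radius, n):
    g = np.mgrid[:n, :n, :n] - (n - 1) / 2.0
    return ((g**2).sum(axis=0) <= radius**2).astype(np.int32)


class TestDetection:
    def test_eight_spots_detected(self, spotted_phantom):
        spec, img, truth, nucleus, metrics = spotted_phantom
        labels, records = cond.detect_condensates(img, nucleus)
        assert len(records) == 8

    def test_centers_match_ground_truth(self, spotted_phantom):
        spec, img, truth, nucleus, metrics = spotted_phantom
        _, records = cond.detect_condensates(img, nucleus)
        found = np.array([r.center for r in records])
        true = np.array(truth.true_spot_centers)
        for t in true:
            assert np.min(np.linalg.norm(found - t, axis=1)) < 0.2

    def test_zero_spots(self, flat_ellipsoid):
        spec, img, truth, nucleus, metrics = flat_ellipsoid
        labels, records = cond.detect_condensates(img, nucleus)
        assert records == []

    def test_count_stable_across_noise_seeds(self):
        for seed in (21, 22, 23):
            spec = synthgen.NucleusPhantomSpec(
                semi_axes=(1.4112, 8.0, 8.0), n_spots=5, spot_diameter=0.6,
                min_spot_separation=2.5, snr=10.0, seed=seed,
            )
            img, _ = synthgen.gen_nucleus_stack(spec)
            nucleus = morpho.segment_nucleus(img, 0.1)
            _, records = cond.detect_condensates(img, nucleus)
            assert len(records) == 5

    def test_touching_spots_split_by_erosion(self):
        # hand-constructed oracle: two 4-voxel-radius bright balls joined by
        # a 1-voxel-wide neck; two erosions disconnect the neck
        data = np.full((24, 40, 24), 50.0)
        nucleus = np.ones_like(data, dtype=np.int32)
        g = np.mgrid[:24, :40, :24].astype(float)
        for cy in (14, 26):
            d2 = (g[0] - 12) ** 2 + (g[1] - cy) ** 2 + (g[2] - 12) ** 2
            data[d2 <= 16] = 200.0
        data[12, 18:22, 12] = 200.0  # neck
        img = VoxelImage(data, (0.1, 0.1, 0.1))
        binary = data > 100
        assert ndimage.label(binary)[1] == 1  # touching before erosion
        _, records = cond.detect_condensates(
            img, nucleus, blur_sigma_um=0.0, n_erosions=2, rim_erosions=0
        )
        assert len(records) == 2

    def test_requires_nucleus(self, spotted_phantom):
        spec, img, *_ = spotted_phantom
        with pytest.raises(ValueError):
            cond.detect_condensates(img, np.zeros_like(img.data, dtype=np.int32))

    def test_equivalent_diameter_near_truth(self, spotted_phantom):
        spec, img, truth, nucleus, metrics = spotted_phantom
        _, records = cond.detect_condensates(img, nucleus)
        med = np.median([r.equivalent_diameter for r in records])
        assert med == pytest.approx(0.6, rel=0.2)


class TestPeripheryShell:
    def test_shell_thickness(self):
        mask = _ball_mask(20, 45)
        shell = cond.periphery_shell(mask, (1.0, 1.0, 1.0), 0.05)
        edt = ndimage.distance_transform_edt(mask)
        assert shell.sum() > 0
        assert edt[shell].max() <= 0.05 * edt.max() + 1e-9
        # all deeper voxels excluded
        assert edt[(mask > 0) & ~shell].min() > 0.05 * edt.max()

    def test_fraction_one_is_whole_object(self):
        mask = _ball_mask(8, 20)
        shell = cond.periphery_shell(mask, (1.0, 1.0, 1.0), 1.0)
        np.testing.assert_array_equal(shell, mask > 0)

    def test_fraction_zero_is_surface(self):
        mask = _ball_mask(8, 20)
        shell = cond.periphery_shell(mask, (1.0, 1.0, 1.0), 0.0)
        surface = (mask > 0) & ~ndimage.binary_erosion(mask > 0)
        assert shell[surface].all()
        interior = ndimage.binary_erosion(mask > 0, iterations=2)
        assert not shell[interior].any()

    def test_empty_mask(self):
        with pytest.raises(ValueError):
            cond.periphery_shell(np.zeros((5, 5, 5)), (1, 1, 1))


@pytest.fixture(scope="module")
def sphere_setup():
    mask = _ball_mask(20, 45)
    img = VoxelImage(mask.astype(float) * 100, (1.0, 1.0, 1.0))
    metrics = morpho.measure_nucleus(img, mask)
    center = np.argwhere(mask).mean(axis=0)
    return mask, metrics, center


class TestDistances:
    def _rec(self, center, rid=1, diam=0.0):
        return cond.CondensateRecord(
            id=rid, nucleus_id=1, center=tuple(center), volume=np.pi / 6 * diam**3,
            equivalent_diameter=diam,
        )

    def test_center_condensate_r_zero(self, sphere_setup):
        mask, metrics, center = sphere_setup
        recs = cond.radial_peripheral_distances(
            [self._rec(center)], mask, metrics, (1.0, 1.0, 1.0)
        )
        assert recs[0].radial_r == pytest.approx(0.0, abs=1e-6)

    def test_half_radius_r(self, sphere_setup):
        # sphere radius 20, offset 10 => r = 10 / (2*20) = 0.25
        mask, metrics, center = sphere_setup
        recs = cond.radial_peripheral_distances(
            [self._rec(center + np.array([0, 10, 0]))], mask, metrics, (1.0, 1.0, 1.0)
        )
        assert recs[0].radial_r == pytest.approx(0.25, abs=0.02)

    def test_touching_shell_p_near_zero(self, sphere_setup):
        mask, metrics, center = sphere_setup
        recs = cond.radial_peripheral_distances(
            [self._rec(center + np.array([0, 19, 0]))], mask, metrics, (1.0, 1.0, 1.0)
        )
        assert recs[0].peripheral_p == pytest.approx(0.0, abs=0.05)

    def test_outside_flagged(self, sphere_setup):
        mask, metrics, center = sphere_setup
        recs = cond.radial_peripheral_distances(
            [self._rec(center + np.array([0, 30, 0]))], mask, metrics, (1.0, 1.0, 1.0)
        )
        assert recs[0].outside_nucleus
        assert recs[0].radial_r is None


class TestControls:
    def test_zero_radius_uniform_ball(self):
        # analytic oracle: radial CDF of uniform ball scaled by diameter,
        # F(x) = (2x)^3 on [0, 1/2]; mean radial_r = 3/8
        mask = _ball_mask(20, 45)
        img = VoxelImage(mask.astype(float) * 100, (1.0, 1.0, 1.0))
        metrics = morpho.measure_nucleus(img, mask)
        recs = [
            cond.CondensateRecord(
                id=i, nucleus_id=1,
                center=tuple(np.argwhere(mask).mean(axis=0)),
                volume=0.0, equivalent_diameter=0.0,
            )
            for i in range(400)
        ]
        controls = cond.sample_control_points(mask, recs, metrics, (1.0, 1.0, 1.0), seed=5)
        rvals = np.array([c.radial_r for c in controls])
        # the voxel sphere's equivalent diameter is slightly under 40; rescale
        scale = metrics.equivalent_diameter / 40.0
        assert np.mean(rvals) * scale == pytest.approx(3.0 / 8.0, abs=0.02)
        ks = stats.kstest(rvals * scale, lambda x: np.clip((2 * x) ** 3, 0, 1))
        assert ks.pvalue > 0.01

    def test_eroded_region_respected(self):
        mask = _ball_mask(20, 45)
        img = VoxelImage(mask.astype(float) * 100, (1.0, 1.0, 1.0))
        metrics = morpho.measure_nucleus(img, mask)
        edt = ndimage.distance_transform_edt(mask)
        recs = [
            cond.CondensateRecord(id=i, nucleus_id=1, center=(22.0, 22.0, 22.0),
                                  volume=1.0, equivalent_diameter=16.0)
            for i in range(50)
        ]
        controls = cond.sample_control_points(mask, recs, metrics, (1.0, 1.0, 1.0), seed=2)
        vs = np.array([c.center for c in controls])
        for v in vs:
            assert edt[tuple(np.round(v).astype(int))] >= 8.0

    def test_oversized_radius_fallback(self):
        mask = _ball_mask(10, 25)
        img = VoxelImage(mask.astype(float) * 100, (1.0, 1.0, 1.0))
        metrics = morpho.measure_nucleus(img, mask)
        edt = ndimage.distance_transform_edt(mask)
        rec = cond.CondensateRecord(id=1, nucleus_id=1, center=(12.0, 12.0, 12.0),
                                    volume=1.0, equivalent_diameter=100.0)
        controls = cond.sample_control_points(mask, [rec], metrics, (1.0, 1.0, 1.0), seed=1)
        picked = np.round(controls[0].center).astype(int)
        assert edt[tuple(picked)] == edt.max()

    def test_deterministic_and_stable_under_extension(self):
        mask = _ball_mask(10, 25)
        img = VoxelImage(mask.astype(float) * 100, (1.0, 1.0, 1.0))
        metrics = morpho.measure_nucleus(img, mask)
        mk = lambda i: cond.CondensateRecord(
            id=i, nucleus_id=1, center=(12.0, 12.0, 12.0), volume=1.0,
            equivalent_diameter=2.0,
        )
        short = cond.sample_control_points(mask, [mk(1), mk(2)], metrics, (1, 1, 1), seed=3)
        longer = cond.sample_control_points(
            mask, [mk(1), mk(2), mk(3)], metrics, (1, 1, 1), seed=3
        )
        assert short[0].center == longer[0].center
        assert short[1].center == longer[1].center


class TestManders:
    def test_identical_masks(self):
        a = _ball_mask(5, 15)
        img = VoxelImage(np.ones((15, 15, 15)), (1, 1, 1))
        assert cond.manders_coefficient(a, img, a).manders_m1 == pytest.approx(1.0)

    def test_disjoint_masks(self):
        a = np.zeros((10, 10, 10), dtype=np.int32)
        b = np.zeros_like(a)
        a[2:4, 2:4, 2:4] = 1
        b[6:8, 6:8, 6:8] = 1
        img = VoxelImage(np.ones((10, 10, 10)), (1, 1, 1))
        assert cond.manders_coefficient(a, img, b).manders_m1 == 0.0

    def test_half_covered(self):
        a = np.zeros((10, 10, 10), dtype=np.int32)
        a[2:6, 2:6, 2:6] = 1  # 64 voxels
        b = np.zeros_like(a)
        b[2:4, 2:6, 2:6] = 1  # covers exactly half of a
        img = VoxelImage(np.full((10, 10, 10), 3.0), (1, 1, 1))
        assert cond.manders_coefficient(a, img, b).manders_m1 == pytest.approx(0.5)

    def test_empty_a_error(self):
        img = VoxelImage(np.ones((5, 5, 5)), (1, 1, 1))
        with pytest.raises(ValueError, match="M1"):
            cond.manders_coefficient(np.zeros((5, 5, 5)), img, np.ones((5, 5, 5)))


def test_scaled_total_volume(spotted_phantom):
    spec, img, truth, nucleus, metrics = spotted_phantom
    _, records = cond.detect_condensates(img, nucleus)
    frac = cond.scaled_total_volume(records, metrics)
    assert 0.0 < frac < 0.2
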