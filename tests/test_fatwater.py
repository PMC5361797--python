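import math
from dataclasses import replace

import numpy as np
import pytest

from fishfat.fatwater import (
    FatFractionMap,
    NoiseEstimate,
    compute_fat_fraction,
    correct_rician_bias,
    estimate_noise_sigma,
    normalize_receiver_gain,
    quantify_fat,
    quantify_pair,
)
from fishfat.io import ChannelStack
from fishfat.phantom import build_truth_volumes, simulate_chess_pair


def make_stack(geometry, value_or_array, channel="fat", gain=1.0):
    data = np.broadcast_to(np.asarray(value_or_array, dtype=float), geometry.shape).copy()
    return ChannelStack(channel, data, gain, geometry)


def brute_force_quantify(fraction_map, density):
    """Naive per-voxel accumulation oracle for quantify_fat."""
    vox = fraction_map.geometry.voxel_volume_mm3()
    volume = 0.0
    for frac, fg in zip(fraction_map.values.ravel(), fraction_map.foreground.ravel()):
        if fg:
            volume += frac * vox
    return volume, volume * density


class TestNoiseEstimation:
    def test_zero_background_gives_zero_sigma(self, small_geometry):
        stack = make_stack(small_geometry, 0.0)
        est = estimate_noise_sigma(stack, "auto")
        assert est.sigma == 0.0
        assert est.n_voxels >= 100

    def test_constant_background_second_moment(self, small_geometry):
        c = 4.2
        stack = make_stack(small_geometry, c)
        est = estimate_noise_sigma(stack, "auto")
        assert est.sigma == pytest.approx(c / math.sqrt(2), rel=1e-12)

    def test_recovers_sigma_from_rician_samples(self, rng):
        """1e5 zero-signal magnitude voxels: second-moment estimator
        recovers sigma within 2%."""
        from fishfat.io import AcquisitionGeometry

        sigma = 5.0
        geom = AcquisitionGeometry((16.0, 16.0), (100, 100), 10, 0.5)
        n = int(np.prod(geom.shape))
        samples = sigma * np.hypot(rng.standard_normal(n), rng.standard_normal(n))
        stack = ChannelStack("water", samples.reshape(geom.shape), 1.0, geom)
        est = estimate_noise_sigma(stack, np.ones(geom.shape, dtype=bool))
        assert est.sigma == pytest.approx(sigma, rel=0.02)

    def test_small_background_rejected_with_count(self, small_geometry):
        stack = make_stack(small_geometry, 1.0)
        mask = np.zeros(small_geometry.shape, dtype=bool)
        mask[0, 0, :10] = True
        with pytest.raises(ValueError, match="10"):
            estimate_noise_sigma(stack, mask)


class TestBiasCorrection:
    @pytest.mark.parametrize(
        "value, sigma, expected",
        [
            (0.0, 1.0, 0.0),
            (math.sqrt(2), 1.0, 0.0),       # exactly at the subtraction boundary
            (3.0, 1.0, math.sqrt(7.0)),
        ],
    )
    def test_power_subtraction(self, small_geometry, value, sigma, expected):
        stack = make_stack(small_geometry, value)
        noise = NoiseEstimate(sigma=sigma, method="mask", n_voxels=100)
        corrected = correct_rician_bias(stack, noise)
        assert corrected.data.flat[0] == pytest.approx(expected, abs=1e-12)
        assert np.all(corrected.data >= 0)

    def test_zero_sigma_is_identity(self, small_geometry, rng):
        stack = make_stack(small_geometry, rng.random(small_geometry.shape))
        noise = NoiseEstimate(sigma=0.0, method="mask", n_voxels=100)
        np.testing.assert_array_equal(correct_rician_bias(stack, noise).data, stack.data)


class TestGainNormalisation:
    def test_unit_gain_identity(self, small_geometry, rng):
        stack = make_stack(small_geometry, rng.random(small_geometry.shape), gain=1.0)
        out = normalize_receiver_gain(stack)
        np.testing.assert_array_equal(out.data, stack.data)
        assert out.receiver_gain == 1.0

    def test_divides_by_gain(self, small_geometry):
        stack = make_stack(small_geometry, 10.0, gain=2.0)
        out = normalize_receiver_gain(stack)
        assert out.data.flat[0] == 5.0
        assert out.receiver_gain == 1.0

    def test_gain_ratio_preserved(self, small_geometry, rng):
        """Identical raw intensities at gains g and 2g give a 2:1
        normalised intensity ratio everywhere."""
        raw = rng.random(small_geometry.shape) + 0.1
        a = normalize_receiver_gain(make_stack(small_geometry, raw, gain=3.0))
        b = normalize_receiver_gain(
            make_stack(small_geometry, raw, channel="water", gain=6.0)
        )
        np.testing.assert_allclose(a.data / b.data, 2.0)


class TestFatFraction:
    @pytest.mark.parametrize(
        "f, w, expected", [(0.0, 8.0, 0.0), (6.0, 0.0, 1.0), (2.0, 6.0, 0.25)]
    )
    def test_pointwise_fraction(self, small_geometry, f, w, expected):
        fat = make_stack(small_geometry, f, channel="fat")
        water = make_stack(small_geometry, w, channel="water")
        fmap = compute_fat_fraction(fat, water, sigma_fat=0.1, sigma_water=0.1, k=3)
        assert np.all(fmap.foreground)  # totals are far above threshold
        assert fmap.values.flat[0] == pytest.approx(expected)

    def test_subthreshold_voxels_masked_to_zero(self, small_geometry):
        fat = make_stack(small_geometry, 0.01)
        water = make_stack(small_geometry, 0.01, channel="water")
        fmap = compute_fat_fraction(fat, water, sigma_fat=1.0, sigma_water=1.0, k=3)
        assert not fmap.foreground.any()
        assert np.all(fmap.values == 0)

    def test_geometry_mismatch_rejected(self, small_geometry):
        from fishfat.io import AcquisitionGeometry

        other = AcquisitionGeometry((8.0, 8.0), (16, 16), 12, 0.5)
        fat = make_stack(small_geometry, 1.0)
        water = make_stack(other, 1.0, channel="water")
        with pytest.raises(ValueError, match="geometr"):
            compute_fat_fraction(fat, water, sigma_fat=0, sigma_water=0)

    def test_map_invariants_enforced(self, small_geometry):
        values = np.zeros(small_geometry.shape)
        fg = np.zeros(small_geometry.shape, dtype=bool)
        values[0, 0, 0] = 0.5  # non-zero outside the foreground
        with pytest.raises(ValueError, match="fraction 0"):
            FatFractionMap(values=values, foreground=fg, geometry=small_geometry)

    def test_fat_water_ratio_convention(self, small_geometry):
        fat = make_stack(small_geometry, 2.0)
        water = make_stack(small_geometry, 6.0, channel="water")
        fmap = compute_fat_fraction(fat, water, sigma_fat=0.1, sigma_water=0.1)
        ratio = fmap.fat_water_ratio()
        assert ratio.flat[0] == pytest.approx(2.0 / 6.0)


class TestQuantifyFat:
    def test_uniform_map(self, small_geometry):
        fg = np.zeros(small_geometry.shape, dtype=bool)
        fg[2:5, 4:9, 4:9] = True
        values = np.where(fg, 1.0, 0.0)
        fmap = FatFractionMap(values=values, foreground=fg, geometry=small_geometry)
        q = quantify_fat(fmap, density=0.9)
        n = int(fg.sum())
        vox = small_geometry.voxel_volume_mm3()
        assert q.fat_volume_mm3 == pytest.approx(n * vox)
        assert q.fat_mass_mg == pytest.approx(0.9 * n * vox)
        assert q.n_foreground_voxels == n

    def test_all_zero_map(self, small_geometry):
        fmap = FatFractionMap(
            values=np.zeros(small_geometry.shape),
            foreground=np.zeros(small_geometry.shape, dtype=bool),
            geometry=small_geometry,
        )
        q = quantify_fat(fmap)
        assert q.fat_volume_mm3 == 0.0 and q.fat_mass_mg == 0.0

    def test_matches_brute_force_on_random_maps(self, small_geometry, rng):
        for _ in range(3):
            fg = rng.random(small_geometry.shape) < 0.4
            values = np.where(fg, rng.random(small_geometry.shape), 0.0)
            fmap = FatFractionMap(values=values, foreground=fg, geometry=small_geometry)
            q = quantify_fat(fmap, density=0.9)
            volume, mass = brute_force_quantify(fmap, 0.9)
            assert q.fat_volume_mm3 == pytest.approx(volume, rel=1e-9)
            assert q.fat_mass_mg == pytest.approx(mass, rel=1e-9)

    def test_nonpositive_density_rejected(self, small_geometry):
        fmap = FatFractionMap(
            values=np.zeros(small_geometry.shape),
            foreground=np.zeros(small_geometry.shape, dtype=bool),
            geometry=small_geometry,
        )
        with pytest.raises(ValueError, match="density"):
            quantify_fat(fmap, density=0.0)


class TestQuantifyPair:
    def test_noise_free_phantom_recovers_truth(self, small_spec):
        spec = replace(small_spec, sigma=0.0, receiver_gain={"fat": 1.0, "water": 1.0})
        fat, water, truth = build_truth_volumes(spec)
        fs, ws = simulate_chess_pair(fat, water, spec)
        q = quantify_pair(fs, ws, density=spec.fat_density_mg_mm3)
        assert q.fat_volume_mm3 == pytest.approx(truth.fat_volume_mm3, rel=1e-9)
        assert q.fat_mass_mg == pytest.approx(truth.fat_mass_mg, rel=1e-9)
        assert q.noise["fat"].sigma == 0.0

    def test_gain_invariance(self, small_spec):
        """Rescaling a channel's intensities together with its recorded
        receiver gain must not change the quantification."""
        fat, water, _ = build_truth_volumes(small_spec)
        noisy = replace(small_spec, sigma=1.5)
        fs, ws = simulate_chess_pair(fat, water, noisy)
        q1 = quantify_pair(fs, ws)
        fs10 = fs.with_data(10.0 * fs.data, receiver_gain=10.0 * fs.receiver_gain)
        ws3 = ws.with_data(3.0 * ws.data, receiver_gain=3.0 * ws.receiver_gain)
        q2 = quantify_pair(fs10, ws3)
        assert q2.fat_mass_mg == pytest.approx(q1.fat_mass_mg, rel=1e-9)
        assert q2.n_foreground_voxels == q1.n_foreground_voxels

    def test_fraction_bounded_and_mass_capped(self, small_spec):
        noisy = replace(small_spec, sigma=4.0)
        fat, water, _ = build_truth_volumes(noisy)
        fs, ws = simulate_chess_pair(fat, water, noisy)
        q, fmap = quantify_pair(fs, ws, return_map=True)
        assert np.all((fmap.values >= 0) & (fmap.values <= 1))
        vox = small_spec.geometry.voxel_volume_mm3()
        cap = q.fat_density_mg_mm3 * q.n_foreground_voxels * vox
        assert 0 <= q.fat_mass_mg <= cap + 1e-9

    def test_pure_noise_mass_vanishes_as_k_grows(self, small_geometry):
        """On a signal-free acquisition the residual fat mass inside the
        foreground decreases to zero as the threshold multiplier grows."""
        from fishfat.phantom import Ellipsoid, PhantomSpec, simulate_chess_pair

        spec = PhantomSpec(
            geometry=small_geometry,
            body=Ellipsoid((0, 0, 0), (0.6, 0.6, 0.6)),
            tube_radius_mm=0.7,
            depots=(),
            sigma=3.0,
            seed=5,
            receiver_gain={"fat": 1.0, "water": 1.0},
        )
        zeros = np.zeros(small_geometry.shape)
        fs, ws = simulate_chess_pair(zeros, zeros, spec)
        masses = [quantify_pair(fs, ws, k=k).fat_mass_mg for k in (0.5, 3.0, 8.0)]
        assert masses[0] > masses[-1]
        assert masses[-1] == pytest.approx(0.0, abs=1e-6)
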