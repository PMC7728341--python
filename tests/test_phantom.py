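import numpy as np
import pytest

from voldvc import (
    AcquisitionModel,
    AffineDeformation,
    Mask,
    RigidDeformation,
    Volume,
    add_noise,
    generate_speckle,
    make_ellipsoid_mask,
    make_zero_strain_pair,
    measure_snr,
    sample_deformed,
)
from voldvc.phantom import TrigDeformation, erode_mask

VS = 0.5


class TestGenerateSpeckle:
    def test_same_seed_bit_identical(self):
        _, a = generate_speckle((24, 24, 24), VS, seed=3)
        _, b = generate_speckle((24, 24, 24), VS, seed=3)
        assert np.array_equal(a.data, b.data)

    def test_different_seeds_differ_almost_everywhere(self):
        _, a = generate_speckle((24, 24, 24), VS, seed=3)
        _, b = generate_speckle((24, 24, 24), VS, seed=4)
        assert np.mean(a.data != b.data) > 0.5

    def test_zero_density_rejected(self):
        with pytest.raises(ValueError, match="untrackable"):
            generate_speckle((16, 16, 16), VS, blob_density=0.0)

    def test_subvoxel_blobs_rejected(self):
        with pytest.raises(ValueError, match="alias"):
            generate_speckle((16, 16, 16), VS, blob_sigma=0.4)


class TestSampleDeformed:
    def test_identity_deformation_bit_identical(self, small_speckle):
        model, vol = small_speckle
        out = sample_deformed(model, RigidDeformation(), vol.shape, VS)
        assert np.array_equal(out.data, vol.data)

    def test_integer_translation_equals_index_shift(self, small_speckle):
        """Analytic evaluation makes translation equivariance exact."""
        model, vol = small_speckle
        shifted = sample_deformed(
            model, RigidDeformation((3 * VS, 0, 0)), vol.shape, VS
        )
        assert np.max(np.abs(shifted.data[3:, :, :] - vol.data[:-3, :, :])) < 1e-9

    def test_affine_ground_truth_strain(self):
        aff = AffineDeformation(((0.002, 0, 0), (0, 0, 0), (0, 0, 0)))
        np.testing.assert_allclose(
            aff.strain_microstrain(), [2000, 0, 0, 0, 0, 0], atol=1e-9
        )
        shear = AffineDeformation(((0, 0.002, 0), (0.002, 0, 0), (0, 0, 0)))
        np.testing.assert_allclose(
            shear.strain_microstrain(), [0, 0, 0, 2000, 0, 0], atol=1e-9
        )

    def test_singular_affine_rejected(self, small_speckle):
        model, vol = small_speckle
        bad = AffineDeformation(((-1.0, 0, 0), (0, 0, 0), (0, 0, 0)))
        with pytest.raises(ValueError, match="non-invertible"):
            sample_deformed(model, bad, (8, 8, 8), VS)

    def test_trig_strain_matches_numerical_derivative(self):
        trig = TrigDeformation((1.0, 0.5, 0.0), (24.0, 16.0, 20.0), VS)
        pts = np.array([[5.0, 3.0, 7.0], [1.0, 2.0, 3.0]])
        eps = trig.strain_microstrain_at(pts)
        h = 1e-6
        for axis in range(3):
            dp = pts.copy()
            dm = pts.copy()
            dp[:, axis] += h
            dm[:, axis] -= h
            du = (trig.displacement(dp) - trig.displacement(dm))[:, axis] / (2 * h)
            np.testing.assert_allclose(eps[:, axis], du * 1e6, rtol=1e-4, atol=1e-3)


class TestZeroStrainPair:
    def test_no_noise_no_offset_bit_identical(self, small_speckle):
        model, _ = small_speckle
        a, b = make_zero_strain_pair(model, (32, 32, 32), VS)
        assert np.array_equal(a.data, b.data)

    def test_rigid_offset_recoverable_exactly(self, small_speckle):
        """Re-evaluating the model at corrected coordinates must undo the offset."""
        model, _ = small_speckle
        shift_vox = np.array([1.7, -0.3, 0.0])
        rigid = RigidDeformation(tuple(shift_vox * VS))
        a, b = make_zero_strain_pair(
            model, (32, 32, 32), VS, inter_scan_rigid=rigid
        )
        assert not np.array_equal(a.data, b.data)
        corrected = sample_deformed(model, RigidDeformation(), (32, 32, 32), VS)
        assert np.max(np.abs(corrected.data - a.data)) < 1e-6

    def test_noise_sd_scales_inversely_with_snr(self, small_speckle):
        model, _ = small_speckle
        shape = (48, 48, 48)
        mask = Mask(np.ones(shape, dtype=np.uint8))
        sds = {}
        for snr in (9.8, 306.2):
            a, b = make_zero_strain_pair(
                model, shape, VS,
                acquisition=AcquisitionModel(snr, seed=9), mask=mask,
            )
            sds[snr] = np.std(a.data - b.data)
        ratio = sds[9.8] / sds[306.2]
        assert abs(ratio - 306.2 / 9.8) / (306.2 / 9.8) < 0.2

    def test_rejects_non_rigid_interscan_motion(self, small_speckle):
        model, _ = small_speckle
        aff = AffineDeformation(((0.01, 0, 0), (0, 0, 0), (0, 0, 0)))
        with pytest.raises(TypeError, match="[Rr]igid"):
            make_zero_strain_pair(model, (16, 16, 16), VS, inter_scan_rigid=aff)


class TestNoise:
    def test_measured_snr_within_contract(self):
        """Blobs confined to an eroded ellipsoid leave the background clean,
        so the measured SNR must land within 5% of the target."""
        shape = (64, 64, 64)
        mask = make_ellipsoid_mask(shape, radii=(26, 24, 22))
        region = erode_mask(mask, 8)
        for target in (306.2, 102.4):
            _, vol = generate_speckle(shape, VS, seed=21, region=region)
            noisy = add_noise(vol, AcquisitionModel(target, seed=22), mask)
            measured = measure_snr(noisy, mask)
            assert abs(measured - target) / target < 0.05

    def test_independent_seeds_give_uncorrelated_noise(self, small_speckle):
        model, vol = small_speckle
        mask = Mask(np.ones(vol.shape, dtype=np.uint8))
        n1 = add_noise(vol, AcquisitionModel(100.0, seed=1), mask)
        n2 = add_noise(vol, AcquisitionModel(100.0, seed=2), mask)
        f1 = (n1.data - vol.data)[mask.data]
        f2 = (n2.data - vol.data)[mask.data]
        r = np.corrcoef(f1, f2)[0, 1]
        assert abs(r) < 0.05

    def test_empty_or_mismatched_mask_rejected(self, small_speckle):
        _, vol = small_speckle
        with pytest.raises(ValueError):
            add_noise(vol, AcquisitionModel(100.0), Mask(np.ones((8, 8, 8), np.uint8)))

    def test_infinite_snr_not_representable(self):
        with pytest.raises(ValueError, match="target_snr"):
            AcquisitionModel(float("inf"))
        with pytest.raises(ValueError, match="target_snr"):
            AcquisitionModel(0.0)


class TestEllipsoidMask:
    def test_huge_radii_give_full_mask(self):
        mask = make_ellipsoid_mask((16, 16, 16), radii=(100, 100, 100))
        assert mask.data.all()

    def test_tiny_radii_give_single_voxel(self):
        mask = make_ellipsoid_mask((15, 15, 15), center=(7, 7, 7), radii=(0.5, 0.5, 0.5))
        assert mask.n_voxels == 1
        assert mask.data[7, 7, 7]

    def test_voxel_count_matches_analytic_volume(self):
        mask = make_ellipsoid_mask((64, 64, 64), radii=(24, 20, 16))
        expected = 4.0 / 3.0 * np.pi * 24 * 20 * 16
        assert abs(mask.n_voxels - expected) / expected < 0.02


class TestMeasureSnr:
    def test_constant_signal_gaussian_background(self):
        rng = np.random.default_rng(7)
        shape = (32, 32, 32)
        mask = np.zeros(shape, dtype=np.uint8)
        mask[8:24, 8:24, 8:24] = 1
        data = rng.normal(0.0, 1.0, shape)
        data[mask.astype(bool)] = 100.0
        snr = measure_snr(Volume(data, VS), Mask(mask))
        assert 95 < snr < 105

    def test_constant_background_reports_inf(self):
        shape = (32, 32, 32)
        mask = np.zeros(shape, dtype=np.uint8)
        mask[8:24, 8:24, 8:24] = 1
        data = np.zeros(shape)
        data[mask.astype(bool)] = 50.0
        with pytest.warns(UserWarning, match="inf"):
            assert measure_snr(Volume(data, VS), Mask(mask)) == np.inf

    def test_requires_enough_voxels_on_both_sides(self):
        mask = np.ones((32, 32, 32), dtype=np.uint8)
        mask[0, 0, 0] = 0
        with pytest.raises(ValueError, match="100"):
            measure_snr(Volume(np.zeros((32, 32, 32)), VS), Mask(mask))
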