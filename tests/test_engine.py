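import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voldvc import (
    Mask,
    MultipassSchedule,
    RigidDeformation,
    SubsetStatus,
    TrigDeformation,
    Volume,
    build_subset_grid,
    cnorm,
    dc_correlation_map,
    dc_displacement,
    fft_displacement,
    fftdc_displacement,
    generate_speckle,
    run_multipass,
    sample_deformed,
    subvoxel_peak,
)
from voldvc.engine import ConstantWindowError

from .oracles import cnorm_loops, dc_map_loops

VS = 0.5


class TestBuildSubsetGrid:
    def test_full_mask_combinatorial_count(self):
        mask = Mask(np.ones((64, 64, 64), dtype=np.uint8))
        grid = build_subset_grid(mask, 16, overlap=0.5, mfvp=0.5)
        assert grid.stride == 8
        assert grid.grid_shape == (7, 7, 7)
        assert grid.n_active == 343

    def test_mfvp_boundary_is_inclusive(self):
        """A window with exactly the threshold fraction in-mask stays active."""
        mask = np.zeros((16, 16, 16), dtype=np.uint8)
        mask[:8] = 1  # first 8 of 16 planes: any 16^3 window is exactly 50%
        grid = build_subset_grid(Mask(mask), 16, overlap=0.5, mfvp=0.5)
        assert grid.valid_fraction.ravel()[0] == pytest.approx(0.5)
        assert grid.active.all()

    def test_window_outside_mask_is_inactive(self):
        mask = np.zeros((48, 48, 48), dtype=np.uint8)
        mask[:16, :16, :16] = 1
        grid = build_subset_grid(Mask(mask), 16, overlap=0.0, mfvp=0.5)
        assert grid.active[0, 0, 0]

    def test_no_active_subsets_raises(self):
        mask = np.zeros((32, 32, 32), dtype=np.uint8)
        mask[0, 0, 0] = 1
        with pytest.raises(ValueError, match="mask too small"):
            build_subset_grid(Mask(mask), 16, overlap=0.5, mfvp=0.5)

    @pytest.mark.parametrize("mfvp_pair", [(0.3, 0.5), (0.5, 0.7), (0.1, 0.9)])
    def test_raising_mfvp_never_adds_active_subsets(self, mfvp_pair):
        rng = np.random.default_rng(17)
        mask = Mask((rng.random((48, 48, 48)) > 0.45).astype(np.uint8))
        lo, hi = mfvp_pair

        def n_active(mfvp):
            try:
                return build_subset_grid(mask, 16, 0.5, mfvp).n_active
            except ValueError:  # no active subsets left at this threshold
                return 0

        assert n_active(hi) <= n_active(lo)


class TestCnorm:
    def test_perfect_match_is_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(6, 6, 6))
        assert cnorm(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_negated_window_is_minus_one(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(5, 5, 5))
        assert cnorm(a, -a) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.normal(10.0, 3.0, size=(4, 4, 4))
        b = rng.normal(10.0, 3.0, size=(4, 4, 4))
        assert cnorm(a, b) == pytest.approx(cnorm_loops(a, b), abs=1e-12)
        valid = rng.random((4, 4, 4)) > 0.3
        assert cnorm(a, b, valid) == pytest.approx(
            cnorm_loops(a, b, valid), abs=1e-12
        )

    @given(
        alpha=st.floats(0.1, 10.0),
        beta=st.floats(-100.0, 100.0),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_affine_intensity_change(self, alpha, beta, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(5, 5, 5))
        b = rng.normal(size=(5, 5, 5))
        assert cnorm(a, alpha * b + beta) == pytest.approx(cnorm(a, b), abs=1e-9)

    def test_constant_window_raises(self):
        a = np.ones((4, 4, 4))
        b = np.random.default_rng(3).normal(size=(4, 4, 4))
        with pytest.raises(ConstantWindowError):
            cnorm(a, b)


class TestSubvoxelPeak:
    def test_symmetric_neighbourhood_gives_zero(self):
        m = np.ones((3, 3, 3)) * 0.5
        m[1, 1, 1] = 1.0
        np.testing.assert_allclose(subvoxel_peak(m), [0, 0, 0], atol=1e-12)

    def test_gaussian_samples_recover_offset_exactly(self):
        """exp(-(x - 0.3)^2 / 2) sampled at -1, 0, 1 per axis -> delta 0.3."""
        x = np.arange(-1.0, 2.0)
        gx = np.exp(-((x - 0.3) ** 2) / 2)
        gy = np.exp(-((x - 0.0) ** 2) / 2)
        gz = np.exp(-((x + 0.2) ** 2) / 2)
        m = gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
        np.testing.assert_allclose(subvoxel_peak(m), [0.3, 0.0, -0.2], atol=1e-9)

    def test_flat_map_returns_zero(self):
        np.testing.assert_array_equal(subvoxel_peak(np.ones((3, 3, 3))), [0, 0, 0])

    def test_nan_neighbour_disables_only_that_axis(self):
        x = np.arange(-1.0, 2.0)
        g = np.exp(-((x - 0.3) ** 2) / 2)
        m = g[:, None, None] * g[None, :, None] * g[None, None, :]
        m[0, 1, 1] = np.nan
        delta = subvoxel_peak(m)
        assert delta[0] == 0.0
        assert delta[1] == pytest.approx(0.3, abs=1e-9)


class TestDcDisplacement:
    def test_identical_volumes_fixed_point(self, small_speckle, full_mask_64):
        _, vol = small_speckle
        grid = build_subset_grid(full_mask_64, 16, 0.5, 0.5)
        f = dc_displacement(vol, vol, grid, search_range=2)
        assert (f.status == SubsetStatus.OK).all()
        assert np.abs(f.u_vox).max() == 0.0
        assert f.cnorm.min() == pytest.approx(1.0, abs=1e-12)

    def test_integer_shift_recovered_exactly(self, small_speckle, full_mask_64):
        model, vol = small_speckle
        shifted = sample_deformed(
            model, RigidDeformation((3 * VS, -2 * VS, 1 * VS)), vol.shape, VS
        )
        grid = build_subset_grid(full_mask_64, 24, 0.5, 0.5)
        f = dc_displacement(vol, shifted, grid, search_range=5)
        interior = _interior_subsets(grid, (3, -2, 1), 5)
        assert interior.sum() >= 8
        assert (f.u_int[interior] == [3, -2, 1]).all()
        assert (np.abs(f.u_frac[interior]) == 0.0).all()  # perfect match rule
        assert f.cnorm[interior].min() > 0.999

    def test_correlation_map_equals_brute_force_oracle(self, small_speckle):
        model, vol = small_speckle
        rng = np.random.default_rng(8)
        noisy = Volume(vol.data + rng.normal(0, 0.05, vol.shape), VS)
        start, N, r = (20, 14, 9), 8, 2
        cmap = dc_correlation_map(vol.data, noisy.data, start, N, r)
        oracle = dc_map_loops(vol.data, noisy.data, start, N, r)
        np.testing.assert_allclose(cmap.values, oracle, atol=1e-12)
        assert tuple(cmap.peak_rel) == tuple(
            np.array(np.unravel_index(np.nanargmax(oracle), oracle.shape)) - r
        )

    def test_peak_on_search_boundary_flagged(self, small_speckle, full_mask_64):
        model, vol = small_speckle
        shifted = sample_deformed(
            model, RigidDeformation((3 * VS, 0, 0)), vol.shape, VS
        )
        grid = build_subset_grid(full_mask_64, 16, 0.5, 0.5)
        f = dc_displacement(vol, shifted, grid, search_range=3)
        interior = _interior_subsets(grid, (3, 0, 0), 3)
        assert (f.status[interior] == SubsetStatus.OUT_OF_RANGE).all()

    def test_intensity_invariance_of_cnorm_values(self, small_speckle, full_mask_64):
        _, vol = small_speckle
        rng = np.random.default_rng(9)
        other = Volume(vol.data + rng.normal(0, 0.1, vol.shape), VS)
        rescaled = Volume(other.data * 1.7 + 40.0, VS)
        grid = build_subset_grid(full_mask_64, 16, 0.5, 0.5)
        f1 = dc_displacement(vol, other, grid, search_range=2)
        f2 = dc_displacement(vol, rescaled, grid, search_range=2)
        np.testing.assert_allclose(f1.cnorm, f2.cnorm, atol=1e-9)
        np.testing.assert_array_equal(f1.u_int, f2.u_int)


def _interior_subsets(grid, shift, margin):
    """Subsets whose full search lattice stays inside the volume."""
    ok = np.ones(grid.grid_shape, dtype=bool)
    N = grid.subset_size
    for ax in range(3):
        starts = grid.starts[ax]
        lo = starts + min(0, shift[ax]) - margin
        hi = starts + N + max(0, shift[ax]) + margin
        good = (lo >= 0) & (hi <= grid.volume_shape[ax])
        shape = [1, 1, 1]
        shape[ax] = len(starts)
        ok &= good.reshape(shape)
    return ok & grid.active


class TestFftDisplacement:
    def test_identical_volumes_fixed_point(self, small_speckle, full_mask_64):
        _, vol = small_speckle
        grid = build_subset_grid(full_mask_64, 16, 0.5, 0.5)
        f = fft_displacement(vol, vol, grid)
        assert np.abs(f.u_vox).max() == 0.0
        assert f.cnorm.min() == pytest.approx(1.0, abs=1e-12)

    def test_integer_shift_agrees_with_dc(self, fine_speckle):
        model, vol = fine_speckle
        mask = Mask(np.ones(vol.shape, dtype=np.uint8))
        shifted = sample_deformed(
            model, RigidDeformation((3 * VS, -2 * VS, 1 * VS)), vol.shape, VS
        )
        grid = build_subset_grid(mask, 24, 0.5, 0.5)
        f_fft = fft_displacement(vol, shifted, grid)
        f_dc = dc_displacement(vol, shifted, grid, search_range=5)
        interior = _interior_subsets(grid, (3, -2, 1), 5)
        np.testing.assert_array_equal(f_fft.u_int[interior], f_dc.u_int[interior])
        assert (f_fft.u_int[interior] == [3, -2, 1]).all()

    def test_large_shift_beyond_dc_range(self, fine_speckle):
        """A 10-voxel shift: FFT finds it, DC at range 5 cannot."""
        model, vol = fine_speckle
        mask = Mask(np.ones(vol.shape, dtype=np.uint8))
        shifted = sample_deformed(
            model, RigidDeformation((10 * VS, 0, 0)), vol.shape, VS
        )
        grid = build_subset_grid(mask, 32, 0.5, 0.5)
        f_fft = fft_displacement(vol, shifted, grid)
        interior = _interior_subsets(grid, (10, 0, 0), 0)
        assert (f_fft.u_int[interior] == [10, 0, 0]).all()
        f_dc = dc_displacement(vol, shifted, grid, search_range=5)
        assert (f_dc.status[interior] != SubsetStatus.OK).any() or not (
            f_dc.u_int[interior] == [10, 0, 0]
        ).all()


class TestFftDcDisplacement:
    def test_identical_volumes_fixed_point(self, small_speckle, full_mask_64):
        _, vol = small_speckle
        grid = build_subset_grid(full_mask_64, 16, 0.5, 0.5)
        for f in (
            fftdc_displacement(vol, vol, grid),
            dc_displacement(vol, vol, grid, search_range=2),
            fft_displacement(vol, vol, grid),
        ):
            assert np.abs(f.u_vox).max() == 0.0
            assert f.cnorm.min() == pytest.approx(1.0, abs=1e-12)

    def test_integer_shift_refinement_contributes_nothing(self, fine_speckle):
        model, vol = fine_speckle
        mask = Mask(np.ones(vol.shape, dtype=np.uint8))
        shifted = sample_deformed(
            model, RigidDeformation((3 * VS, -2 * VS, 1 * VS)), vol.shape, VS
        )
        grid = build_subset_grid(mask, 24, 0.5, 0.5)
        f = fftdc_displacement(vol, shifted, grid)
        interior = _interior_subsets(grid, (3, -2, 1), 2)
        assert (f.u_int[interior] == [3, -2, 1]).all()
        assert (np.abs(f.u_frac[interior]) == 0.0).all()

    def test_subvoxel_translation_recovery(self):
        """0.25-voxel translation, subset 40: median error well under 0.1 vox."""
        shape = (96, 96, 96)
        model, vol = generate_speckle(shape, VS, seed=5)
        shifted = sample_deformed(
            model, RigidDeformation((0.25 * VS, 0, 0)), shape, VS
        )
        mask = Mask(np.ones(shape, dtype=np.uint8))
        grid = build_subset_grid(mask, 40, 0.5, 0.5)
        f = fftdc_displacement(vol, shifted, grid)
        err = np.abs(f.u_vox[f.ok] - [0.25, 0.0, 0.0])
        assert (np.median(err, axis=0) < 0.1).all()


class TestMultipass:
    def test_schedule_validation(self):
        with pytest.raises(ValueError, match="decreasing"):
            MultipassSchedule((40, 48))
        with pytest.raises(ValueError, match="8"):
            MultipassSchedule((16, 4))

    def test_zero_strain_pair_stays_zero(self, small_speckle, full_mask_64):
        _, vol = small_speckle
        schedule = MultipassSchedule((32, 24, 16), 2)
        field, info = run_multipass(vol, vol, full_mask_64, schedule)
        assert np.abs(field.u_vox).max() == 0.0
        assert field.grid.subset_size == 16

    def test_executes_sizes_times_iterations_passes(self, small_speckle, full_mask_64):
        _, vol = small_speckle
        schedule = MultipassSchedule((24, 16), 3)
        _, info = run_multipass(vol, vol, full_mask_64, schedule)
        assert info["n_passes"] == 6
        assert [p["subset_size"] for p in info["passes"]] == [24, 24, 24, 16, 16, 16]

    def test_multipass_not_worse_than_single_pass_on_smooth_field(self):
        shape = (96, 96, 96)
        model, vol = generate_speckle(shape, VS, blob_density=0.02, blob_sigma=0.6, seed=31)
        trig = TrigDeformation((2.0, 0.0, 0.0), (48 * VS, 48 * VS, 48 * VS), VS)
        deformed = sample_deformed(model, trig, shape, VS)
        mask = Mask(np.ones(shape, dtype=np.uint8))

        def rms_err(field):
            ok = field.ok
            centers = field.grid.centers()[ok] * VS
            u_true = trig.displacement(centers) / VS
            return float(np.sqrt(np.mean((field.u_vox[ok] - u_true) ** 2)))

        single_grid = build_subset_grid(mask, 40, 0.5, 0.5)
        single = fftdc_displacement(vol, deformed, single_grid)
        multi, _ = run_multipass(
            vol, deformed, mask, MultipassSchedule((64, 56, 48, 40), 3)
        )
        assert rms_err(multi) <= rms_err(single) * 1.05
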