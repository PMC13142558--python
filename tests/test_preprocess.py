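"""Motion binning, PCA denoising, drift correction, orientation."""

import numpy as np
import pytest

from cestkit.core import AcquisitionParams, OffsetImageStack
from cestkit.preprocess import (apply_binning, malinowski_rank, motion_bin,
                                orient, pca_denoise, thermal_drift_correct)
from cestkit.synth import make_radial_series


class TestMotionBin:
    def test_flat_signal_discards_nothing(self):
        series, _ = make_radial_series(n_offsets=3, n_segments=8)
        res = motion_bin(series)
        assert res.n_discarded_per_offset == 0
        assert all(len(v) == 8 for v in res.kept_segments.values())

    def test_constructed_corruptions_detected_everywhere(self):
        # two 40%-attenuated segments at one offset -> exactly two
        # discarded at EVERY offset (equal-count enforcement)
        series, bad = make_radial_series(
            n_offsets=4, n_segments=10,
            corrupt_segments=[(1, 2), (1, 7)], attenuation=0.4)
        res = motion_bin(series)
        assert res.n_discarded_per_offset == 2
        for off, kept in res.kept_segments.items():
            assert len(kept) == 8
        # the corrupted segments themselves are among the discarded
        assert 2 not in res.kept_segments[1]
        assert 7 not in res.kept_segments[1]

    def test_direct_threshold_arithmetic(self):
        series, _ = make_radial_series(
            n_offsets=2, n_segments=6, corrupt_segments=[(0, 3)],
            attenuation=0.5)
        res = motion_bin(series, window=5, n_sigma=1.0)
        # recompute the flag rule by hand
        sums = res.segment_sums
        flagged = sums < (res.moving_average - 1.0 * np.std(res.moving_average))
        assert flagged.any()
        assert res.n_discarded_per_offset == max(
            flagged[:6].sum(), flagged[6:].sum())

    @pytest.mark.parametrize("seed", range(10))
    def test_equal_retained_counts_random_corruption(self, seed):
        rng = np.random.default_rng(seed)
        n_off, n_seg = 3, 9
        bad = [(int(rng.integers(n_off)), int(rng.integers(n_seg)))
               for _ in range(rng.integers(0, 4))]
        series, _ = make_radial_series(
            n_offsets=n_off, n_segments=n_seg,
            corrupt_segments=bad, noise_sd=0.01, seed=seed)
        res = motion_bin(series)
        counts = {len(v) for v in res.kept_segments.values()}
        assert len(counts) == 1

    def test_values_unaltered_only_membership(self):
        series, _ = make_radial_series(
            n_offsets=2, n_segments=5, corrupt_segments=[(0, 1)])
        res = motion_bin(series)
        kept = apply_binning(series, res)
        # every retained projection equals its original row bit-exactly
        for row in kept.projections:
            assert any(np.array_equal(row, orig)
                       for orig in series.projections)

    def test_error_when_nothing_would_remain(self):
        series, _ = make_radial_series(
            n_offsets=4, n_segments=3,
            corrupt_segments=[(1, 0), (1, 1), (1, 2)], attenuation=0.9)
        with pytest.raises(ValueError, match="leave no data"):
            motion_bin(series, window=11)


def _stack_from_matrix(X, shape):
    """pixels x offsets matrix -> stack."""
    c = X.shape[1]
    data = X.T.reshape(c, *shape)
    offsets = np.linspace(-5, 5, c)
    return OffsetImageStack(data=data, offsets_ppm=offsets,
                            params=AcquisitionParams(offsets_ppm=offsets))


class TestPcaDenoise:
    def test_noiseless_low_rank_selects_true_rank(self):
        rng = np.random.default_rng(0)
        r, c, k = 256, 12, 3
        X = rng.random((r, k)) @ rng.random((k, c))
        stack = _stack_from_matrix(X, (16, 16))
        out, rank = pca_denoise(stack)
        assert rank <= k
        err = np.linalg.norm(out.data - stack.data) / np.linalg.norm(stack.data)
        assert err < 1e-8

    def test_denoising_improves_rmse_on_noisy_low_rank(self):
        rng = np.random.default_rng(1)
        r, c, k = 400, 15, 3
        base = rng.random((r, k)) @ rng.random((k, c))
        wins = 0
        trials = 20
        for t in range(trials):
            noisy = base + rng.normal(0, base.std() / 20, base.shape)
            out, _ = pca_denoise(_stack_from_matrix(noisy, (20, 20)))
            rmse_noisy = np.sqrt(np.mean((noisy - base) ** 2))
            rmse_den = np.sqrt(
                np.mean((out.data.reshape(c, -1).T - base) ** 2))
            wins += rmse_den < rmse_noisy
        assert wins >= int(0.95 * trials)

    def test_constant_data_returned_unchanged_rank_zero(self):
        X = np.full((100, 8), 3.0)
        stack = _stack_from_matrix(X, (10, 10))
        out, rank = pca_denoise(stack)
        assert rank == 0
        np.testing.assert_array_equal(out.data, stack.data)

    def test_mask_smaller_than_offset_count_rejected(self):
        X = np.random.default_rng(2).random((100, 8))
        stack = _stack_from_matrix(X, (10, 10))
        mask = np.zeros((10, 10), bool)
        mask[0, 0] = True
        with pytest.raises(ValueError, match="pixels"):
            pca_denoise(stack, mask=mask)

    def test_shape_preserved(self):
        X = np.random.default_rng(3).random((144, 10))
        stack = _stack_from_matrix(X, (12, 12))
        out, _ = pca_denoise(stack)
        assert out.data.shape == stack.data.shape


class TestDriftCorrection:
    def _stack(self, factors):
        offsets = np.linspace(-5, 5, factors.size)
        data = np.ones((factors.size, 8, 8)) * factors[:, None, None]
        return OffsetImageStack(
            data=data, offsets_ppm=offsets,
            params=AcquisitionParams(offsets_ppm=offsets),
            frame_times_s=np.arange(factors.size, dtype=float) * 10)

    def test_equal_references_change_nothing(self):
        stack = self._stack(np.ones(10))
        out = thermal_drift_correct(stack, [1.0, 1.0, 1.0], [0.0, 45.0, 90.0])
        np.testing.assert_allclose(out.data, stack.data)

    def test_two_percent_linear_decay_flattened(self):
        n = 12
        times = np.arange(n, dtype=float) * 10
        drift = 1.0 - 0.02 * times / times[-1]
        stack = self._stack(drift)
        ref_idx = [0, n // 2, n - 1]
        out = thermal_drift_correct(stack, drift[ref_idx], times[ref_idx])
        means = out.data.mean(axis=(1, 2))
        assert np.ptp(means) / means.mean() < 1e-3

    def test_equals_least_squares_line_division(self):
        rng = np.random.default_rng(4)
        times = np.array([0.0, 30.0, 60.0, 90.0])
        refs = 1.0 + rng.normal(0, 0.01, 4)  # nonmonotonic noise
        stack = self._stack(np.ones(6))
        out = thermal_drift_correct(stack, refs, times,
                                    frame_times_s=stack.frame_times_s)
        b, a = np.polyfit(times, refs, 1)
        expected = 1.0 / ((a + b * stack.frame_times_s) / (a + b * times[0]))
        np.testing.assert_allclose(out.data.mean(axis=(1, 2)), expected)

    def test_single_reference_warns_no_correction(self):
        stack = self._stack(np.ones(5))
        with pytest.warns(UserWarning, match="2 reference"):
            out = thermal_drift_correct(stack, [1.0], [0.0])
        np.testing.assert_array_equal(out.data, stack.data)


class TestOrient:
    def _stack(self):
        rng = np.random.default_rng(5)
        offsets = np.linspace(-5, 5, 4)
        return OffsetImageStack(
            data=rng.random((4, 6, 8)), offsets_ppm=offsets,
            params=AcquisitionParams(offsets_ppm=offsets),
            m0=rng.random((6, 8)))

    def test_four_rotations_identity(self):
        s = self._stack()
        out = orient(s, rotations_90=4)
        np.testing.assert_array_equal(out.data, s.data)

    def test_double_flip_identity(self):
        s = self._stack()
        out = orient(orient(s, flip_h=True), flip_h=True)
        np.testing.assert_array_equal(out.data, s.data)
        np.testing.assert_array_equal(out.m0, s.m0)

    def test_rot_then_flip_equals_index_permutation(self):
        s = self._stack()
        out = orient(s, rotations_90=1, flip_h=True)
        expected = np.rot90(s.data, 1, axes=(1, 2))[:, :, ::-1]
        np.testing.assert_array_equal(out.data, expected)
        assert out.orientation_ops[-1]["rotations_90"] == 1


class TestMalinowski:
    def test_indicator_picks_elbow(self):
        # strong components then a flat noise floor
        lam = np.array([100.0, 50.0, 20.0] + [0.01] * 9)
        assert malinowski_rank(lam, r=500, c=12) == 3
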