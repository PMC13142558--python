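"""WASSR B0, double-angle B1, spline upsampling, variable-TR T1."""

import numpy as np
import pytest

from cestkit.core import AcquisitionParams, OffsetImageStack, PixelMap
from cestkit.fieldmaps import (FieldMaps, dam_b1, segment_field_stats,
                               t1_map, upsample_map, wassr_b0)
from cestkit.segmentation import SegmentSet
from cestkit.zspec import lorentzian


def wassr_stack(b0_field, offsets=None, noise_sd=0.0, seed=0):
    """Normalized WASSR stack with per-pixel dip centers b0_field."""
    if offsets is None:
        offsets = np.linspace(-1.0, 1.0, 33)
    rng = np.random.default_rng(seed)
    b0_field = np.asarray(b0_field, dtype=float)
    data = 1.0 - lorentzian(0.85, 0.35, 0.0,
                            offsets[:, None, None] - b0_field[None])
    if noise_sd:
        data = data + rng.normal(0, noise_sd, data.shape)
    return OffsetImageStack(
        data=data, offsets_ppm=offsets,
        params=AcquisitionParams(offsets_ppm=offsets), normalized=True)


class TestWassr:
    def test_recovers_known_shift(self):
        stack = wassr_stack(np.full((3, 3), 0.12))
        pmap = wassr_b0(stack)
        np.testing.assert_allclose(pmap.values, 0.12, atol=0.005)

    def test_symmetric_dip_gives_zero(self):
        stack = wassr_stack(np.zeros((2, 2)))
        pmap = wassr_b0(stack)
        np.testing.assert_allclose(pmap.values, 0.0, atol=1e-3)

    def test_linear_gradient_recovered(self):
        cols = np.linspace(-0.2, 0.2, 8)
        field = np.tile(cols, (4, 1))
        pmap = wassr_b0(wassr_stack(field))
        assert np.max(np.abs(pmap.values - field)) < 0.01
        assert np.corrcoef(pmap.values.ravel(), field.ravel())[0, 1] > 0.999

    def test_axis_shift_equivariance(self):
        offsets = np.linspace(-1.0, 1.0, 33)
        base = wassr_b0(wassr_stack(np.full((2, 2), 0.05), offsets))
        delta = 0.1
        shifted = wassr_b0(wassr_stack(np.full((2, 2), 0.05),
                                       offsets))  # same data...
        # ...but with the offset axis shifted by delta
        st = wassr_stack(np.full((2, 2), 0.05), offsets)
        st = OffsetImageStack(data=st.data, offsets_ppm=offsets + delta,
                              params=st.params, normalized=True)
        moved = wassr_b0(st)
        np.testing.assert_allclose(moved.values - base.values, delta,
                                   atol=1e-3)
        np.testing.assert_allclose(shifted.values, base.values)

    def test_unnormalized_stack_rejected(self):
        offsets = np.linspace(-1, 1, 11)
        st = OffsetImageStack(data=np.ones((11, 2, 2)) * 500,
                              offsets_ppm=offsets,
                              params=AcquisitionParams(offsets_ppm=offsets))
        with pytest.raises(ValueError, match="normalized"):
            wassr_b0(st)


class TestDamB1:
    def test_unit_kappa_at_sixty_degrees(self):
        m = np.full((2, 2), 0.866)
        pmap = dam_b1(m, m, theta_nominal_deg=60.0)
        np.testing.assert_allclose(pmap.values, 1.0, atol=1e-3)

    def test_equal_images_at_forty_five(self):
        one = np.ones((2, 2))
        pmap = dam_b1(one, one, theta_nominal_deg=45.0)
        np.testing.assert_allclose(pmap.values, 60.0 / 45.0, rtol=1e-9)

    def test_arccos_domain_violation_invalid(self):
        m = np.ones((2, 2))
        pmap = dam_b1(m, 2.2 * m, theta_nominal_deg=30.0)
        assert not pmap.valid_mask.any()

    @pytest.mark.parametrize("scale", [0.5, 3.0, 1e4])
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(0)
        kappa = rng.uniform(0.8, 1.2, (4, 4))
        th = np.deg2rad(30.0)
        m1, m2 = np.sin(kappa * th), np.sin(kappa * 2 * th)
        a = dam_b1(m1, m2, 30.0)
        b = dam_b1(scale * m1, scale * m2, 30.0)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)
        np.testing.assert_allclose(a.values, kappa, rtol=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            dam_b1(np.ones((2, 2)), np.ones((3, 3)), 30.0)

    def test_noise_floor_masks_background(self):
        m1 = np.array([[1.0, 0.001], [1.0, 0.002]])
        m2 = 0.8 * m1
        pmap = dam_b1(m1, m2, 30.0, noise_floor=0.01)
        assert pmap.valid_mask[0, 0] and not pmap.valid_mask[0, 1]


class TestUpsample:
    def test_constant_stays_constant(self):
        pmap = PixelMap(np.full((8, 8), 2.5))
        out = upsample_map(pmap, (20, 20))
        np.testing.assert_allclose(out.values, 2.5, rtol=1e-9)

    def test_linear_ramp_reproduced(self):
        # bicubic splines reproduce polynomials up to degree 3
        src = np.outer(np.ones(8), np.arange(8, dtype=float))
        out = upsample_map(PixelMap(src), (8, 15))
        expected = np.outer(np.ones(8), np.linspace(0, 7, 15))
        np.testing.assert_allclose(out.values, expected, atol=1e-9)

    def test_equal_sizes_is_identity(self):
        vals = np.random.default_rng(1).random((6, 6))
        out = upsample_map(PixelMap(vals), (6, 6))
        np.testing.assert_array_equal(out.values, vals)

    def test_downsampling_rejected(self):
        with pytest.raises(ValueError):
            upsample_map(PixelMap(np.ones((8, 8))), (4, 4))


class TestT1Map:
    TRS = np.array([0.3, 0.6, 1.0, 1.6, 2.5, 4.0, 6.5, 10.0])

    def test_noiseless_recovery(self):
        t1 = 1.8
        imgs = 1000.0 * (1 - np.exp(-self.TRS[:, None, None] / t1)) \
            * np.ones((1, 3, 3))
        pmap = t1_map(imgs, self.TRS)
        np.testing.assert_allclose(pmap.values, 1.8, atol=0.01)

    def test_two_compartment_recovery(self):
        t1s = np.where(np.arange(6) < 3, 1.0, 2.5)
        imgs = 1000.0 * (1 - np.exp(-self.TRS[:, None, None]
                                    / t1s[None, None, :])) * np.ones((1, 1, 6))
        pmap = t1_map(imgs, self.TRS)
        assert pmap.values[0, :3].mean() == pytest.approx(1.0, rel=0.02)
        assert pmap.values[0, 3:].mean() == pytest.approx(2.5, rel=0.02)

    def test_noise_bias_small(self):
        rng = np.random.default_rng(2)
        t1 = 1.8
        clean = 1000.0 * (1 - np.exp(-self.TRS / t1))
        vals = []
        for _ in range(50):
            s = clean + rng.normal(0, 20.0, clean.size)  # SNR 50
            pmap = t1_map(s[:, None, None], self.TRS)
            vals.append(pmap.values[0, 0])
        vals = np.array(vals)
        assert abs(vals.mean() - t1) / t1 < 0.02       # bias < 2%
        assert np.sqrt(np.mean((vals - t1) ** 2)) / t1 < 0.05

    def test_degenerate_tr_list_rejected(self):
        with pytest.raises(ValueError):
            t1_map(np.ones((4, 2, 2)), [10.0, 10.0, 10.0, 10.0])

    def test_too_few_trs_rejected(self):
        with pytest.raises(ValueError, match="4 TR"):
            t1_map(np.ones((3, 2, 2)), [0.3, 1.0, 3.0])


class TestSegmentStats:
    def _maps(self, b0):
        return FieldMaps(b0_ppm=PixelMap(b0, "B0 shift", "ppm"),
                         kappa=PixelMap(np.ones_like(b0), "kappa"))

    def test_uniform_field_equal_medians(self):
        b0 = np.full((4, 6), 0.07)
        masks = {"a": np.zeros((4, 6), bool), "b": np.zeros((4, 6), bool)}
        masks["a"][:, :3] = True
        masks["b"][:, 3:] = True
        df = segment_field_stats(self._maps(b0), SegmentSet(masks=masks))
        assert df["b0_ppm_median"].nunique() == 1

    def test_gradient_orders_medians(self):
        b0 = np.tile(np.linspace(-0.2, 0.2, 6), (4, 1))
        masks = {"left": np.zeros((4, 6), bool),
                 "right": np.zeros((4, 6), bool)}
        masks["left"][:, :2] = True
        masks["right"][:, 4:] = True
        df = segment_field_stats(self._maps(b0),
                                 SegmentSet(masks=masks)).set_index("segment")
        assert df.loc["left", "b0_ppm_median"] < df.loc["right",
                                                        "b0_ppm_median"]

    def test_empty_segment_omitted_with_warning(self):
        b0 = np.zeros((3, 3))
        masks = {"some": np.zeros((3, 3), bool),
                 "none": np.zeros((3, 3), bool)}
        masks["some"][0, 0] = True
        with pytest.warns(UserWarning, match="empty"):
            df = segment_field_stats(self._maps(b0), SegmentSet(masks=masks))
        assert list(df["segment"]) == ["some"]
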