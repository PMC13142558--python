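"""QUESP: saturation efficiency, closed-form MTRasym, and the three
fitting routes, cross-validated against the Bloch-McConnell simulator."""

import numpy as np
import pytest

from cestkit import bloch
from cestkit.core import AcquisitionParams
from cestkit.quesp import (DEFAULT_BOUNDS, QuespSeries, alpha, fit_quesp,
                           mtrasym_from_stack, mtrasym_model, mtrrex_model,
                           omega1, steady_state_warning)
from conftest import raw_stack

GAMMA = 2.0 * np.pi * 42.577  # rad/s per uT


class TestAlpha:
    def test_equal_terms_give_half(self):
        kb = omega1(3.0)
        assert alpha(3.0, kb) == pytest.approx(0.5)

    def test_zero_b1_gives_zero(self):
        assert alpha(0.0, 500.0) == 0.0

    def test_zero_exchange_gives_one(self):
        assert alpha(2.0, 0.0) == pytest.approx(1.0)


def mtrasym_independent(fb, kb, b1, r1a, tp, zi):
    """Second, independently coded evaluation of the closed-form MTRasym
    (different algebraic arrangement, scalar math)."""
    import math

    w1 = 2.0 * math.pi * 42.577 * b1
    a = w1 * w1 / (w1 * w1 + kb * kb)
    rex = fb * kb * a
    ss = rex / (r1a + rex)
    term1 = (zi - 1.0) * math.exp(-r1a * tp)
    term2 = (zi - (1.0 - ss)) * math.exp(-(r1a + rex) * tp)
    return ss + term1 - term2


class TestMtrasymModel:
    @pytest.mark.parametrize("seed", range(20))
    def test_zero_at_tp_zero_random_draws(self, seed):
        rng = np.random.default_rng(seed)
        v = mtrasym_model(rng.uniform(1e-5, 5e-3), rng.uniform(50, 5e3),
                          rng.uniform(0.5, 8), rng.uniform(0.2, 2), 0.0,
                          rng.uniform(0.0, 1.0))
        assert v == pytest.approx(0.0, abs=1e-12)

    def test_steady_state_limit_half(self):
        # choose fb*kb*alpha = R1a -> limit 0.5
        r1a, kb, b1 = 0.33, 1000.0, 4.0
        fb = r1a / (kb * alpha(b1, kb))
        v = mtrasym_model(fb, kb, b1, r1a, 1e3)
        assert v == pytest.approx(0.5, abs=1e-9)

    def test_agrees_with_independent_evaluator(self):
        v = mtrasym_model(1e-3, 1000.0, 4.0, 0.33, 4.0, 1.0)
        w = mtrasym_independent(1e-3, 1000.0, 4.0, 0.33, 4.0, 1.0)
        assert v == pytest.approx(w, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_draws_match_independent_evaluator(self, seed):
        rng = np.random.default_rng(100 + seed)
        args = (rng.uniform(1e-5, 5e-3), rng.uniform(50, 5e3),
                rng.uniform(0.5, 8), rng.uniform(0.2, 2),
                rng.uniform(0.5, 20), rng.uniform(0, 1))
        assert mtrasym_model(*args) == pytest.approx(
            mtrasym_independent(*args), abs=1e-12)


class TestFitQuesp:
    B1 = np.array([1.0, 2.0, 3.0, 4.0, 6.0])

    def _tile(self, y, shape=(2, 2)):
        return np.tile(np.asarray(y)[:, None, None], (1, *shape))

    def test_mtrasym_route_recovers_noiseless(self):
        fb_t, kb_t, r1a, tp = 7.2e-4, 800.0, 0.33, 15.0
        y = mtrasym_model(fb_t, kb_t, self.B1, r1a, tp)
        series = QuespSeries(b1_uT=self.B1, tp_s=tp,
                             mtr_asym=self._tile(y), r1a=r1a)
        fit = fit_quesp(series, "mtr_asym")
        assert fit.fb.values[0, 0] == pytest.approx(fb_t, rel=0.01)
        assert fit.kb.values[0, 0] == pytest.approx(kb_t, rel=0.01)
        assert fit.r2.values[0, 0] > 0.999

    def test_rex_and_omega_routes_agree(self):
        # algebraic rearrangements of the same expression
        fb_t, kb_t, r1a = 1.1e-3, 600.0, 0.5
        rex = mtrrex_model(fb_t, kb_t, self.B1, r1a)
        z_ref = np.full_like(self.B1, 0.85)
        z_lab = 1.0 / (rex + 1.0 / z_ref)
        series = QuespSeries(b1_uT=self.B1, tp_s=20.0,
                             z_lab=self._tile(z_lab),
                             z_ref=self._tile(z_ref), r1a=r1a)
        fit_rex = fit_quesp(series, "mtr_rex")
        fit_om = fit_quesp(series, "omega_plot")
        for fit in (fit_rex, fit_om):
            assert fit.fb.values[0, 0] == pytest.approx(fb_t, rel=0.01)
            assert fit.kb.values[0, 0] == pytest.approx(kb_t, rel=0.01)
        assert fit_rex.kb.values[0, 0] == pytest.approx(
            fit_om.kb.values[0, 0], rel=0.01)

    def test_all_zero_series_flagged_low_r2(self):
        series = QuespSeries(b1_uT=self.B1, tp_s=10.0,
                             mtr_asym=self._tile(np.zeros(5)), r1a=0.5)
        fit = fit_quesp(series, "mtr_asym")
        assert fit.fb.values[0, 0] <= 10 * DEFAULT_BOUNDS["fb"][0]

    def test_noise_recovery_median_kb_error(self):
        rng = np.random.default_rng(11)
        fb_t, kb_t, r1a, tp = 9e-4, 1000.0, 0.45, 12.0
        clean = mtrasym_model(fb_t, kb_t, self.B1, r1a, tp)
        errs = []
        for _ in range(30):
            y = clean + rng.normal(0, 0.002, clean.size)
            series = QuespSeries(b1_uT=self.B1, tp_s=tp,
                                 mtr_asym=y[:, None, None], r1a=r1a)
            fit = fit_quesp(series, "mtr_asym")
            errs.append(abs(fit.kb.values[0, 0] - kb_t) / kb_t)
        assert np.median(errs) < 0.15

    def test_eq6_vs_full_simulation_dilute_regime(self):
        # analytic MTRasym within 10% of Bloch-McConnell at 7T, >= 2 ppm
        field = 300.33
        fb_t, kb_t, r1a, tp, dw = 5e-4, 800.0, 0.33, 6.0, 3.5
        pools = [bloch.water_pool(r1=r1a, r2=0.5),
                 bloch.PoolParameters("s", fb_t, kb_t, dw, 1.0, 50.0)]
        for b1 in (2.0, 4.0):
            z_lab = bloch.simulate_z(
                pools, bloch.SaturationEvent(b1, tp, dw), field)
            z_ref = bloch.simulate_z(
                pools, bloch.SaturationEvent(b1, tp, -dw), field)
            sim = z_ref - z_lab
            ana = mtrasym_model(fb_t, kb_t, b1, r1a, tp)
            assert ana == pytest.approx(sim, rel=0.10)

    def test_too_few_b1_values_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            QuespSeries(b1_uT=np.array([1.0, 1.0, 2.0]), tp_s=5.0)


class TestSteadyStateWarning:
    def _params(self, tp, rec):
        return AcquisitionParams(offsets_ppm=np.array([2.0]),
                                 sat_time_s=tp, recovery_time_s=rec)

    def test_long_saturation_no_warning(self):
        msgs = steady_state_warning(self._params(10.0, 10.0), t1a_s=1.8)
        assert msgs == []

    def test_short_saturation_warns(self):
        with pytest.warns(UserWarning, match="steady-state"):
            msgs = steady_state_warning(self._params(2.0, 10.0), t1a_s=1.8)
        assert len(msgs) == 1

    def test_short_recovery_warns(self):
        with pytest.warns(UserWarning, match="relax"):
            msgs = steady_state_warning(self._params(10.0, 1.0), t1a_s=1.8)
        assert len(msgs) == 1


class TestMtrasymFromStack:
    def _stack(self, z_of_dw, b1s, offsets):
        n_b1 = len(b1s)
        all_off = np.tile(offsets, n_b1)
        frames = np.concatenate(
            [z_of_dw(offsets, b)[:, None, None] * np.ones((1, 2, 2))
             for b in b1s])
        params = AcquisitionParams(
            offsets_ppm=all_off, sat_time_s=5.0,
            b1_list_uT=np.repeat(b1s, offsets.size))
        from cestkit.core import OffsetImageStack
        return OffsetImageStack(data=frames, offsets_ppm=all_off,
                                params=params, normalized=True)

    def test_symmetric_spectrum_gives_zero(self):
        offsets = np.linspace(-4, 4, 17)
        stack = self._stack(lambda o, b: 1 - 0.5 * np.exp(-o**2),
                            [1.0, 2.0, 3.0], offsets)
        asym = mtrasym_from_stack(stack, dw_ppm=2.0)
        for img in asym.values():
            np.testing.assert_allclose(img, 0.0, atol=1e-12)

    def test_label_dip_gives_positive_asymmetry(self):
        offsets = np.linspace(-4, 4, 33)

        def z(o, b):
            return 1 - 0.05 * b * np.exp(-((o - 2.0) ** 2))

        stack = self._stack(z, [1.0, 2.0, 3.0], offsets)
        asym = mtrasym_from_stack(stack, dw_ppm=2.0)
        assert all(np.all(img > 0) for img in asym.values())
        assert asym[3.0][0, 0] > asym[1.0][0, 0]

    def test_one_sided_acquisition_rejected(self):
        offsets = np.linspace(0.5, 4, 8)
        stack = self._stack(lambda o, b: np.ones_like(o),
                            [1.0, 2.0, 3.0], offsets)
        with pytest.raises(ValueError, match="one-sided"):
            mtrasym_from_stack(stack, dw_ppm=2.0)
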