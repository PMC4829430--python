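"""Closed-form cap kinetics against independent numerical oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq

from ebcap.cap_models import (
    CapPrediction,
    KineticParams,
    ThresholdSpec,
    cap_decay_rate,
    delay_dispersion,
    delay_end_density,
    delay_from_intensity_ratio,
    delay_total_number,
    delay_two_step,
    delay_window_L,
    intensity_predictions,
    site_density,
    sites_in_window,
    total_sites,
    two_step_end_density,
    two_step_total,
)

MAL3 = KineticParams(v_g=33.0, v_s=40.0, k_m=0.16)
CONC = KineticParams(v_g=28.0, v_s=0.28 * 28.0 + 22.0, k_m=0.16)

params_strategy = st.builds(
    KineticParams,
    v_g=st.floats(10.0, 90.0),
    v_s=st.floats(0.0, 60.0),
    k_m=st.floats(0.05, 0.5),
)


class TestSiteDensity:
    def test_maximum_at_origin(self):
        assert site_density(0.0, 0.0, MAL3) == pytest.approx(13.0 / 8.0)

    def test_one_decay_length(self):
        p = MAL3
        assert site_density(p.v_g / p.k_m, 0.0, p) == pytest.approx(1.625 / math.e)

    def test_integral_matches_total_sites(self):
        p = KineticParams(v_g=33.0, v_s=0.0, k_m=0.16)
        integral, _ = quad(lambda x: site_density(x, 0.0, p), 0.0, np.inf)
        assert integral == pytest.approx(335.15625, rel=1e-8)
        assert total_sites(0.0, p) == pytest.approx(integral, rel=1e-8)

    @pytest.mark.parametrize("bad", [-1.0, np.nan, np.inf])
    def test_invalid_arguments(self, bad):
        with pytest.raises(ValueError):
            site_density(bad, 0.0, MAL3)
        with pytest.raises(ValueError):
            site_density(0.0, bad, MAL3)


class TestTotalSites:
    def test_initial_count(self):
        assert total_sites(0.0, KineticParams(v_g=33.0, k_m=0.16)) == pytest.approx(335.2, abs=0.05)

    def test_decay_rate_definition(self):
        t = 1.0 / cap_decay_rate(MAL3)
        assert total_sites(t, MAL3) / total_sites(0.0, MAL3) == pytest.approx(1.0 / math.e)

    def test_no_shrinkage_limit(self):
        p = KineticParams(v_g=33.0, v_s=0.0, k_m=0.16)
        assert total_sites(3.0, p) / total_sites(0.0, p) == pytest.approx(math.exp(-0.16 * 3.0))


class TestCapDecayRate:
    def test_mal3_printed_value(self):
        assert cap_decay_rate(MAL3) == pytest.approx(0.3539, abs=5e-4)
        assert round(cap_decay_rate(MAL3), 2) == 0.35

    def test_limits(self):
        assert cap_decay_rate(KineticParams(v_g=30.0, v_s=0.0, k_m=0.2)) == pytest.approx(0.2)
        assert cap_decay_rate(KineticParams(v_g=30.0, v_s=30.0, k_m=0.2)) == pytest.approx(0.4)

    @given(params_strategy)
    @settings(max_examples=50, deadline=None)
    def test_never_below_maturation_rate(self, p):
        assert cap_decay_rate(p) >= p.k_m


class TestDelayFromIntensityRatio:
    def test_mal3_prediction(self):
        # with the cap 29% of its initial size at catastrophe, the decay
        # rate 0.35 1/s predicts the measured ~3.5 s mean delay
        t = delay_from_intensity_ratio(1.0, 0.29, cap_decay_rate(MAL3))
        assert t == pytest.approx(3.5, abs=0.05)

    def test_trivial_ratios(self):
        assert delay_from_intensity_ratio(50.0, 50.0, 0.3) == 0.0
        assert delay_from_intensity_ratio(1.0, 1.0 / math.e, 1.0) == pytest.approx(1.0)

    def test_rejects_growth(self):
        with pytest.raises(ValueError):
            delay_from_intensity_ratio(10.0, 11.0, 0.3)


class TestDelayDispersion:
    def test_pythagorean_noise_subtraction(self):
        sd, _ = delay_dispersion(100.0, 5.0, 50.0, 3.0, 3.0, 1.0)
        # at catastrophe sd=3=lattice -> intrinsic 0; at washout sqrt(25-9)=4
        assert sd == pytest.approx(4.0 / 100.0)

    def test_zero_intrinsic_sd(self):
        with pytest.warns(RuntimeWarning):
            sd, shrink = delay_dispersion(100.0, 2.0, 29.0, 2.0, 3.0, 0.33, v_s=40.0)
        assert sd == 0.0 and shrink == 0.0

    def test_first_order_formula_value(self):
        sd, shrink = delay_dispersion(100.0, math.sqrt(30**2 + 3**2), 29.0,
                                      math.sqrt(15**2 + 3**2), 3.0, 0.33, v_s=40.0)
        assert sd == pytest.approx(1.812, abs=0.005)
        assert shrink == pytest.approx(40.0 * sd)

    def test_monte_carlo_agreement_small_cv(self):
        # linearization is accurate when the intensity CVs are small
        rng = np.random.default_rng(42)
        I0, Icat, s0, scat, k = 100.0, 60.0, 5.0, 4.0, 0.33
        draws = -np.log(
            (Icat + scat * rng.standard_normal(200_000))
            / (I0 + s0 * rng.standard_normal(200_000))
        ) / k
        sd, _ = delay_dispersion(I0, s0, Icat, scat, 0.0, k)
        assert sd == pytest.approx(float(np.std(draws)), rel=0.03)


class TestThresholdDelays:
    def test_end_density_value(self):
        pred = delay_end_density(CONC, 0.20)
        assert pred.delay == pytest.approx(4.869, abs=2e-3)
        assert pred.shrink_length == pytest.approx(CONC.v_s * pred.delay)
        # cross-check by root finding: the terminal density is the lab-frame
        # profile evaluated at the shrinking front x0' = v_s t
        root = brentq(
            lambda t: site_density(CONC.v_s * t, t, CONC) - 0.20 * CONC.n_x0,
            0.0,
            50.0,
        )
        assert pred.delay == pytest.approx(root, abs=1e-6)

    def test_end_density_edges(self):
        assert delay_end_density(CONC, 1.0).delay == 0.0
        for bad in (0.0, 1.2, -0.1):
            with pytest.raises(ValueError):
                delay_end_density(CONC, bad)

    def test_total_number_value(self):
        pred = delay_total_number(CONC, 100.0)
        assert total_sites(0.0, CONC) == pytest.approx(284.375)
        assert pred.delay == pytest.approx(3.162, abs=2e-3)
        root = brentq(lambda t: total_sites(t, CONC) - 100.0, 0.0, 50.0)
        assert pred.delay == pytest.approx(root, abs=1e-6)

    def test_total_number_edges(self):
        N0 = total_sites(0.0, CONC)
        assert delay_total_number(CONC, N0).delay == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(ValueError):
            delay_total_number(CONC, N0 * 1.01)

    def test_model_discrimination_signature(self):
        """At fixed thresholds the total-number delay rises faster with v_g."""
        vgs = np.linspace(20.0, 80.0, 13)

        def delays(model_fn, threshold):
            out = []
            for v in vgs:
                p = KineticParams(v_g=v, v_s=0.28 * v + 22.0, k_m=0.16)
                out.append(model_fn(p, threshold).delay)
            return np.array(out)

        d_end = delays(delay_end_density, 0.20)
        d_tot = delays(delay_total_number, 50.0)
        # normalise at the slowest speed and compare growth across the range
        assert np.all(np.diff(d_tot / d_tot[0] - d_end / d_end[0]) > 0)

    def test_end_density_invariance_under_speed_changes(self):
        """The end-density delay depends on (k_cap, f_crit) only."""
        k_cap = 0.33
        delays = []
        for v_g in (15.0, 33.0, 70.0):
            for k_m in (0.1, 0.2):
                v_s = (k_cap / k_m - 1.0) * v_g
                p = KineticParams(v_g=v_g, v_s=v_s, k_m=k_m)
                assert cap_decay_rate(p) == pytest.approx(k_cap)
                delays.append(delay_end_density(p, 0.2).delay)
                # the total-number delay is NOT invariant (depends on cap length)
        assert np.ptp(delays) < 1e-12
        tot = [
            delay_total_number(
                KineticParams(v_g=v_g, v_s=(k_cap / 0.16 - 1.0) * v_g, k_m=0.16), 30.0
            ).delay
            for v_g in (15.0, 33.0, 70.0)
        ]
        assert np.ptp(tot) > 1.0


class TestWindowL:
    def test_large_L_recovers_total(self):
        assert sites_in_window(1.3, CONC, 1e9) == pytest.approx(total_sites(1.3, CONC))

    def test_window_count_value(self):
        val = sites_in_window(0.0, CONC, 80.0)
        oracle, _ = quad(lambda x: site_density(x, 0.0, CONC), 0.0, 80.0)
        assert val == pytest.approx(104.34, abs=0.05)
        assert val == pytest.approx(oracle, rel=1e-9)

    def test_small_L_density_limit(self):
        L = 1e-6
        assert sites_in_window(0.0, CONC, L) / L == pytest.approx(CONC.n_x0, rel=1e-6)

    def test_delay_limits(self):
        NL0 = sites_in_window(0.0, CONC, 80.0)
        assert delay_window_L(CONC, 80.0, NL0).delay == pytest.approx(0.0, abs=1e-12)
        big_L = 1e9
        N_crit = 100.0
        assert delay_window_L(CONC, big_L, N_crit).delay == pytest.approx(
            delay_total_number(CONC, N_crit).delay, rel=1e-9
        )

    def test_small_L_approaches_end_density(self):
        """At L = one dimer the window model collapses onto the end density."""
        L = 8.0
        for v_g in np.linspace(20.0, 80.0, 7):
            p = KineticParams(v_g=v_g, v_s=0.28 * v_g + 22.0, k_m=0.16)
            L_eff = (v_g / p.k_m) * (1.0 - math.exp(-p.k_m * L / v_g))
            f_equiv = 0.5 * sites_in_window(0.0, p, L) / (p.n_x0 * L_eff)
            d_L = delay_window_L(p, L, 0.5 * sites_in_window(0.0, p, L)).delay
            d_end = delay_end_density(p, f_equiv).delay
            assert d_L == pytest.approx(d_end, rel=0.03)

    def test_intensity_predictions(self):
        p = KineticParams(v_g=33.0, k_m=0.16)
        I_wo, I_cat = intensity_predictions(1.0, p, 80.0, 50.0)
        assert I_wo == pytest.approx(33.0)
        I_wo2, _ = intensity_predictions(1.0, KineticParams(v_g=66.0, k_m=0.16), 80.0, 50.0)
        assert I_wo2 == pytest.approx(2.0 * I_wo)
        assert I_cat == pytest.approx(15.31, abs=0.01)
        # consistency: the window count at T_L equals NL_crit, and the
        # intensity ratio at L -> inf equals NL_crit / N(0)
        T = delay_window_L(p, 80.0, 50.0).delay
        assert sites_in_window(T, p, 80.0) == pytest.approx(50.0, rel=1e-9)
        I_wo3, I_cat3 = intensity_predictions(2.0, p, 1e9, 50.0)
        assert I_cat3 / I_wo3 == pytest.approx(50.0 / total_sites(0.0, p), rel=1e-6)


class TestTwoStep:
    P2 = KineticParams(v_g=28.0, v_s=29.84, k_m=0.16, k_1=0.8)

    def test_density_at_zero(self):
        assert two_step_end_density(0.0, self.P2) == pytest.approx(1.625)

    def test_total_at_zero_printed_prefactor(self):
        # the printed prefactor is n_x0 * v_g/k_m * (1 + k_m/k_1)
        expect = 1.625 * 28.0 / 0.16 * (1.0 + 0.16 / 0.8)
        assert two_step_total(0.0, self.P2) == pytest.approx(expect, rel=1e-12)

    def test_fast_first_step_limit(self):
        p = KineticParams(v_g=28.0, v_s=29.84, k_m=0.16, k_1=160.0)
        k_cap = cap_decay_rate(p)
        for t in np.linspace(0.0, 10.0, 21):
            one_step = p.n_x0 * math.exp(-k_cap * t)
            assert two_step_end_density(t, p) == pytest.approx(one_step, rel=2e-3)

    def test_monotone_decreasing(self):
        grid = np.linspace(0.0, 20.0, 2001)
        vals = np.array([two_step_end_density(t, self.P2) for t in grid])
        assert np.all(np.diff(vals) < 0)

    def test_delay_matches_grid_scan(self):
        spec = ThresholdSpec("end_density_2step", f_crit=0.25)
        pred = delay_two_step(self.P2, spec)
        grid = np.arange(0.0, 20.0, 1e-3)
        vals = np.array([two_step_end_density(t, self.P2) for t in grid])
        t_grid = grid[np.argmax(vals <= 0.25 * self.P2.n_x0)]
        assert pred.delay == pytest.approx(t_grid, abs=2e-3)

    def test_limit_equivalence_with_one_step(self):
        p = KineticParams(v_g=28.0, v_s=29.84, k_m=0.16, k_1=160.0)
        d2 = delay_two_step(p, ThresholdSpec("end_density_2step", f_crit=0.2)).delay
        d1 = delay_end_density(p, 0.2).delay
        assert d2 == pytest.approx(d1, rel=0.01)

    def test_threshold_at_initial_value(self):
        spec = ThresholdSpec("end_density_2step", f_crit=1.0)
        assert delay_two_step(self.P2, spec).delay == 0.0

    def test_singular_rates_rejected(self):
        with pytest.raises(ValueError):
            KineticParams(v_g=28.0, v_s=29.84, k_m=0.16, k_1=0.16)


class TestInvariants:
    @given(params_strategy, st.floats(0.05, 0.95))
    @settings(max_examples=60, deadline=None)
    def test_back_substitution_end_density(self, p, f_crit):
        delay = delay_end_density(p, f_crit).delay
        assert math.exp(-cap_decay_rate(p) * delay) == pytest.approx(f_crit, rel=1e-9)

    @given(params_strategy, st.floats(0.05, 0.95))
    @settings(max_examples=60, deadline=None)
    def test_back_substitution_total_number(self, p, frac):
        N_crit = frac * total_sites(0.0, p)
        delay = delay_total_number(p, N_crit).delay
        assert total_sites(delay, p) == pytest.approx(N_crit, rel=1e-9)

    @given(params_strategy, st.floats(10.0, 500.0), st.floats(0.05, 0.95))
    @settings(max_examples=60, deadline=None)
    def test_back_substitution_window(self, p, L, frac):
        NL_crit = frac * sites_in_window(0.0, p, L)
        delay = delay_window_L(p, L, NL_crit).delay
        assert sites_in_window(delay, p, L) == pytest.approx(NL_crit, rel=1e-9)

    @given(params_strategy, st.floats(2.0, 50.0), st.floats(0.05, 0.95))
    @settings(max_examples=40, deadline=None)
    def test_two_step_back_substitution(self, p_base, ratio, frac):
        p = p_base.with_(k_1=ratio * p_base.k_m)
        spec = ThresholdSpec("end_density_2step", f_crit=frac)
        delay = delay_two_step(p, spec).delay
        assert two_step_end_density(delay, p) == pytest.approx(
            frac * p.n_x0, rel=1e-5
        )

    @given(params_strategy, st.floats(0.1, 10.0))
    @settings(max_examples=40, deadline=None)
    def test_total_sites_agrees_with_quadrature(self, p, t):
        # independent oracle: integrate the uniformly decayed lab-frame
        # profile from the shrinking front x0' = v_s t to infinity
        oracle, _ = quad(
            lambda x: p.n_x0 * math.exp(-x * p.k_m / p.v_g) * math.exp(-p.k_m * t),
            p.v_s * t,
            np.inf,
        )
        assert total_sites(t, p) == pytest.approx(oracle, rel=1e-7)
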