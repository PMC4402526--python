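"""Closed-form cycle kinetics, derived quantities and their invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ratchetkin import (
    KBT_22C,
    MMCoefficients,
    Model1Rates,
    Model2Rates,
    RatchetRates,
    bell_rate,
    coefficients_from_rates,
    occupancy,
    rates_from_coefficients,
    rupture_force,
    translocation_landscape,
    unicycle_steady_state,
    velocity_model1,
    velocity_model2,
    velocity_model3,
)
from ratchetkin.kinetics import (
    DegenerateCycleError,
    InvalidParameterError,
    model1_cycle,
    model2_cycle,
    model3_cycle,
)


class TestBellRate:
    @pytest.mark.parametrize(
        "k0, d, F, expected",
        [
            (670.0, 0.35, 0.0, 670.0),                 # zero-load identity
            (670.0, 0.35, -20.0, 120.2395858818),      # hindered forward rate
            (420.0, -0.05, -20.0, 536.8149761914),     # accelerated backward
        ],
    )
    def test_examples(self, k0, d, F, expected):
        assert bell_rate(k0, d, F, KBT_22C) == pytest.approx(expected)

    def test_log_space_consistency(self):
        # exponential force law is linear in log space
        F = np.linspace(-30, 20, 11)
        logk = np.log(bell_rate(100.0, 0.4, F))
        slopes = np.diff(logk) / np.diff(F)
        assert np.allclose(slopes, 0.4 / KBT_22C)

    @pytest.mark.parametrize("bad", [dict(k0=0.0), dict(kBT=-1.0)])
    def test_invalid_parameters(self, bad):
        kwargs = dict(k0=10.0, d=0.3, F=0.0, kBT=KBT_22C)
        kwargs.update(bad)
        with pytest.raises(InvalidParameterError):
            bell_rate(kwargs["k0"], kwargs["d"], kwargs["F"], kwargs["kBT"])


class TestVelocityModel3:
    def test_reference_conditions(self, coeffs):
        assert velocity_model3(0.0, 500.0, coeffs) == pytest.approx(
            95.057, abs=0.1)
        # 10 pN hindering load: near the measured active peak 79 +- 6 bp/s
        v10 = velocity_model3(-10.0, 500.0, coeffs)
        assert v10 == pytest.approx(77.15, abs=0.1)
        assert abs(v10 - 79.0) < 6.0

    def test_saturating_limit_is_one_over_a_plus_b(self, coeffs):
        v_inf = velocity_model3(0.0, 1e12, coeffs)
        assert v_inf == pytest.approx(1.0 / (coeffs.a + coeffs.b), rel=1e-6)

    def test_zero_dntp_gives_zero(self, coeffs):
        assert velocity_model3(0.0, 0.0, coeffs) == 0.0

    @given(F=st.floats(-40, 20), dntp=st.floats(1, 1000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, F, dntp):
        coeffs = MMCoefficients()
        v = velocity_model3(F, dntp, coeffs)
        assert v > 0
        # strictly increasing in F and in dNTP
        assert velocity_model3(F + 1.0, dntp, coeffs) > v
        assert velocity_model3(F, dntp * 1.1, coeffs) > v
        # bounded by k_cat and by the forward translocation rate
        rates = rates_from_coefficients(coeffs)
        assert v <= min(rates.k_cat, bell_rate(rates.k_T0, rates.d_T, F)) + 1e-9


class TestVelocityModel1:
    def test_vmax_is_force_independent(self):
        rates = Model1Rates(k_on0=5.0, k_off0=2.0, k_cat=120.0,
                            d_on=0.35, d_off=0.1)
        vmax = [velocity_model1(F, np.inf, rates) for F in (-30, -10, 0, 20)]
        assert np.ptp(vmax) < 1e-12 * rates.k_cat
        assert vmax[0] == pytest.approx(120.0, rel=1e-9)

    def test_scalar_evaluation(self):
        # oracle: 1/v = 1/120 + 1/(5*31) -> 67.64 nt/s
        rates = Model1Rates(k_on0=5.0, k_off0=0.0, k_cat=120.0, d_on=0.35)
        assert velocity_model1(0.0, 31.0, rates) == pytest.approx(
            67.6364, abs=1e-3)

    def test_hindering_load_slows_binding(self):
        rates = Model1Rates(k_on0=5.0, k_off0=0.0, k_cat=120.0, d_on=0.35)
        assert (velocity_model1(-20.0, 500.0, rates)
                < velocity_model1(0.0, 500.0, rates))


class TestVelocityModel2:
    RATES = Model2Rates(k_on=5.0, k_off=0.0, k_cat=120.0, k_mcat=10.0,
                        k_ppi0=1.0e4, d_ppi=0.35)

    def test_saturating_velocity(self):
        # oracle: 1/v = 1e-4 + (1/120)(1 + 1e-3) -> 118.46 nt/s
        assert velocity_model2(0.0, 1e12, self.RATES) == pytest.approx(
            118.460, abs=1e-2)

    def test_km_over_vmax_nearly_flat_when_ppi_fast(self):
        # k_mcat/k_ppi << 1 -> 1/k_b varies by < 5% over +-25 pN
        inv_kb = []
        for F in (-25.0, 0.0, 25.0):
            v = lambda C: velocity_model2(F, C, self.RATES)
            # K_M/V_max = limit of C*(1/v(C) - 1/v(inf)) as C -> inf
            inv_kb.append(1e6 * (1.0 / v(1e6) - 1.0 / v(1e12)))
        assert np.ptp(inv_kb) / np.mean(inv_kb) < 0.05

    def test_extreme_hindering_load_stalls(self):
        assert velocity_model2(-500.0, 500.0, self.RATES) < 1e-6


class TestUnicycleSteadyState:
    def test_symmetric_two_state_cycle(self):
        v, p = unicycle_steady_state([1.0, 1.0], [1.0, 1.0])
        assert v == pytest.approx(0.0, abs=1e-14)
        assert p == pytest.approx([0.5, 0.5])

    def test_rate_limiting_step_dominates(self):
        slow = 1e-3
        v, _ = unicycle_steady_state([slow, 1.0, 1.0], [0.0, 0.0, 0.0])
        assert v == pytest.approx(slow, rel=2e-3)

    def test_matches_ratchet_closed_form_at_reference(self, rates):
        f, b, _ = model3_cycle(rates, 0.0, 500.0)
        v, p = unicycle_steady_state(f, b)
        coeffs = coefficients_from_rates(rates)
        assert v == pytest.approx(velocity_model3(0.0, 500.0, coeffs),
                                  rel=1e-12)
        assert v == pytest.approx(95.45, abs=0.01)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_cycle_raises(self):
        with pytest.raises(DegenerateCycleError):
            unicycle_steady_state([0.0, 0.0], [0.0, 0.0])

    def test_oracle_equivalence_all_models(self, rng):
        """Closed forms equal the master-equation flux, 100 random sets."""
        for _ in range(100):
            F = rng.uniform(-30, 20)
            C = rng.uniform(1, 800)
            kBT = KBT_22C
            m3 = RatchetRates(
                k_on=rng.uniform(0.5, 20), k_off=rng.uniform(0, 50),
                k_cat=rng.uniform(20, 500), k_ppi=1e5,
                k_T0=rng.uniform(100, 2000), k_mT0=rng.uniform(50, 2000),
                d_T=rng.uniform(0, 0.5), d_mT=rng.uniform(0, 0.3))
            v_cycle, _ = unicycle_steady_state(*model3_cycle(m3, F, C)[:2])
            v_closed = velocity_model3(F, C, coefficients_from_rates(m3))
            assert v_cycle == pytest.approx(v_closed, rel=1e-8)

            m1 = Model1Rates(k_on0=rng.uniform(0.5, 20),
                             k_off0=rng.uniform(0, 100),
                             k_cat=rng.uniform(20, 500),
                             d_on=rng.uniform(0, 0.5),
                             d_off=rng.uniform(0, 0.3))
            v_cycle, _ = unicycle_steady_state(*model1_cycle(m1, F, C)[:2])
            assert v_cycle == pytest.approx(velocity_model1(F, C, m1),
                                            rel=1e-8)

            m2 = Model2Rates(k_on=rng.uniform(0.5, 20),
                             k_off=rng.uniform(0, 100),
                             k_cat=rng.uniform(20, 500),
                             k_mcat=rng.uniform(0, 100),
                             k_ppi0=rng.uniform(1e3, 1e5),
                             d_ppi=rng.uniform(0, 0.5))
            v_cycle, _ = unicycle_steady_state(*model2_cycle(m2, F, C)[:2])
            assert v_cycle == pytest.approx(velocity_model2(F, C, m2),
                                            rel=1e-8)


class TestCoefficientAlgebra:
    def test_published_relations(self, coeffs):
        rates = rates_from_coefficients(coeffs)
        assert rates.k_cat == pytest.approx(119.05, abs=0.01)   # ~120 1/s
        assert rates.k_T0 == pytest.approx(666.7, abs=0.1)      # ~670 1/s
        K_delta = coeffs.r / coeffs.s_coef
        assert K_delta == pytest.approx(1.583, abs=0.01)        # ~1.59
        assert -math.log(K_delta) == pytest.approx(-0.4595, abs=1e-3)

    def test_round_trip_identity(self, rng):
        for _ in range(20):
            rates = RatchetRates(
                k_on=rng.uniform(0.5, 20), k_off=rng.uniform(0, 50),
                k_cat=rng.uniform(20, 500), k_ppi=1e5,
                k_T0=rng.uniform(100, 2000), k_mT0=rng.uniform(50, 2000),
                d_T=rng.uniform(0, 0.5), d_mT=rng.uniform(0, 0.3))
            c = coefficients_from_rates(rates)
            back = rates_from_coefficients(
                c, k_off_over_kcat=rates.k_off / rates.k_cat,
                k_ppi=rates.k_ppi)
            for fld in ("k_on", "k_off", "k_cat", "k_T0", "k_mT0",
                        "d_T", "d_mT"):
                assert getattr(back, fld) == pytest.approx(
                    getattr(rates, fld), rel=1e-12, abs=1e-12)

    def test_ds_smaller_than_db_rejected(self):
        bad = MMCoefficients(d_b=0.4, d_s=0.3)
        with pytest.raises(InvalidParameterError):
            rates_from_coefficients(bad)

    def test_ds_reconstruction_exact(self, rates):
        c = coefficients_from_rates(rates)
        assert c.d_s == pytest.approx(c.d_b + rates.d_mT, abs=1e-15)


class TestOccupancy:
    def test_bound_fraction_equals_v_over_kcat(self, rates):
        from scipy.optimize import brentq

        def v_at(F):
            f, b, _ = model3_cycle(rates, F, 500.0)
            return unicycle_steady_state(f, b)[0]

        F7 = brentq(lambda F: v_at(F) - 7.0, -200, 0)
        occ = occupancy(rates, F7, 500.0)
        assert occ.M_bound == pytest.approx(7.0 / rates.k_cat, abs=1e-9)
        assert occ.M_bound == pytest.approx(0.058, abs=0.002)   # ~6 %
        assert occ.M_free == pytest.approx(0.942, abs=0.002)    # ~94 %

    def test_fractions_sum_to_one(self, rates):
        occ = occupancy(rates, -10.0, 100.0)
        assert occ.M_free + occ.M_bound == pytest.approx(1.0, abs=1e-12)
        assert sum(occ.per_state.values()) == pytest.approx(1.0, abs=1e-12)

    def test_extreme_hindering_load_empties_bound_state(self, rates):
        occ = occupancy(rates, -300.0, 500.0)
        assert occ.M_bound < 1e-6
        assert occ.per_state["pre"] > 0.999

    def test_saturating_dntp_occupancy(self, rates):
        occ = occupancy(rates, 0.0, 1e9)
        vmax = 1.0 / (1.0 / rates.k_cat + 1.0 / rates.k_T0)
        assert occ.M_bound == pytest.approx(vmax / rates.k_cat, rel=1e-6)
        assert occ.M_bound == pytest.approx(0.848, abs=0.005)


class TestLandscape:
    def test_zero_load_free_energy(self, rates):
        land = translocation_landscape(rates, 0.0)
        assert land.dG_trans == pytest.approx(-0.467, abs=0.01)  # ~-0.46 kBT
        assert land.K_delta == pytest.approx(670.0 / 420.0)
        assert land.delta == pytest.approx(0.40)

    def test_symmetric_rates_give_zero(self):
        sym = RatchetRates(k_T0=500.0, k_mT0=500.0)
        assert translocation_landscape(sym, 0.0).dG_trans == pytest.approx(
            0.0, abs=1e-14)

    def test_load_tilts_landscape_exactly(self, rates):
        land0 = translocation_landscape(rates, 0.0)
        for F in (-10.0, -25.0, 15.0):
            land = translocation_landscape(rates, F)
            # dG(F) = dG(0) - F*delta/kBT, exactly
            assert land.dG_trans == pytest.approx(
                land0.dG_trans - F * rates.delta / KBT_22C, rel=1e-12)
            # K(F)/K(0) = exp(F*delta/kBT), exactly
            assert land.K_delta / land0.K_delta == pytest.approx(
                math.exp(F * rates.delta / KBT_22C), rel=1e-12)
        land10 = translocation_landscape(rates, -10.0)
        assert land10.dG_trans == pytest.approx(0.515, abs=0.01)
        assert land10.barrier_shift == pytest.approx(10 * 0.35 / KBT_22C)


class TestRuptureForce:
    def test_saturating_dntp(self, coeffs):
        # ~50 pN at 500 uM; ~17 pN.nm of work against a 0.34 nm step
        f = rupture_force(coeffs, 500.0)
        assert f == pytest.approx(49.3, abs=0.1)
        assert f * 0.34 == pytest.approx(17.0, abs=0.5)

    def test_low_dntp(self, coeffs):
        assert rupture_force(coeffs, 10.0) == pytest.approx(22.1, abs=0.1)

    def test_monotone_in_dntp(self, coeffs):
        assert rupture_force(coeffs, 200.0) < rupture_force(coeffs, 500.0)

    def test_no_root_returns_none(self, coeffs):
        # at 2 uM the zero-load velocity is below the detachment criterion
        assert velocity_model3(0.0, 2.0, coeffs) < 7.0
        assert rupture_force(coeffs, 2.0) is None


class TestSerialization:
    def test_rates_and_coefficients_json_round_trip(self, rates, coeffs):
        assert RatchetRates.from_json(rates.to_json()) == rates
        assert MMCoefficients.from_json(coeffs.to_json()) == coeffs
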