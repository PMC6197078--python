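"""Unit and property tests for the daily-update tumor model."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import radfrac as rf
from radfrac.errors import DegeneracyError, InvalidParameterError

from naive_reference import naive_trajectory


class TestOxygenPressure:
    @pytest.mark.parametrize(
        "k, v_a, expected",
        [
            (220.0, 100.0, 100 * 120 / 220),  # patient A's initial state
            (150.0, 150.0, 0.0),  # active volume at capacity
            (100.0, 120.0, 0.0),  # capacity overshot: clamped
            (200.0, 0.0, 100.0),  # no consumers: fully oxygenated
        ],
    )
    def test_values(self, k, v_a, expected):
        assert rf.oxygen_pressure(k, v_a) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_capacity_rejected(self):
        with pytest.raises(InvalidParameterError):
            rf.oxygen_pressure(0.0, 50.0)
        with pytest.raises(InvalidParameterError):
            rf.oxygen_pressure(-10.0, 50.0)

    @given(
        k=st.floats(1e-3, 1e4, allow_nan=False),
        v_a=st.floats(0, 1e4, allow_nan=False),
    )
    def test_always_in_unit_range(self, k, v_a):
        assert 0.0 <= rf.oxygen_pressure(k, v_a) <= 100.0


class TestRadiosensitivity:
    def test_endpoints_and_midpoint(self):
        assert rf.radiosensitivity(0.0) == pytest.approx(0.001)
        assert rf.radiosensitivity(100.0) == pytest.approx(0.3)
        assert rf.radiosensitivity(50.0) == pytest.approx(0.1505)

    def test_out_of_range_rejected(self):
        for bad in (-1.0, 100.5):
            with pytest.raises(InvalidParameterError):
                rf.radiosensitivity(bad)

    @given(po2=st.floats(0, 100, allow_nan=False))
    def test_bounded_by_alpha_limits(self, po2):
        alpha = rf.radiosensitivity(po2)
        assert 0.001 <= alpha <= 0.3


class TestSurvivingFraction:
    def test_zero_dose_kills_nothing(self):
        assert rf.surviving_fraction(0.2, 1.0, 0.0, 10.0) == 1.0

    def test_standard_fraction_bounds(self):
        # at maximal and minimal radiosensitivity the standard 1.8 Gy
        # fraction brackets the intended (0.5, 1) survival window
        hi = rf.surviving_fraction(0.3, 1.0, 1.8, 10.0)
        lo = rf.surviving_fraction(0.001, 1.0, 1.8, 10.0)
        assert hi == pytest.approx(0.5287709117472098, rel=1e-12)
        assert lo == pytest.approx(0.9978782540918205, rel=1e-12)
        assert 0.5 < hi < lo < 1.0

    def test_negative_dose_rejected(self):
        with pytest.raises(InvalidParameterError):
            rf.surviving_fraction(0.2, 1.0, -1.0, 10.0)

    @given(
        alpha=st.floats(0.001, 0.3),
        d=st.floats(0.1, 4.5),
        bump=st.floats(0.01, 1.0),
    )
    def test_strictly_decreasing_in_dose_and_alpha(self, alpha, d, bump):
        base = rf.surviving_fraction(alpha, 1.0, d, 10.0)
        assert rf.surviving_fraction(alpha, 1.0, d + bump, 10.0) < base
        assert rf.surviving_fraction(alpha + bump, 1.0, d, 10.0) < base
        assert 0.0 < base < 1.0


class TestNecroticVolume:
    def test_single_cohort_halves_after_one_half_time(self):
        state = rf.TumorState(t=7, v_a=50.0, k=200.0,
                              cohorts=(rf.NecroticCohort(0, 10.0),))
        assert rf.necrotic_volume(state, t_half=7.0, law="exponential") == pytest.approx(5.0)

    def test_no_cohorts_means_zero(self):
        state = rf.TumorState(t=5, v_a=50.0, k=200.0)
        assert rf.necrotic_volume(state, 10.0) == 0.0

    def test_term_by_term_sum(self):
        state = rf.TumorState(
            t=4, v_a=50.0, k=200.0,
            cohorts=(rf.NecroticCohort(0, 10.0), rf.NecroticCohort(2, 4.0)),
        )
        # 10 * 2^-2 + 4 * 2^-1
        assert rf.necrotic_volume(state, 2.0, law="exponential") == pytest.approx(4.5)

    def test_compound_weight_matches_daily_reapplication(self):
        # the closed form must equal literally multiplying the cohort by
        # the elapsed-lag factor on every day since creation
        t_half = 9.0
        for lag in range(0, 25):
            value = 1.0
            for age in range(1, lag + 1):
                value *= 2.0 ** (-age / t_half)
            assert rf.clearance_weight(lag, t_half, "compound") == pytest.approx(
                value, rel=1e-12
            )

    def test_compound_decays_faster_than_exponential(self):
        for lag in range(2, 30):
            assert rf.clearance_weight(lag, 14.0, "compound") < rf.clearance_weight(
                lag, 14.0, "exponential"
            )


class TestStep:
    def test_single_step_hand_values(self, patient_a):
        """First treated day of patient A against a hand calculation."""
        state = rf.initial_state(patient_a)
        new = rf.step(state, 1.8, patient_a)
        assert new.t == 1
        assert new.v_a == pytest.approx(80.03192280834672, rel=1e-12)
        assert new.k == pytest.approx(143.78281185143152, rel=1e-12)
        assert len(new.cohorts) == 1
        assert new.cohorts[0].t_i == 0
        assert new.cohorts[0].v0 == pytest.approx(29.42746154677003, rel=1e-12)

    def test_rest_day_with_zero_growth_changes_nothing(self):
        params = rf.PatientParameters("still", rho=1e-12, t_half=10.0,
                                      k_hat=200.0, gamma_v=0.5)
        state = rf.TumorState(t=3, v_a=80.0, k=200.0,
                              cohorts=(rf.NecroticCohort(1, 5.0),))
        new = rf.step(state, None, params)
        assert new.v_a == pytest.approx(80.0, rel=1e-12)
        assert new.k == 200.0
        assert new.cohorts == state.cohorts  # cohorts decay lazily, not in place

    def test_gompertz_fixed_point(self, patient_a):
        state = rf.TumorState(t=0, v_a=220.0, k=220.0)
        new = rf.step(state, None, patient_a)
        assert new.v_a == pytest.approx(220.0, rel=1e-12)

    def test_degenerate_kill_names_the_day(self, patient_a):
        state = rf.TumorState(t=4, v_a=100.0, k=220.0)
        with pytest.raises(DegeneracyError) as err:
            rf.step(state, 1e6, patient_a)  # absurd dose underflows SF to 0
        assert err.value.day == 5
        assert "day 5" in str(err.value)


class TestSimulate:
    def test_record_count_and_day_zero(self, patient_a):
        sched = rf.constant_schedule(1.8)
        res = rf.simulate(patient_a, sched)
        assert res.t_e == sched.last_day + 1
        assert len(res.frame) == res.t_e + 1
        first = res.frame.iloc[0]
        assert first["day"] == 0 and first["V_a"] == 100.0 and first["V_n"] == 0.0

    def test_trajectory_positivity_across_cohort_and_doses(self, cohort):
        for params in cohort:
            for build in (
                lambda: rf.constant_schedule(3.0),
                lambda: rf.ramp_schedule(direction="decreasing"),  # includes 4.5 Gy
            ):
                frame = rf.simulate(params, build()).frame
                assert (frame["V_a"] > 0).all()
                assert (frame["V_n"] >= 0).all()
                assert (frame["k"] > 0).all()

    def test_no_treatment_grows_monotonically_toward_capacity(self, patient_b):
        # an all-rest course: single far-future fraction, horizon before it
        sched = rf.FractionationSchedule(fractions=((500, 1.0),), label="idle")
        res = rf.simulate(patient_b, sched, horizon=120)
        v_a = res.frame["V_a"].to_numpy()
        gaps = np.abs(v_a - patient_b.k_hat)
        assert (np.diff(v_a) > 0).all()
        assert (np.diff(gaps) < 0).all()
        assert (res.frame["V_n"] == 0).all()
        assert (res.frame["k"] == patient_b.k_hat).all()

    def test_agrees_with_naive_oracle_everywhere(self, cohort):
        """Machine-precision agreement with an independent recomputation."""
        for params in cohort:
            for sched in (rf.constant_schedule(1.8), rf.ramp_schedule()):
                res = rf.simulate(params, sched)
                vas, vns, vts, ks = naive_trajectory(
                    params.rho, params.t_half, params.k_hat, params.gamma_v,
                    sched.fractions, res.t_e,
                )
                frame = res.frame
                np.testing.assert_allclose(frame["V_a"], vas, rtol=1e-12)
                np.testing.assert_allclose(frame["V_n"], vns, rtol=1e-12, atol=1e-15)
                np.testing.assert_allclose(frame["V_t"], vts, rtol=1e-12)
                np.testing.assert_allclose(frame["k"], ks, rtol=1e-12)

    def test_exponential_clearance_matches_oracle_too(self, patient_b):
        opts = rf.ModelOptions(clearance="exponential")
        sched = rf.constant_schedule(2.0)
        res = rf.simulate(patient_b, sched, options=opts)
        _, vns, _, _ = naive_trajectory(
            patient_b.rho, patient_b.t_half, patient_b.k_hat, patient_b.gamma_v,
            sched.fractions, res.t_e, clearance="exponential",
        )
        np.testing.assert_allclose(res.frame["V_n"], vns, rtol=1e-12, atol=1e-15)

    def test_mass_conserving_option_conserves_within_day(self, patient_a):
        opts = rf.ModelOptions(mass_conserving=True)
        state = rf.initial_state(patient_a)
        new = rf.step(state, 2.0, patient_a, options=opts)
        grown = state.v_a * (1 + patient_a.rho * math.log(state.k / state.v_a))
        assert new.v_a + new.cohorts[0].v0 == pytest.approx(grown, rel=1e-12)

    @pytest.mark.parametrize("d_lo, d_hi", [(1.0, 1.5), (1.8, 2.5), (2.0, 3.0)])
    def test_higher_dose_lower_active_volume_daily(self, patient_b, d_lo, d_hi):
        """For equal fraction counts, more dose per fraction kills more,
        on every single day of the course."""
        n = 15
        days = [(i // 5) * 7 + i % 5 for i in range(n)]
        lo = rf.FractionationSchedule(tuple((t, d_lo) for t in days))
        hi = rf.FractionationSchedule(tuple((t, d_hi) for t in days))
        va_lo = rf.simulate(patient_b, lo).frame["V_a"].to_numpy()
        va_hi = rf.simulate(patient_b, hi).frame["V_a"].to_numpy()
        assert (va_hi[1:] < va_lo[1:]).all()

    def test_horizon_extends_past_course(self, patient_b):
        sched = rf.constant_schedule(3.0)
        res = rf.simulate(patient_b, sched, horizon=60)
        assert res.t_e == 60 and len(res.frame) == 61


class TestParameterValidation:
    def test_bounds_check_strict_and_relaxed(self):
        wild = rf.PatientParameters("wild", rho=0.5, t_half=50.0, k_hat=400.0,
                                    gamma_v=1.5)
        with pytest.raises(InvalidParameterError):
            wild.check_bounds(strict=True)
        msgs = wild.check_bounds(strict=False)
        assert len(msgs) == 4

    def test_nonpositive_parameters_rejected_outright(self):
        with pytest.raises(InvalidParameterError):
            rf.PatientParameters("bad", rho=-0.1, t_half=10.0, k_hat=200.0, gamma_v=0.5)
        with pytest.raises(InvalidParameterError):
            rf.PatientParameters("bad", rho=0.1, t_half=0.0, k_hat=200.0, gamma_v=0.5)

    def test_constants_invariants(self):
        with pytest.raises(InvalidParameterError):
            rf.ModelConstants(alpha_min=0.5, alpha_max=0.3)
        with pytest.raises(InvalidParameterError):
            rf.ModelConstants(gamma_tumor=0.8)
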