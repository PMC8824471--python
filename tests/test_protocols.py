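"""The protocol battery: anchors, monotonicity and paradigm behavior.

Protocol runs are deterministic, so curves computed once per session
(module-scoped fixtures) are asserted against repeatedly.
"""

import numpy as np
import pytest

import navresurge as nv


@pytest.fixture(scope="module")
def availability(wt_model):
    return nv.availability_curve(wt_model)


@pytest.fixture(scope="module")
def activation(wt_model):
    return nv.activation_curve(wt_model)


@pytest.fixture(scope="module")
def duration(wt_model):
    return nv.duration_dependence(wt_model)


@pytest.fixture(scope="module")
def ratio_curve(wt_model):
    return nv.resurgent_ratio_curve(wt_model)


class TestAvailability:
    def test_normalization_anchor(self, availability):
        assert availability.y[0] == 1.0
        assert availability.x[0] == -120.0

    def test_decreasing_over_the_inactivating_range(self, availability):
        """Availability falls monotonically with depolarized conditioning.

        Below about -80 mV the curve is flat near 1 with a small (<5%)
        non-monotonic ripple from the interplay of closed-state
        distribution and activation speed; the inactivating limb is
        strictly decreasing.
        """
        limb = availability.y[availability.x >= -75.0]
        assert np.all(np.diff(limb) < 0)
        assert availability.y.max() <= 1.05

    def test_boltzmann_fit_converges(self, availability):
        fit = nv.fit_boltzmann(availability.x, np.clip(availability.y, 0.0, 1.05))
        assert fit.slope_mV < 0  # falling with depolarization
        assert -80.0 < fit.v_half_mV < -40.0


class TestActivation:
    def test_normalization_anchor(self, activation):
        assert activation.y[-1] == 1.0
        assert activation.x[-1] == 0.0

    def test_monotone_rising_to_saturation(self, activation):
        """Rising limb is strictly monotone; near 0 mV the peak open
        probability saturates with a slight (<5%) droop."""
        rising = activation.y[activation.x <= -15.0]
        assert np.all(np.diff(rising) > 0)
        assert activation.y.max() <= 1.05

    def test_boltzmann_fit_converges(self, activation):
        fit = nv.fit_boltzmann(activation.x, np.clip(activation.y, 0.0, 1.05))
        assert fit.slope_mV > 0


class TestInactivationTau:
    def test_taus_finite_positive_and_speeding_with_depolarization(self, wt_model):
        curve = nv.inactivation_tau_curve(wt_model)
        assert len(curve.x) == 11  # every voltage in -50..0 produced a tau
        assert np.all(curve.y > 0)
        assert np.all(np.isfinite(curve.y))
        assert np.all(np.diff(curve.y) < 0)  # faster decay toward 0 mV


class TestRecovery:
    def test_monotone_and_complete(self, wt_model):
        curve = nv.recovery_curve(wt_model)
        # strictly rising until complete; numerically flat (to ~1e-4) after
        assert np.all(np.diff(curve.y[curve.x <= 20.0]) > 0)
        assert np.all(np.diff(curve.y) > -1e-4)
        assert curve.y[-1] == pytest.approx(1.0, abs=0.02)  # full by 500 ms
        near20 = curve.y[np.argmin(np.abs(curve.x - 20.0))]
        assert near20 > 0.9  # nearly complete recovery by ~20 ms


class TestPersistentFraction:
    def test_small_positive_fraction(self, wt_model):
        value = nv.persistent_fraction(wt_model)
        assert 0.0 < value < 1.0
        assert value < 0.2  # persistent is a small fraction of the transient

    def test_independent_of_conductance_scale(self, wt_params):
        model = nv.NavModel(wt_params)
        v1 = nv.persistent_fraction(model, nv.CurrentModel(g_max=1.0))
        v2 = nv.persistent_fraction(model, nv.CurrentModel(g_max=7.3))
        assert v1 == pytest.approx(v2, rel=1e-12)


class TestResurgentRatio:
    def test_peak_ratio_at_minus_45(self, ratio_curve):
        assert ratio_curve.x[np.argmax(ratio_curve.y)] == -45.0

    def test_ratios_below_one(self, ratio_curve):
        assert np.all(ratio_curve.y < 1.0)
        assert np.all(ratio_curve.y > 0.0)

    def test_small_at_deep_hyperpolarization(self, ratio_curve):
        """At -80 mV closed-state recovery dominates and the resurgent
        component is much smaller than at its -45 mV peak."""
        y80 = ratio_curve.y[ratio_curve.x == -80.0][0]
        assert y80 < 0.5 * ratio_curve.y.max()


class TestDurationDependence:
    def test_normalization_anchor(self, duration):
        assert duration.x[0] == 2.0
        assert duration.y[0] == 1.0
        assert len(duration.x) == 18  # 2..36 ms in 2 ms steps

    def test_strictly_decreasing(self, duration):
        assert np.all(np.diff(duration.y) < 0)

    def test_single_exponential_fit(self, duration):
        fit = nv.fit_single_exponential(duration.x, duration.y, with_offset=True)
        assert fit.tau_ms > 0
        assert fit.residual_sse < 1e-3


class TestResurgentDecayTaus:
    def test_taus_slower_than_transient(self, wt_model):
        inar = nv.resurgent_decay_taus(wt_model)
        inat = nv.inactivation_tau_curve(wt_model)
        assert len(inar.x) == 9  # -45..-5 in 5 mV steps, none excluded
        assert np.all(inar.y > 0) and np.all(np.isfinite(inar.y))
        # resurgent decay is slower than transient decay at every
        # comparable voltage
        for v, tau in zip(inar.x, inar.y):
            match = inat.y[inat.x == v]
            if len(match):
                assert tau > match[0]
        assert inar.y.max() > 5.0  # tens of ms at the slow end


class TestPrepulseIndependence:
    def test_cv_below_two_percent(self, wt_model):
        curve, cv = nv.prepulse_peak_spread(wt_model)
        assert cv < 0.02
        assert np.all(curve.y > 0)

    def test_near_constant_with_positive_prepulse(self, wt_model):
        voltages = tuple(np.arange(-35.0, -4.0, 5.0)) + (10.0,)
        curve, cv = nv.prepulse_peak_spread(wt_model, prepulse_mV=voltages)
        assert cv < 0.05


class TestSequentialRecovery:
    def test_ratios_nearly_equal(self, wt_model):
        """The single-population model recovers the transient and resurgent
        components together: the two ratios come out nearly equal (the
        experimentally observed differential recovery is not reproduced)."""
        rel_inat, rel_inar = nv.sequential_recovery(wt_model)
        assert rel_inat == pytest.approx(rel_inar, abs=0.05)
        assert 0.0 < rel_inat <= 1.01
        assert 0.0 < rel_inar <= 1.01
        assert rel_inat > 0.9  # near-complete transient recovery in 20 ms


class TestEnvelope:
    def test_envelope_superposition(self, wt_model):
        """Peaks of repetitive brief repolarizations trace the sustained
        resurgent decay; the early repetitions match closely and the
        envelope decays monotonically."""
        sustained, repetitive, deviation = nv.envelope_comparison(wt_model)
        assert deviation < 0.10
        # repetitive peaks decay monotonically, like the sustained current
        peaks = []
        for seg in range(1, len(repetitive.segment_bounds), 2):
            amp, _ = nv.measure_peak(repetitive, repetitive.segment_window(seg))
            peaks.append(abs(amp))
        assert np.all(np.diff(peaks) < 0)

    def test_slow_inactivation_accumulates_under_both_protocols(self, wt_model):
        sustained, repetitive, _ = nv.envelope_comparison(wt_model)
        i_is = sustained.states.index("IS")
        assert sustained.occupancies[-1, i_is] > 0.3
        assert repetitive.occupancies[-1, i_is] == pytest.approx(
            sustained.occupancies[-1, i_is], rel=0.35)


@pytest.fixture(scope="module")
def up(wt_model):
    return nv.ramp_current(wt_model, direction="up")


@pytest.fixture(scope="module")
def down(wt_model):
    return nv.ramp_current(wt_model, direction="down")


class TestRamps:
    def test_current_vanishes_at_hyperpolarized_end(self, up):
        assert abs(up.y[0]) < 0.1 * np.abs(up.y).max()

    def test_up_ramp_is_quasi_steady_persistent(self, wt_model, up):
        """The slow depolarizing ramp tracks the instantaneous steady-state
        open probability (only the persistent component)."""
        v_test = -45.0
        i_ramp = float(np.interp(v_test, up.x, up.y))
        ss = nv.steady_state(wt_model, v_test)
        i_ss = ss["O"] * (v_test - 75.0)
        assert i_ramp == pytest.approx(i_ss, rel=0.35)

    def test_up_and_down_ramps_overlap(self, up, down):
        x_dn = down.x[::-1]
        y_dn = down.y[::-1]
        y_dn_on_up = np.interp(up.x, x_dn, y_dn)
        scale = np.abs(up.y).max()
        mask = np.abs(up.y) > 0.1 * scale
        rel = np.abs(up.y[mask] - y_dn_on_up[mask]) / scale
        assert rel.max() < 0.25

    def test_invalid_direction_rejected(self, wt_model):
        with pytest.raises(ValueError):
            nv.ramp_current(wt_model, direction="sideways")


class TestDeterminism:
    def test_summary_curves_bitwise_reproducible(self, wt_model):
        c1 = nv.duration_dependence(wt_model, durations_ms=(2.0, 10.0, 20.0))
        c2 = nv.duration_dependence(wt_model, durations_ms=(2.0, 10.0, 20.0))
        assert np.array_equal(c1.y, c2.y)
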