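"""Unit and property tests for the short-term-plasticity closed forms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synwm.stp import (
    EfficacyVariant,
    STPParams,
    STPState,
    alpha_factor,
    modulated_efficacy,
    psp_peak_time,
    stp_decay,
    stp_fixed_point,
    stp_spike_update,
)
from synwm.neuron import NeuronParams


DEFAULT = STPParams(U=0.19, tau_f=1500.0, tau_d=200.0)


def euler_stp(params, spike_times, t_end, dt=1e-3):
    """Dense Euler integration of the facilitation/depression ODEs.

    Independent oracle for the event-driven closed form: integrates
    du/dt = -(u-U)/tau_f, dx/dt = (1-x)/tau_d between spikes and applies
    the jump maps at spikes.  Returns (u, x) right-limits at t_end.
    """
    u, x = params.U, 1.0
    t = 0.0
    spikes = iter(list(spike_times) + [float("inf")])
    next_spike = next(spikes)
    while t < t_end - 1e-12:
        step = min(dt, t_end - t, next_spike - t)
        u += -(u - params.U) / params.tau_f * step
        x += (1.0 - x) / params.tau_d * step
        t += step
        if abs(t - next_spike) < 1e-12:
            u = u + params.U * (1.0 - u)
            x = x - u * x
            next_spike = next(spikes)
    return u, x


class TestDecay:
    def test_zero_interval_is_identity(self):
        s = STPState(u=0.5, x=0.3, t_last=10.0)
        u, x = stp_decay(s, 10.0, DEFAULT)
        assert u == pytest.approx(0.5, abs=1e-15)
        assert x == pytest.approx(0.3, abs=1e-15)

    def test_infinite_interval_recovers_baseline(self):
        s = STPState(u=0.9, x=0.1, t_last=0.0)
        u, x = stp_decay(s, 1e9, DEFAULT)
        assert u == pytest.approx(DEFAULT.U, abs=1e-12)
        assert x == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_after_one_facilitation_time(self):
        # one spike from rest, then decay tau_f = 1500 ms
        s = STPState(u=0.3439, x=0.6561, t_last=0.0)
        u, x = stp_decay(s, 1500.0, DEFAULT)
        assert u == pytest.approx(0.19 + 0.1539 * math.exp(-1.0), rel=1e-6)
        assert x == pytest.approx(1.0 - 0.3439 * math.exp(-7.5), rel=1e-6)
        assert u == pytest.approx(0.24662, abs=5e-6)
        assert x == pytest.approx(0.99981, abs=5e-6)

    def test_causality_error(self):
        s = STPState(u=0.3, x=0.9, t_last=100.0)
        with pytest.raises(ValueError, match="causality"):
            stp_decay(s, 99.0, DEFAULT)


class TestSpikeUpdate:
    def test_first_spike_from_rest(self):
        u, x = stp_spike_update(0.19, 1.0, DEFAULT)
        assert u == pytest.approx(0.3439, abs=1e-12)
        assert x == pytest.approx(0.6561, abs=1e-12)

    def test_full_utilization_saturates(self):
        p = STPParams(U=1.0, tau_f=100.0, tau_d=100.0)
        for u_minus in (0.0, 0.4, 1.0):
            u, _ = stp_spike_update(u_minus, 0.5, p)
            assert u == pytest.approx(1.0)

    def test_depleted_resources_stay_depleted(self):
        _, x = stp_spike_update(0.5, 0.0, DEFAULT)
        assert x == 0.0


class TestModulatedEfficacy:
    def test_first_spike_post_u(self):
        s = STPState.resting(DEFAULT)
        J, s2 = modulated_efficacy(0.45, s, 0.0, DEFAULT, EfficacyVariant.POST_U)
        assert J == pytest.approx(0.45 * 0.3439, abs=1e-10)
        assert (s2.u, s2.x) == (pytest.approx(0.3439), pytest.approx(0.6561))

    def test_first_spike_pre_u(self):
        s = STPState.resting(DEFAULT)
        J, _ = modulated_efficacy(0.45, s, 0.0, DEFAULT, EfficacyVariant.PRE_U)
        assert J == pytest.approx(0.45 * 0.19, abs=1e-10)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.5, 200.0), min_size=1, max_size=30),
           st.floats(0.05, 0.95))
    def test_post_u_never_below_pre_u(self, isis, U):
        """Modulating with the freshly incremented utilization always yields
        at least the efficacy of the pre-spike convention."""
        p = STPParams(U=U, tau_f=1500.0, tau_d=200.0)
        sp = STPState.resting(p)
        sq = STPState.resting(p)
        t = 0.0
        for isi in isis:
            t += isi
            Jp, sp = modulated_efficacy(1.0, sp, t, p, EfficacyVariant.POST_U)
            Jq, sq = modulated_efficacy(1.0, sq, t, p, EfficacyVariant.PRE_U)
            assert Jp >= Jq - 1e-12
        # the two variants advance the state identically
        assert sp.u == pytest.approx(sq.u) and sp.x == pytest.approx(sq.x)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_state_bounds_on_random_trains(self, seed):
        """u stays in [U, 1] and x in [0, 1] at all pre/post points."""
        rng = np.random.default_rng(seed)
        p = STPParams(U=float(rng.uniform(0.05, 0.9)),
                      tau_f=float(rng.uniform(50, 3000)),
                      tau_d=float(rng.uniform(50, 3000)))
        s = STPState.resting(p)
        t = 0.0
        for isi in rng.exponential(100.0, size=40):
            t += isi
            um, xm = stp_decay(s, t, p)
            assert p.U - 1e-12 <= um <= 1.0 + 1e-12
            assert 0.0 <= xm <= 1.0 + 1e-12
            _, s = modulated_efficacy(1.0, s, t, p)
            assert p.U - 1e-12 <= s.u <= 1.0 + 1e-12
            assert 0.0 <= s.x <= 1.0 + 1e-12


class TestEulerOracle:
    @pytest.mark.parametrize("rate_hz,seed", [(1, 0), (10, 1), (50, 2)])
    def test_closed_form_matches_dense_euler(self, rate_hz, seed):
        """Event-driven updates agree with dt=1e-3 ms Euler integration of
        the continuous dynamics on Poisson trains."""
        rng = np.random.default_rng(seed)
        t_end = 400.0
        n = rng.poisson(rate_hz * t_end / 1000.0)
        times = np.sort(rng.uniform(1.0, t_end - 1.0, size=n))
        u_e, x_e = euler_stp(DEFAULT, times, t_end)
        s = STPState.resting(DEFAULT)
        for t in times:
            _, s = modulated_efficacy(1.0, s, float(t), DEFAULT)
        u_c, x_c = stp_decay(s, t_end, DEFAULT)
        assert u_c == pytest.approx(u_e, abs=1e-5)
        assert x_c == pytest.approx(x_e, abs=1e-5)

    def test_facilitation_dominance_at_low_rate(self):
        """With tau_f >> tau_d and small U, the steady-state efficacy under
        a 10 Hz periodic train exceeds the first-spike efficacy."""
        u_star, x_star = stp_fixed_point(DEFAULT, 100.0)
        first = 0.3439 * 1.0
        assert u_star * x_star > first


class TestFixedPoint:
    def test_long_isi_limit(self):
        u, x = stp_fixed_point(DEFAULT, 1e9)
        assert u == pytest.approx(DEFAULT.U * (2 - DEFAULT.U), rel=1e-9)
        assert x == pytest.approx(1.0, rel=1e-9)

    def test_saturated_utilization(self):
        p = STPParams(U=1.0, tau_f=100.0, tau_d=100.0)
        u, _ = stp_fixed_point(p, 37.0)
        assert u == pytest.approx(1.0)

    @pytest.mark.parametrize("isi", [10.0, 100.0, 700.0])
    def test_matches_brute_force_iteration(self, isi):
        u_star, x_star = stp_fixed_point(DEFAULT, isi)
        s = STPState(u=0.7, x=0.2, t_last=0.0)
        t = 0.0
        for _ in range(10_000):
            t += isi
            um, xm = stp_decay(s, t, DEFAULT)
            up, xp = stp_spike_update(um, xm, DEFAULT)
            s = STPState(u=up, x=xp, t_last=t)
        # compare post-spike u and pre-spike x on the cycle
        assert s.u == pytest.approx(u_star, abs=1e-12)
        assert xm == pytest.approx(x_star, abs=1e-12)


class TestAlphaFactor:
    def test_peak_time_closed_form(self):
        assert psp_peak_time(15.0, 2.0) == pytest.approx(
            (30.0 / 13.0) * math.log(7.5), rel=1e-12
        )
        assert psp_peak_time(15.0, 2.0) == pytest.approx(4.650, abs=1e-3)

    def test_unit_psp_contract_by_simulation(self):
        """A J=1 mV spike through the alpha-scaled current jump peaks at
        exactly 1 mV on a fine grid."""
        from synwm.neuron import NeuronState, make_propagator, step_neuron

        params = NeuronParams(tau_m=15.0, V_th=1e9, V_reset=-1.0)
        a = alpha_factor(params, params.tau_exc)
        dt = 0.001
        prop = make_propagator(params, dt)
        st_ = NeuronState(I_exc=a * 1.0 / params.tau_exc)
        vmax, t = 0.0, 0.0
        for _ in range(int(12.0 / dt)):
            st_, _ = step_neuron(st_, prop, 0.0, params, t)
            t += dt
            vmax = max(vmax, st_.V)
        assert vmax == pytest.approx(1.0, abs=1e-4)

    def test_scales_inversely_with_membrane_resistance(self):
        lo = alpha_factor(NeuronParams(R_m=1.0), 2.0)
        hi = alpha_factor(NeuronParams(R_m=0.5), 2.0)
        assert hi == pytest.approx(2.0 * lo, rel=1e-12)

    def test_degenerate_equal_time_constants(self):
        params = NeuronParams(tau_m=2.0, tau_exc=2.0, V_th=1e9, V_reset=-1.0)
        a = alpha_factor(params, 2.0)
        assert a == pytest.approx(2.0 * math.e, rel=1e-12)
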