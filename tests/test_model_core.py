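"""Unit tests for the four dynamical components and the stepping core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from laminarcortex import (ConnectionMap, InstabilityError, LaminarCortexModel,
                           ModelParams, ParameterError, aggregate_membrane,
                           conduction_delay, firing_rate, psp_kernel)
from laminarcortex.connectome import Connection
from laminarcortex.model import lateral_kernel
from laminarcortex.stimulus import StimulusFields


# ---------------------------------------------------------------------------
# spike generation
# ---------------------------------------------------------------------------

class TestFiringRate:
    def test_midpoint_at_threshold(self, tiny_params):
        assert firing_rate(tiny_params.sigmoid_theta, tiny_params) == \
            pytest.approx(tiny_params.sigmoid_qmax / 2)

    def test_asymptotes(self, tiny_params):
        assert firing_rate(-1e3, tiny_params) == pytest.approx(0.0, abs=1e-12)
        assert firing_rate(1e3, tiny_params) == pytest.approx(
            tiny_params.sigmoid_qmax)

    def test_monotone_and_bounded_over_sampled_pairs(self, tiny_params, rng):
        v = np.sort(rng.uniform(-120, 20, size=200))
        q = firing_rate(v, tiny_params)
        assert np.all(np.diff(q) > 0)
        assert np.all(q >= 0) and np.all(q <= tiny_params.sigmoid_qmax)

    def test_non_finite_potential_raises(self, tiny_params):
        with pytest.raises(InstabilityError):
            firing_rate(np.array([0.0, np.nan]), tiny_params)


# ---------------------------------------------------------------------------
# conduction delays
# ---------------------------------------------------------------------------

class TestConductionDelay:
    def test_zero_distance_floors_at_one_step(self, tiny_params):
        assert conduction_delay((0, 2, 2), (0, 2, 2), tiny_params) == 1

    def test_lateral_delay_from_speed(self):
        # 0.48 mm at 0.24 m/s = 2 ms -> 2 steps
        p = ModelParams(grid_n=9, element_spacing=0.48)
        assert conduction_delay((0, 0, 0), (0, 0, 1), p) == 2

    def test_vertical_delay_from_interlaminar_speed(self):
        # 0.288 mm at 1.2 x 0.24 = 0.288 m/s = 1 ms -> 1 step
        p = ModelParams(grid_n=5, layer_spacing=0.288)
        assert conduction_delay((0, 2, 2), (1, 2, 2), p) == 1

    def test_lateral_distance_wraps_on_torus(self):
        p = ModelParams(grid_n=10)
        near = conduction_delay((0, 0, 0), (0, 0, 1), p)
        wrapped = conduction_delay((0, 0, 0), (0, 0, 9), p)
        assert near == wrapped


# ---------------------------------------------------------------------------
# PSP kernel
# ---------------------------------------------------------------------------

class TestPspKernel:
    def test_causal_zero_at_and_before_onset(self):
        t = np.array([-5.0, -1.0, 0.0])
        assert np.all(psp_kernel(t, 1.0, 10.0, 2.0) == 0.0)

    def test_peak_equals_gain(self):
        t = np.linspace(0, 200, 200001)
        k = psp_kernel(t, 1.0, 10.0, 3.5e-4)
        assert k.max() == pytest.approx(3.5e-4, rel=1e-6)

    def test_unimodal_nonnegative_and_decaying(self):
        t = np.linspace(0, 150, 1501)
        k = psp_kernel(t, 2.0, 20.0, 1.0)
        assert np.all(k >= 0)
        peak = int(np.argmax(k))
        assert np.all(np.diff(k[:peak + 1]) >= 0)
        assert np.all(np.diff(k[peak:]) <= 0)
        assert k[-1] < 1e-3 * k.max()

    def test_rise_must_be_below_decay(self):
        with pytest.raises(ParameterError):
            psp_kernel(1.0, 10.0, 10.0, 1.0)


# ---------------------------------------------------------------------------
# membrane aggregation
# ---------------------------------------------------------------------------

class TestAggregateMembrane:
    def test_rest_is_fixed_point_of_zero_drive(self):
        v = aggregate_membrane(-64.0, 0.0, rest=-64.0, tau_m=15.0, dt=1.0)
        assert v == -64.0

    def test_exponential_decay_matches_closed_form(self):
        # start 1 mV above rest, free decay for one time constant
        tau = 15.0
        v = -63.0
        for _ in range(15):
            v = aggregate_membrane(v, 0.0, rest=-64.0, tau_m=tau, dt=1.0)
        assert v - (-64.0) == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_constant_drive_reaches_rest_plus_drive(self):
        v = -64.0
        for _ in range(150):  # 10 time constants
            v = aggregate_membrane(v, 3.0, rest=-64.0, tau_m=15.0, dt=1.0)
        assert v == pytest.approx(-61.0, rel=1e-2)

    @settings(max_examples=30, deadline=None)
    @given(drive=st.floats(-20, 20), v0=st.floats(-80, -50))
    def test_relaxation_is_contraction_toward_target(self, drive, v0):
        target = -64.0 + drive
        v1 = aggregate_membrane(v0, drive, rest=-64.0, tau_m=15.0, dt=1.0)
        assert abs(v1 - target) <= abs(v0 - target)


# ---------------------------------------------------------------------------
# lateral kernel
# ---------------------------------------------------------------------------

class TestLateralKernel:
    def test_unit_sum_and_distance_decay(self, tiny_params):
        w, d = lateral_kernel(tiny_params, 0)
        assert w.sum() == pytest.approx(1.0)
        assert w[0, 0] == w.max()          # self-offset carries largest weight
        assert np.all(d >= 1)

    def test_inhibitory_kernel_is_narrower(self):
        p = ModelParams(grid_n=15)
        w_e, _ = lateral_kernel(p, 0)
        w_i, _ = lateral_kernel(p, 1)
        # fraction of weight on the self element is larger for the short-range kind
        assert w_i[0, 0] > w_e[0, 0]

    def test_cutoff_at_three_ranges(self):
        p = ModelParams(grid_n=31, range_e=1.0, element_spacing=0.5)
        w, _ = lateral_kernel(p, 0)
        # 3 x 1.0 mm = 6 elements; offsets beyond that carry no weight
        assert w[0, 7] == 0.0 and w[0, 6] > 0.0


# ---------------------------------------------------------------------------
# stepping core
# ---------------------------------------------------------------------------

def _silent_stimuli(n_steps):
    return StimulusFields(np.zeros(n_steps), np.zeros(n_steps))


def _uniform_map(count_ee=10.0):
    """Minimal map: within-layer E->E everywhere, nothing else."""
    entries = [Connection(l, "E", l, "E", count_ee, "intracortical")
               for l in ("I", "II/III", "IV", "V", "VI")]
    return ConnectionMap(entries)


class TestStep:
    def test_zero_gain_system_stays_at_rest(self, tiny_params):
        p = tiny_params.replace(gain_e=0.0, gain_i=0.0)
        model = LaminarCortexModel(p)
        state = model.initial_state()
        stim = _silent_stimuli(50)
        for _ in range(50):
            state = model.step(state, stim)
        assert np.allclose(state.membrane_potential[:, 0], p.resting_potential_e)
        assert np.allclose(state.membrane_potential[:, 1], p.resting_potential_i)

    def test_step_is_deterministic(self, tiny_params):
        model = LaminarCortexModel(tiny_params)
        stim = _silent_stimuli(30)
        s1, s2 = model.initial_state(), model.initial_state()
        for _ in range(30):
            s1 = model.step(s1, stim)
            s2 = model.step(s2, stim)
        assert np.array_equal(s1.membrane_potential, s2.membrane_potential)

    def test_network_equilibrium_is_invariant_under_step(self, tiny_params):
        # With zero external input the network settles to a self-consistent
        # equilibrium; once there, a step leaves the state unchanged.
        model = LaminarCortexModel(tiny_params)
        state = model.initial_state()
        stim = _silent_stimuli(3000)
        for _ in range(2500):
            state = model.step(state, stim)
        before = state.membrane_potential.copy()
        state = model.step(state, stim)
        assert np.allclose(state.membrane_potential, before, atol=1e-9)

    def test_instability_aborts_with_time_in_message(self):
        p = ModelParams(grid_n=3, gain_e=1.0, gain_i=0.0)  # absurd gain
        model = LaminarCortexModel(p, _uniform_map(1000.0))
        state = model.initial_state()
        stim = _silent_stimuli(1000)
        with pytest.raises(InstabilityError, match="ms"):
            for _ in range(1000):
                state = model.step(state, stim)

    def test_firing_rates_stay_within_sigmoid_bounds(self, tiny_params):
        model = LaminarCortexModel(tiny_params)
        state = model.initial_state()
        n = 100
        stim = StimulusFields(np.full(n, 30.0), np.full(n, 10.0))
        for _ in range(n):
            state = model.step(state, stim)
            q = state.firing_rate
            assert np.all(q >= 0) and np.all(q <= tiny_params.sigmoid_qmax)


class TestPropagation:
    def test_zero_rates_propagate_to_zero(self, tiny_params):
        model = LaminarCortexModel(tiny_params)
        state = model.initial_state()
        state.rate_history[:] = 0.0
        state.rate_history_fft[:] = 0.0
        aff_e, aff_i = model.propagate_spikes(state, _silent_stimuli(10))
        assert np.allclose(aff_e, 0.0, atol=1e-12)
        assert np.allclose(aff_i, 0.0, atol=1e-12)

    def test_uniform_rate_times_synapse_count(self):
        # normalised lateral weights: uniform source rate r gives afferent
        # rate exactly count * r at every element
        p = ModelParams(grid_n=6, gain_e=0.0, gain_i=0.0)
        model = LaminarCortexModel(p, _uniform_map(7.0))
        state = model.initial_state()
        state.rate_history[:] = 3.0
        state.rate_history_fft[:] = np.fft.rfft2(state.rate_history, axes=(-2, -1))
        aff_e, _ = model.propagate_spikes(state, _silent_stimuli(10))
        assert np.allclose(aff_e[:, 0], 21.0)  # E targets: count 7 x rate 3
        assert np.allclose(aff_e[:, 1], 0.0)   # no E->I entries in this map

    def test_single_source_matches_nested_loop_reference(self):
        """FFT lateral propagation agrees with a brute-force double loop."""
        p = ModelParams(grid_n=5)
        model = LaminarCortexModel(p, _uniform_map(1.0))
        state = model.initial_state()
        state.rate_history[:] = 0.0
        # one source element firing at 10 spikes/s at every past lag
        rate = np.zeros((5, 5))
        rate[1, 3] = 10.0
        state.rate_history[:, :, 0] = rate
        state.rate_history_fft[:] = np.fft.rfft2(state.rate_history, axes=(-2, -1))
        aff_e, _ = model.propagate_spikes(state, _silent_stimuli(10))

        w, _ = lateral_kernel(p, 0)
        expected = np.zeros((5, 5))
        for ti in range(5):
            for tj in range(5):
                for si in range(5):
                    for sj in range(5):
                        expected[ti, tj] += w[(ti - si) % 5, (tj - sj) % 5] \
                            * rate[si, sj]
        for layer in range(5):
            np.testing.assert_allclose(aff_e[layer, 0], expected, rtol=1e-9)

    def test_interlaminar_coupling_is_vertical_only(self):
        # IV -> II/III coupling: a point source in IV appears only at the
        # vertically aligned II/III element
        entries = [Connection("IV", "E", "II/III", "E", 5.0, "intracortical")]
        p = ModelParams(grid_n=5)
        model = LaminarCortexModel(p, ConnectionMap(entries))
        state = model.initial_state()
        state.rate_history[:] = 0.0
        state.rate_history[:, 2, 0, 2, 2] = 4.0   # layer IV E source at (2, 2)
        state.rate_history_fft[:] = np.fft.rfft2(state.rate_history, axes=(-2, -1))
        aff_e, _ = model.propagate_spikes(state, _silent_stimuli(10))
        expected = np.zeros((5, 5))
        expected[2, 2] = 20.0
        np.testing.assert_allclose(aff_e[1, 0], expected, atol=1e-12)
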