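"""Circuit core: switch logic, DC solves, integration and spike extraction."""

import numpy as np
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st

from nlifsim import (
    NeuronCircuitParams,
    SimulationTrace,
    SpikeTrain,
    SwitchState,
    ThresholdSwitchSpec,
    crank_nicolson_step,
    detect_spikes,
    rest_state,
    simulate,
    steady_state,
    switch_voltage,
    update_switch_state,
)

from conftest import make_state


# ---------------------------------------------------------------------------
# switch voltages and hysteresis


def test_switch_voltage_is_drop_from_bias(params):
    # V1 = 0.1 with V_dc1 = -0.9 puts exactly v_on across S1
    st_ = make_state(params, v1=0.1, v2=0.0)
    assert switch_voltage(st_, "S1", params) == pytest.approx(1.0)
    # zero drop when the node sits at its bias
    st_ = make_state(params, v1=0.0, v2=params.v_dc2)
    assert switch_voltage(st_, "S2", params) == pytest.approx(0.0)
    # V2 = -0.1 with V_dc2 = 0.9 puts -v_on across S2 (signed)
    st_ = make_state(params, v1=0.0, v2=-0.1)
    assert switch_voltage(st_, "S2", params) == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        switch_voltage(st_, "S3", params)


@pytest.mark.parametrize(
    "is_on,v,expect_on",
    [
        (False, 1.0, True),    # off->on exactly at v_on (closed comparison)
        (False, 0.99, False),
        (True, 0.7, True),     # inside the hysteresis band: state held
        (True, 0.5, False),    # on->off exactly at v_off
        (True, -1.2, True),    # magnitude matters, sign does not
        (False, -1.0, True),
    ],
)
def test_update_switch_state_thresholds(is_on, v, expect_on):
    spec = ThresholdSwitchSpec()
    out = update_switch_state(SwitchState(is_on, spec), v)
    assert out.is_on is expect_on


@given(v=st.floats(min_value=0.5, max_value=1.0,
                   exclude_min=True, exclude_max=True),
       sign=st.sampled_from([-1.0, 1.0]),
       is_on=st.booleans())
@settings(deadline=None, max_examples=100, derandomize=True)
def test_hysteresis_band_is_identity(v, sign, is_on):
    """Strictly inside (v_off, v_on) the update never changes the state."""
    spec = ThresholdSwitchSpec()
    out = update_switch_state(SwitchState(is_on, spec), sign * v)
    assert out.is_on is is_on


def test_switch_spec_invariants():
    with pytest.raises(ValueError):
        ThresholdSwitchSpec(r_on=1e6, r_off=1e6)
    with pytest.raises(ValueError):
        ThresholdSwitchSpec(v_on=0.5, v_off=0.5)
    with pytest.raises(ValueError):
        NeuronCircuitParams(c1=-1e-9)


# ---------------------------------------------------------------------------
# DC steady states


def test_resting_fixed_point_near_printed_value(params):
    v1, v2 = steady_state(params, False, False, 0.0)
    assert v2 == pytest.approx(0.044, abs=0.005)
    assert v1 == pytest.approx(-0.042, abs=0.005)


def test_steady_state_matches_symbolic_solve(params):
    """Independent symbolic solve of the nodal equations (exact oracle)."""
    v1s, v2s = sympy.symbols("v1 v2")
    for s1_on, s2_on, i_in in [(False, False, 0.0), (True, False, 1e-6),
                               (False, True, 0.0), (True, True, 0.5e-6)]:
        rs1 = sympy.Rational(1, 1) * (params.s1.r_on if s1_on else params.s1.r_off)
        rs2 = sympy.Rational(1, 1) * (params.s2.r_on if s2_on else params.s2.r_off)
        eq1 = sympy.Eq(i_in - (v1s - params.v_dc1) / rs1 - (v1s - v2s) / params.r2, 0)
        eq2 = sympy.Eq((v1s - v2s) / params.r2 - (v2s - params.v_dc2) / rs2
                       - v2s / params.r_load, 0)
        sol = sympy.solve([eq1, eq2], [v1s, v2s])
        v1, v2 = steady_state(params, s1_on, s2_on, i_in)
        assert abs(v1 - float(sol[v1s])) < 1e-6
        assert abs(v2 - float(sol[v2s])) < 1e-6


def test_steady_state_unbiased_circuit_is_zero(params):
    from dataclasses import replace

    p = replace(params, v_dc1=0.0, v_dc2=0.0)
    v1, v2 = steady_state(p, False, False, 0.0)
    assert v1 == pytest.approx(0.0, abs=1e-15)
    assert v2 == pytest.approx(0.0, abs=1e-15)


def test_steady_state_agrees_with_relaxed_integration(params):
    """The DC solve is a fixed point of the time stepper (<1 uV)."""
    v1, v2 = steady_state(params, False, False, 0.0)
    state = make_state(params, v1=0.2, v2=-0.05)
    for _ in range(20000):
        state = crank_nicolson_step(state, 0.0, 5e-6, params)
    assert abs(state.v1 - v1) < 1e-6
    assert abs(state.v2 - v2) < 1e-6


# ---------------------------------------------------------------------------
# Crank-Nicolson stepping


def test_step_keeps_fixed_point_stationary(params):
    v1, v2 = steady_state(params, False, False, 0.0)
    state = make_state(params, v1=v1, v2=v2)
    out = crank_nicolson_step(state, 0.0, 1e-6, params)
    assert out.v1 == pytest.approx(v1, abs=1e-12)
    assert out.v2 == pytest.approx(v2, abs=1e-12)
    assert out.s1_state.is_on is False and out.s2_state.is_on is False


def _rk4_oracle(params, state, i_in, dt, n_steps):
    """Explicit RK4 on the same piecewise-linear ODE with post-step switch
    updates; independent of the Crank-Nicolson path."""
    from nlifsim.circuit import _system_matrices

    v = np.array([state.v1, state.v2])
    s1, s2 = state.s1_state, state.s2_state
    for _ in range(n_steps):
        a, b = _system_matrices(params, s1.resistance, s2.resistance, i_in)

        def f(x):
            return a @ x + b

        k1 = f(v)
        k2 = f(v + 0.5 * dt * k1)
        k3 = f(v + 0.5 * dt * k2)
        k4 = f(v + dt * k3)
        v = v + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        ns = make_state(params, v1=v[0], v2=v[1], s1_on=s1.is_on, s2_on=s2.is_on)
        s1 = update_switch_state(s1, switch_voltage(ns, "S1", params))
        s2 = update_switch_state(s2, switch_voltage(ns, "S2", params))
    return v, s1.is_on, s2.is_on


def test_crank_nicolson_tracks_rk4_oracle(params):
    """1 uA drive over 1 ms at dt = 10 ns: CN and RK4 agree to < 1 mV."""
    dt = 10e-9
    n = 100_000
    rest = rest_state(params)
    v_rk4, _, _ = _rk4_oracle(params, rest, 1e-6, dt, n)
    from nlifsim.circuit import raw_run

    res = raw_run(params, 1e-6, n * dt, dt, initial=rest, record=True)
    v1_t, v2_t, _, _ = res.trace_arrays
    assert abs(v1_t[-1] - v_rk4[0]) < 1e-3
    assert abs(v2_t[-1] - v_rk4[1]) < 1e-3


def test_crank_nicolson_second_order_convergence(params):
    """Richardson check on a smooth (event-free) sub-threshold segment."""
    from nlifsim.circuit import raw_run

    i_in = 0.2e-6  # below the firing threshold: no switching events
    duration = 1e-3
    ref = raw_run(params, i_in, duration, dt=0.0625e-6, record=True)
    assert ref.n_events == 0
    v_ref = np.array([ref.trace_arrays[0][-1], ref.trace_arrays[1][-1]])
    errs = []
    dts = [4e-6, 2e-6, 1e-6]
    for dt in dts:
        res = raw_run(params, i_in, duration, dt=dt, record=True)
        v = np.array([res.trace_arrays[0][-1], res.trace_arrays[1][-1]])
        errs.append(np.max(np.abs(v - v_ref)))
    slope = np.polyfit(np.log(dts), np.log(errs), 1)[0]
    assert slope == pytest.approx(2.0, abs=0.2)


# ---------------------------------------------------------------------------
# full simulations


def test_reference_drive_spikes_periodically(reference_trace, reference_train):
    assert reference_train.activity > 10
    isis = reference_train.isis()
    assert np.std(isis[2:]) / np.mean(isis[2:]) < 0.02  # periodic after onset
    # membrane excursions confined to the threshold range
    after_onset = reference_trace.times > reference_train.spike_times[1]
    v2 = reference_trace.v2[after_onset]
    assert v2.min() >= -0.1 - 5e-3
    assert v2.max() <= 0.4 + 5e-3


def test_zero_current_relaxes_to_rest(params):
    trace = simulate(params, 0.0, 30e-3,
                     initial=make_state(params, v1=0.05, v2=-0.02))
    assert trace.events == []
    v1, v2 = steady_state(params, False, False, 0.0)
    assert trace.v1[-1] == pytest.approx(v1, abs=1e-6)
    assert trace.v2[-1] == pytest.approx(v2, abs=1e-6)


def test_passivity_without_sources(params):
    """No drive and no bias: voltage magnitudes decay monotonically."""
    from dataclasses import replace

    p = replace(params, v_dc1=0.0, v_dc2=0.0)
    trace = simulate(p, 0.0, 2e-3,
                     initial=make_state(p, v1=0.3, v2=-0.2))
    env = np.maximum(np.abs(trace.v1), np.abs(trace.v2))
    assert np.all(np.diff(env) <= 1e-12)


def test_oversized_c2_suppresses_spiking(params):
    """With C2 far above the window, S1 recovers off before S2 turns on."""
    slow = params.with_capacitances(3e-9, 100e-9)
    trace = simulate(slow, 1e-6, 30e-3)
    train = detect_spikes(trace, 30e-3)
    assert train.activity == 0


# ---------------------------------------------------------------------------
# spike extraction


def _trace_with_events(events, t_end=0.03):
    n = 10
    times = np.linspace(0.0, t_end, n)
    z = np.zeros(n)
    return SimulationTrace(times=times, v1=z, v2=z, r_s1=z, r_s2=z,
                           events=events)


def test_detect_spikes_counts_completed_flickers():
    trace = _trace_with_events([
        (1e-3, "S2", "on"), (2e-3, "S2", "off"),
        (5e-3, "S2", "on"), (6e-3, "S2", "off"),
    ])
    train = detect_spikes(trace, 30e-3)
    np.testing.assert_allclose(train.spike_times, [1e-3, 5e-3])
    assert train.activity == 2


def test_detect_spikes_ignores_stuck_on_cycle():
    trace = _trace_with_events([(1e-3, "S2", "on")])
    assert detect_spikes(trace, 30e-3).activity == 0


def test_detect_spikes_ignores_s1_events():
    trace = _trace_with_events([
        (0.5e-3, "S1", "on"), (0.9e-3, "S1", "off"),
        (1e-3, "S2", "on"), (2e-3, "S2", "off"),
    ])
    assert detect_spikes(trace, 30e-3).activity == 1


def test_spike_train_window_activity():
    train = SpikeTrain(np.array([1e-3, 10e-3, 29e-3, 31e-3]), window=30e-3)
    assert train.activity == 3
    with pytest.raises(ValueError):
        SpikeTrain(np.array([2e-3, 1e-3]), window=30e-3)
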