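"""Core integration of the NLIF neuron circuit.

The circuit has two state variables: the auxiliary node voltage V1 and the
membrane potential V2 (the output node).  Nodal balance gives

    C1 dV1/dt = I_in - (V1 - V_dc1)/R_S1 - (V1 - V2)/R2
    C2 dV2/dt = (V1 - V2)/R2 - (V2 - V_dc2)/R_S2 - V2/R_L

where R_S1, R_S2 are the state-dependent switch resistances, held constant
within an integration step.  The pair (V1, V2) is advanced with the
Crank-Nicolson scheme; after each step the switch states are updated from
the new voltages (post-step event handling, no sub-step bisection).

A spike is one completed off->on->off cycle ("flicker") of switch S2; its
time stamp is the on-switching event time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .params import NeuronCircuitParams, NeuronState, SwitchState, ThresholdSwitchSpec

__all__ = [
    "PulseCurrent",
    "SimulationTrace",
    "SpikeTrain",
    "DEFAULT_DT",
    "switch_voltage",
    "update_switch_state",
    "crank_nicolson_step",
    "steady_state",
    "rest_state",
    "simulate",
    "detect_spikes",
]

#: default integration step [s]; far below the smallest RC time
#: (R_on * C2 = 100 us for the reference circuit)
DEFAULT_DT = 0.5e-6


@dataclass(frozen=True)
class PulseCurrent:
    """Rectangular current pulse: ``amplitude`` between ``onset`` and
    ``onset + width``, zero elsewhere."""

    amplitude: float
    onset: float = 0.0
    width: float = np.inf

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.where((t >= self.onset) & (t < self.onset + self.width),
                        self.amplitude, 0.0)


CurrentProfile = float | PulseCurrent | Callable[[np.ndarray], np.ndarray] | np.ndarray


@dataclass
class SimulationTrace:
    """Sampled voltage/resistance time series plus the switching-event log.

    ``events`` holds ``(time, switch, transition)`` tuples with switch in
    {"S1", "S2"} and transition in {"on", "off"}.
    """

    times: np.ndarray
    v1: np.ndarray
    v2: np.ndarray
    r_s1: np.ndarray
    r_s2: np.ndarray
    events: list[tuple[float, str, str]]

    def __post_init__(self) -> None:
        n = len(self.times)
        if not all(len(a) == n for a in (self.v1, self.v2, self.r_s1, self.r_s2)):
            raise ValueError("trace arrays must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.times, "v1": self.v1, "v2": self.v2,
             "r_s1": self.r_s1, "r_s2": self.r_s2}
        )

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["t", "switch", "transition"])


@dataclass
class SpikeTrain:
    """Spike times (seconds) and the observation window used for activity."""

    spike_times: np.ndarray
    window: float

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size and np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("spike_times must be strictly increasing")

    @property
    def activity(self) -> int:
        """Number of spikes within the observation window."""
        return int(np.count_nonzero(self.spike_times <= self.window))

    def isis(self) -> np.ndarray:
        return np.diff(self.spike_times)

    def __len__(self) -> int:
        return self.spike_times.size


# ---------------------------------------------------------------------------
# elementary operations


def switch_voltage(state: NeuronState, which: str,
                   params: NeuronCircuitParams) -> float:
    """Signed voltage across a switch: V1 - V_dc1 for S1, V2 - V_dc2 for S2."""
    w = which.upper()
    if w == "S1":
        return state.v1 - params.v_dc1
    if w == "S2":
        return state.v2 - params.v_dc2
    raise ValueError(f"unknown switch id {which!r}; expected 'S1' or 'S2'")


def update_switch_state(state: SwitchState, v_across: float) -> SwitchState:
    """Hysteretic update: off->on at |v| >= v_on, on->off at |v| <= v_off.

    Inside the hysteresis band (v_off < |v| < v_on) the state is kept.
    Both comparisons are closed, giving deterministic boundary behavior.
    """
    mag = abs(v_across)
    if not state.is_on and mag >= state.spec.v_on:
        return SwitchState(True, state.spec)
    if state.is_on and mag <= state.spec.v_off:
        return SwitchState(False, state.spec)
    return state


def _system_matrices(params: NeuronCircuitParams, rs1: float, rs2: float,
                     i_in: float) -> tuple[np.ndarray, np.ndarray]:
    """Continuous-time system dV/dt = A V + b for fixed switch resistances."""
    a = np.array([
        [-(1.0 / rs1 + 1.0 / params.r2) / params.c1,
         (1.0 / params.r2) / params.c1],
        [(1.0 / params.r2) / params.c2,
         -(1.0 / params.r2 + 1.0 / rs2 + 1.0 / params.r_load) / params.c2],
    ])
    b = np.array([
        (i_in + params.v_dc1 / rs1) / params.c1,
        (params.v_dc2 / rs2) / params.c2,
    ])
    return a, b


def crank_nicolson_step(state: NeuronState, i_in: float, dt: float,
                        params: NeuronCircuitParams) -> NeuronState:
    """One Crank-Nicolson step followed by the post-step switch update.

    The switch resistances are taken from the incoming state and held
    constant over the step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    a, b = _system_matrices(params, state.s1_state.resistance,
                            state.s2_state.resistance, i_in)
    eye = np.eye(2)
    m = eye - 0.5 * dt * a
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    if det == 0.0:
        raise ValueError("singular Crank-Nicolson step matrix (non-physical parameters)")
    v = np.array([state.v1, state.v2])
    rhs = (eye + 0.5 * dt * a) @ v + dt * b
    v_new = np.linalg.solve(m, rhs)
    new = NeuronState(
        v1=float(v_new[0]), v2=float(v_new[1]),
        s1_state=state.s1_state, s2_state=state.s2_state,
        t=state.t + dt,
    )
    s1 = update_switch_state(new.s1_state, switch_voltage(new, "S1", params))
    s2 = update_switch_state(new.s2_state, switch_voltage(new, "S2", params))
    return NeuronState(new.v1, new.v2, s1, s2, new.t)


def steady_state(params: NeuronCircuitParams, s1_on: bool, s2_on: bool,
                 i_in: float) -> tuple[float, float]:
    """DC fixed point (v1, v2) for a fixed switch configuration.

    Solves the nodal system with the capacitors removed; this is the fixed
    point of the piecewise-linear dynamics for that configuration.
    """
    return dc_solve(params, params.s1.resistance(s1_on),
                    params.s2.resistance(s2_on), i_in)


def dc_solve(params: NeuronCircuitParams, rs1: float, rs2: float,
             i_in: float) -> tuple[float, float]:
    """DC nodal solve (v1, v2) for explicit switch resistances."""
    g = np.array([
        [1.0 / rs1 + 1.0 / params.r2, -1.0 / params.r2],
        [-1.0 / params.r2, 1.0 / params.r2 + 1.0 / rs2 + 1.0 / params.r_load],
    ])
    rhs = np.array([i_in + params.v_dc1 / rs1, params.v_dc2 / rs2])
    try:
        v = np.linalg.solve(g, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular DC nodal system") from exc
    return float(v[0]), float(v[1])


def rest_state(params: NeuronCircuitParams) -> NeuronState:
    """Both-off steady state at zero input current (the resting point)."""
    v1, v2 = steady_state(params, False, False, 0.0)
    return NeuronState(
        v1=v1, v2=v2,
        s1_state=SwitchState(False, params.s1),
        s2_state=SwitchState(False, params.s2),
        t=0.0,
    )


# ---------------------------------------------------------------------------
# kernel plumbing


def _resolve_current(current: CurrentProfile, n_steps: int, dt: float) -> np.ndarray:
    """Reduce any accepted current profile to the kernel's array form."""
    if isinstance(current, (int, float)):
        return np.array([float(current)])
    if isinstance(current, np.ndarray) and current.ndim == 2 and current.shape[1] == 2:
        nodes = np.arange(n_steps + 1) * dt
        return np.interp(nodes, current[:, 0], current[:, 1])
    if callable(current):
        nodes = np.arange(n_steps + 1) * dt
        return np.asarray(current(nodes), dtype=float)
    raise TypeError(
        "current must be a number, a callable t->A, a PulseCurrent, or an "
        "(m, 2) time-current table"
    )


class RawRunResult(NamedTuple):
    spike_times: np.ndarray
    n_events: int
    v1: float
    v2: float
    s1_on: bool
    s2_on: bool
    max_s2_on: float
    tail_s2_on: float
    sum_s2_on: float
    events: tuple[np.ndarray, np.ndarray, np.ndarray]  # (t, switch, direction)
    trace_arrays: tuple[np.ndarray, ...] | None


def _spec_row(spec: ThresholdSwitchSpec) -> list[float]:
    return [spec.r_on, spec.r_off, spec.v_on, spec.v_off]


def raw_run(
    params: NeuronCircuitParams,
    current: CurrentProfile,
    duration: float,
    dt: float = DEFAULT_DT,
    initial: NeuronState | None = None,
    *,
    noisy: bool = False,
    init_resample: bool = False,
    means: np.ndarray | None = None,
    devs: np.ndarray | None = None,
    seed: int = 0,
    record: bool = False,
) -> RawRunResult:
    """Low-level driver around the compiled kernel (internal API).

    ``means``/``devs`` are (2, 4) arrays over [r_on, r_off, v_on, v_off]
    rows for S1 and S2; only used when ``noisy`` is True.
    """
    if duration < dt:
        raise ValueError("duration must be at least dt")
    n_steps = int(round(duration / dt))
    state = rest_state(params) if initial is None else initial
    specs = np.array([_spec_row(params.s1), _spec_row(params.s2)], dtype=float)
    if means is None:
        means = specs.copy()
    if devs is None:
        devs = np.zeros((2, 4))
    cur = _resolve_current(current, n_steps, dt)

    spike_cap = max(256, int(duration / 5e-5) + 64)
    ev_cap = 6 * spike_cap
    spike_buf = np.empty(spike_cap)
    ev_t = np.empty(ev_cap)
    ev_sw = np.empty(ev_cap, dtype=np.int64)
    ev_dir = np.empty(ev_cap, dtype=np.int64)
    if record:
        v1_out = np.empty(n_steps + 1)
        v2_out = np.empty(n_steps + 1)
        rs1_out = np.empty(n_steps + 1)
        rs2_out = np.empty(n_steps + 1)
    else:
        v1_out = v2_out = rs1_out = rs2_out = np.empty(1)

    (n_events, n_spikes, v1, v2, s1_on, s2_on, max_s2_on, tail_s2_on,
     sum_s2_on, status) = _kernels.run_neuron(
        float(state.v1), float(state.v2),
        bool(state.s1_state.is_on), bool(state.s2_state.is_on),
        specs, np.asarray(means, dtype=float), np.asarray(devs, dtype=float),
        params.r2, params.r_load, params.c1, params.c2,
        params.v_dc1, params.v_dc2,
        cur, n_steps, dt,
        noisy, init_resample, int(seed),
        record, v1_out, v2_out, rs1_out, rs2_out,
        ev_t, ev_sw, ev_dir, spike_buf,
    )
    if status == 1:
        raise RuntimeError(
            "switch-parameter resampler exhausted its redraws; the noise "
            "deviations are too large for the physical constraints"
        )
    if status == 2:
        raise RuntimeError("event/spike buffer overflow")
    if status == 3:
        raise ValueError("singular Crank-Nicolson step matrix (non-physical parameters)")
    trace = (v1_out, v2_out, rs1_out, rs2_out) if record else None
    return RawRunResult(
        spike_times=spike_buf[:n_spikes].copy(),
        n_events=n_events, v1=v1, v2=v2, s1_on=bool(s1_on), s2_on=bool(s2_on),
        max_s2_on=max_s2_on, tail_s2_on=tail_s2_on, sum_s2_on=sum_s2_on,
        events=(ev_t[:n_events].copy(), ev_sw[:n_events].copy(),
                ev_dir[:n_events].copy()),
        trace_arrays=trace,
    )


def _events_to_list(events: tuple[np.ndarray, np.ndarray, np.ndarray]
                    ) -> list[tuple[float, str, str]]:
    t, sw, direction = events
    return [
        (float(ti), "S1" if s == 0 else "S2", "on" if d == 1 else "off")
        for ti, s, d in zip(t, sw, direction)
    ]


def simulate(
    params: NeuronCircuitParams,
    current: CurrentProfile,
    duration: float,
    dt: float = DEFAULT_DT,
    initial: NeuronState | None = None,
) -> SimulationTrace:
    """Noise-free simulation; the trace is sampled at every step.

    ``initial=None`` starts from the rest state (both switches off at the
    zero-current steady state).
    """
    res = raw_run(params, current, duration, dt, initial, record=True)
    n_steps = int(round(duration / dt))
    v1_out, v2_out, rs1_out, rs2_out = res.trace_arrays
    return SimulationTrace(
        times=np.arange(n_steps + 1) * dt,
        v1=v1_out, v2=v2_out, r_s1=rs1_out, r_s2=rs2_out,
        events=_events_to_list(res.events),
    )


def detect_spikes(trace: SimulationTrace, window: float) -> SpikeTrain:
    """Extract spikes from the event log of a trace.

    One spike per completed S2 on->off cycle, stamped at the on-switching
    time; cycles still open at the end of the trace (stuck-on) do not
    count.
    """
    spikes = []
    on_time: float | None = None
    for t, sw, tr in trace.events:
        if sw != "S2":
            continue
        if tr == "on":
            on_time = t
        elif tr == "off" and on_time is not None:
            spikes.append(on_time)
            on_time = None
    return SpikeTrain(np.asarray(spikes), window=window)
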