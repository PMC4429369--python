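"""Numba-compiled integration kernel shared by all simulation entry points.

One kernel advances the two-node circuit with the Crank-Nicolson scheme,
applies post-step threshold-switch updates, optionally resamples switch
parameters after every switching event (the event-driven noise model), and
accumulates spikes plus the S2 on-duration bookkeeping used by the
stuck-on failure detector.

The per-step linear system is solved in closed form (2x2).  Switch
resistances are held constant over a step and updated from the *new*
voltages after the step, with closed threshold comparisons
(|v| >= v_on turns on, |v| <= v_off turns off).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Column layout of a switch-spec row: [r_on, r_off, v_on, v_off]
R_ON, R_OFF, V_ON, V_OFF = 0, 1, 2, 3

#: maximum redraws when truncating the Gaussian parameter sampler
MAX_REDRAWS = 1000


@njit(cache=True)
def resample_spec(out, means, devs):
    """Draw one switch spec into ``out`` (length-4 row).

    Parameters with zero deviation stay exactly at their mean.  Draws are
    redrawn until all values are positive, r_off > r_on and v_on > v_off.
    Returns True on success, False if MAX_REDRAWS was exhausted.
    """
    for _ in range(MAX_REDRAWS):
        ok = True
        for j in range(4):
            if devs[j] > 0.0:
                out[j] = np.random.normal(means[j], devs[j] * means[j])
            else:
                out[j] = means[j]
            if out[j] <= 0.0:
                ok = False
        if ok and out[R_OFF] > out[R_ON] and out[V_ON] > out[V_OFF]:
            return True
    return False


@njit(cache=True)
def run_neuron(
    v1,
    v2,
    s1_on,
    s2_on,
    specs,          # (2,4) current switch specs, mutated on resampling
    means,          # (2,4) sampling means (ignored unless noisy)
    devs,           # (2,4) relative standard deviations (ignored unless noisy)
    r2,
    rl,
    c1,
    c2,
    vdc1,
    vdc2,
    current,        # (1,) constant or (n_steps+1,) per-node values [A]
    n_steps,
    dt,
    noisy,          # resample the transitioned switch after each event
    init_resample,  # also draw both switch specs at t=0 (device history)
    seed,
    record,         # write full voltage/resistance traces
    v1_out,         # (n_steps+1,) if record else (1,)
    v2_out,
    rs1_out,
    rs2_out,
    ev_t,           # event buffers
    ev_sw,
    ev_dir,
    spike_times,    # completed S2 flicker on-times
):
    """Advance the circuit ``n_steps`` steps of size ``dt``.

    Returns (n_events, n_spikes, v1, v2, s1_on, s2_on,
             max_s2_on, tail_s2_on, sum_s2_on_completed, status)
    where status is 0 on success, 1 if the resampler exhausted its
    redraws, 2 if an event/spike buffer overflowed, 3 on a singular
    step matrix.
    """
    if noisy:
        np.random.seed(seed)
        if init_resample:
            for k in range(2):
                if not resample_spec(specs[k], means[k], devs[k]):
                    return (0, 0, v1, v2, s1_on, s2_on, 0.0, 0.0, 0.0, 1)
    per_node = current.shape[0] > 1
    n_events = 0
    n_spikes = 0
    s2_on_since = -1.0   # time of the ongoing S2 on-phase start
    max_s2_on = 0.0
    sum_s2_on = 0.0
    status = 0
    if record:
        v1_out[0] = v1
        v2_out[0] = v2
        rs1_out[0] = specs[0, R_ON] if s1_on else specs[0, R_OFF]
        rs2_out[0] = specs[1, R_ON] if s2_on else specs[1, R_OFF]
    for i in range(n_steps):
        rs1 = specs[0, R_ON] if s1_on else specs[0, R_OFF]
        rs2 = specs[1, R_ON] if s2_on else specs[1, R_OFF]
        if per_node:
            iin = 0.5 * (current[i] + current[i + 1])
        else:
            iin = current[0]
        # nodal balance: C1 v1' = iin - (v1-vdc1)/rs1 - (v1-v2)/r2
        #                C2 v2' = (v1-v2)/r2 - (v2-vdc2)/rs2 - v2/rl
        a11 = -(1.0 / rs1 + 1.0 / r2) / c1
        a12 = (1.0 / r2) / c1
        a21 = (1.0 / r2) / c2
        a22 = -(1.0 / r2 + 1.0 / rs2 + 1.0 / rl) / c2
        b1 = (iin + vdc1 / rs1) / c1
        b2 = (vdc2 / rs2) / c2
        h = 0.5 * dt
        m11 = 1.0 - h * a11
        m12 = -h * a12
        m21 = -h * a21
        m22 = 1.0 - h * a22
        det = m11 * m22 - m12 * m21
        if det == 0.0:
            status = 3
            break
        r1v = v1 + h * (a11 * v1 + a12 * v2) + dt * b1
        r2v = v2 + h * (a21 * v1 + a22 * v2) + dt * b2
        v1 = (r1v * m22 - m12 * r2v) / det
        v2 = (m11 * r2v - m21 * r1v) / det
        t = (i + 1) * dt
        if record:
            v1_out[i + 1] = v1
            v2_out[i + 1] = v2

        # --- post-step threshold checks (closed comparisons) ---
        ev1 = 0  # 0 none, 1 on, -1 off
        va1 = abs(v1 - vdc1)
        if not s1_on and va1 >= specs[0, V_ON]:
            s1_on = True
            ev1 = 1
        elif s1_on and va1 <= specs[0, V_OFF]:
            s1_on = False
            ev1 = -1
        ev2 = 0
        va2 = abs(v2 - vdc2)
        if not s2_on and va2 >= specs[1, V_ON]:
            s2_on = True
            ev2 = 1
            s2_on_since = t
        elif s2_on and va2 <= specs[1, V_OFF]:
            s2_on = False
            ev2 = -1
            if s2_on_since >= 0.0:
                dur = t - s2_on_since
                sum_s2_on += dur
                if dur > max_s2_on:
                    max_s2_on = dur
                if n_spikes < spike_times.shape[0]:
                    spike_times[n_spikes] = s2_on_since
                    n_spikes += 1
                else:
                    status = 2
        for k in range(2):
            ev = ev1 if k == 0 else ev2
            if ev == 0:
                continue
            if n_events < ev_t.shape[0]:
                ev_t[n_events] = t
                ev_sw[n_events] = k
                ev_dir[n_events] = 1 if ev == 1 else 0
                n_events += 1
            else:
                status = 2
            if noisy:
                if not resample_spec(specs[k], means[k], devs[k]):
                    status = 1
                    return (n_events, n_spikes, v1, v2, s1_on, s2_on,
                            max_s2_on, 0.0, sum_s2_on, status)
        if record:
            rs1_out[i + 1] = specs[0, R_ON] if s1_on else specs[0, R_OFF]
            rs2_out[i + 1] = specs[1, R_ON] if s2_on else specs[1, R_OFF]

    tail_s2_on = 0.0
    if s2_on and s2_on_since >= 0.0:
        tail_s2_on = n_steps * dt - s2_on_since
        if tail_s2_on > max_s2_on:
            max_s2_on = tail_s2_on
    elif s2_on:
        # on from the start and never switched
        tail_s2_on = n_steps * dt
        max_s2_on = max(max_s2_on, tail_s2_on)
    return (n_events, n_spikes, v1, v2, s1_on, s2_on,
            max_s2_on, tail_s2_on, sum_s2_on, status)
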