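"""Event-driven switching noise: the stochastic model of device variability.

Experimental threshold switches do not reproduce the same parameters on
every switching cycle.  This is modelled as *noise rather than
heterogeneity*: immediately after each on- and each off-switching event,
the parameters of the switch that just transitioned are redrawn from
Gaussians centered on their nominal means (relative standard deviation
per parameter), truncated so that all values stay positive, r_off > r_on
and v_on > v_off.  Between events the parameters are constant, so the
resistance traces step-fluctuate.

The dominant failure mode under noise is S2 sticking in its on-state
(the membrane potential stays high and S1 stops switching); it is
detected from anomalously long S2 on-phases relative to the noise-free
rhythm at the same drive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .circuit import (
    DEFAULT_DT,
    CurrentProfile,
    SimulationTrace,
    SpikeTrain,
    _events_to_list,
    dc_solve,
    detect_spikes,
    raw_run,
)
from .params import NeuronCircuitParams, ThresholdSwitchSpec

__all__ = [
    "NoiseSpec",
    "TrialOutcome",
    "NoiseFreeReference",
    "sample_switch_spec",
    "simulate_noisy",
    "detect_stuck_failure",
    "success_rate_scan",
    "noisy_activity",
    "noise_free_reference",
    "certainly_silent",
]

PARAM_NAMES = ("r_on", "r_off", "v_on", "v_off")

#: an S2 on-phase longer than this multiple of the noise-free mean ISI
#: (at the same drive) flags a stuck-on failure
STUCK_ISI_MULTIPLIER = 10.0
#: an S2 on-phase still open at stimulus end longer than this multiple of
#: the noise-free spike width flags a stuck-on failure
STUCK_WIDTH_MULTIPLIER = 10.0


@dataclass(frozen=True)
class NoiseSpec:
    """Per-parameter sampling means and relative standard deviations.

    Defaults: means at the reference switch values with zero deviation.
    ``resistance_noise`` builds the combined-noise case used for the
    coding and population studies, where only r_on and r_off fluctuate
    (v_on has negligible effect on success and v_off would need a
    tolerance far tighter than the resistances).
    """

    r_on: float = 50e3
    r_off: float = 1e6
    v_on: float = 1.0
    v_off: float = 0.5
    dev_r_on: float = 0.0
    dev_r_off: float = 0.0
    dev_v_on: float = 0.0
    dev_v_off: float = 0.0
    seed: int = 0
    #: device-history variant: also draw both switches' parameters at
    #: trial start (a running device's parameters are whatever its last
    #: switching cycle set them to).  The default starts every trial at
    #: the nominal means, so only in-operation switching noise acts.
    sample_initial: bool = False

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            if getattr(self, name) <= 0:
                raise ValueError(f"mean {name} must be positive")
            if getattr(self, "dev_" + name) < 0:
                raise ValueError(f"dev_{name} must be >= 0")

    @classmethod
    def resistance_noise(cls, dev: float, seed: int = 0, **kwargs) -> "NoiseSpec":
        return cls(dev_r_on=dev, dev_r_off=dev, seed=seed, **kwargs)

    @property
    def means(self) -> np.ndarray:
        return np.array([self.r_on, self.r_off, self.v_on, self.v_off])

    @property
    def devs(self) -> np.ndarray:
        return np.array([self.dev_r_on, self.dev_r_off,
                         self.dev_v_on, self.dev_v_off])

    @property
    def is_noisy(self) -> bool:
        return bool(np.any(self.devs > 0))

    def restricted(self, which_params: Iterable[str]) -> "NoiseSpec":
        """Copy with deviations zeroed for parameters not listed."""
        keep = set(which_params)
        unknown = keep - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown switch parameters: {sorted(unknown)}")
        updates = {f"dev_{n}": (getattr(self, f"dev_{n}") if n in keep else 0.0)
                   for n in PARAM_NAMES}
        return replace(self, **updates)


FailureMode = Literal["none", "stuck_on"]


@dataclass
class TrialOutcome:
    success: bool
    spike_train: SpikeTrain
    failure_mode: FailureMode

    def __post_init__(self) -> None:
        if self.failure_mode == "stuck_on" and self.success:
            raise ValueError("a stuck_on trial cannot be a success")


def sample_switch_spec(
    noise: NoiseSpec,
    which_params: Iterable[str] | None = None,
    rng: np.random.Generator | None = None,
    max_redraws: int = 1000,
) -> ThresholdSwitchSpec:
    """Draw one switch spec; unlisted parameters stay at their mean.

    Redraws until all values are positive, r_off > r_on and v_on > v_off;
    raises if ``max_redraws`` is exhausted (unusable NoiseSpec).
    """
    spec = noise if which_params is None else noise.restricted(which_params)
    rng = np.random.default_rng(noise.seed) if rng is None else rng
    means, devs = spec.means, spec.devs
    for _ in range(max_redraws):
        vals = np.where(devs > 0, rng.normal(means, devs * means), means)
        if np.all(vals > 0) and vals[1] > vals[0] and vals[2] > vals[3]:
            return ThresholdSwitchSpec(*vals)
    raise RuntimeError(
        "switch-parameter sampling exhausted its redraws; deviations are "
        "too large for the physical constraints"
    )


@dataclass(frozen=True)
class NoiseFreeReference:
    """Noise-free spiking rhythm at a given drive, used by the stuck detector."""

    mean_isi: float | None
    mean_spike_width: float | None
    n_spikes: int
    n_events: int


@lru_cache(maxsize=512)
def noise_free_reference(params: NeuronCircuitParams, i_in: float,
                         duration: float = 30e-3,
                         dt: float = DEFAULT_DT) -> NoiseFreeReference:
    res = raw_run(params, i_in, duration, dt)
    n = len(res.spike_times)
    mean_isi = float(np.mean(np.diff(res.spike_times))) if n >= 2 else None
    width = res.sum_s2_on / n if n >= 1 else None
    return NoiseFreeReference(mean_isi, width, n, res.n_events)


def certainly_silent(
    params: NeuronCircuitParams,
    noise: NoiseSpec,
    i_in: float,
    duration: float = 30e-3,
    dt: float = DEFAULT_DT,
    n_sigma: float = 6.0,
    margin: float = 0.95,
) -> bool:
    """True if a noisy trial at this drive provably produces no events.

    Without initial sampling this is exact: the pre-first-event transient
    equals the noise-free trajectory, so no noise-free events means no
    events at all.  With initial sampling, a conservative static screen
    is used instead: over all switch-resistance draws within ``n_sigma``
    deviations (and v_on lowered by the same allowance), the DC drop
    across both switches must stay below ``margin`` times the
    on-threshold.  The sub-threshold dynamics is a monotone approach to
    the DC point, so no on-switching can occur.
    """
    if not noise.is_noisy or not noise.sample_initial:
        return noise_free_reference(params, i_in, duration, dt).n_events == 0
    v_on_limit = margin * noise.v_on * (1.0 - n_sigma * noise.dev_v_on)
    if v_on_limit <= 0:
        return False
    def bracket(mean: float, dev: float) -> tuple[float, float]:
        lo = max(mean * (1.0 - n_sigma * dev), 1.0)
        return lo, mean * (1.0 + n_sigma * dev)

    # both switches start off: their resistances are r_off draws
    for rs1 in bracket(noise.r_off, noise.dev_r_off):
        for rs2 in bracket(noise.r_off, noise.dev_r_off):
            v1, v2 = dc_solve(params, rs1, rs2, i_in)
            if abs(v1 - params.v_dc1) >= v_on_limit:
                return False
            if abs(v2 - params.v_dc2) >= v_on_limit:
                return False
    return True


def _stuck_limits(ref: NoiseFreeReference, duration: float,
                  isi_multiplier: float = STUCK_ISI_MULTIPLIER,
                  width_multiplier: float = STUCK_WIDTH_MULTIPLIER
                  ) -> tuple[float, float]:
    """On-duration limits (continuous, trailing); conservative fallbacks
    when the noise-free circuit does not spike at this drive."""
    on_limit = (isi_multiplier * ref.mean_isi if ref.mean_isi is not None
                else duration / 3.0)
    tail_limit = (width_multiplier * ref.mean_spike_width
                  if ref.mean_spike_width is not None else duration / 10.0)
    return on_limit, tail_limit


def _is_stuck(max_s2_on: float, tail_s2_on: float, n_events: int,
              limits: tuple[float, float]) -> bool:
    if n_events == 0:
        return False  # silent is not stuck
    on_limit, tail_limit = limits
    return max_s2_on > on_limit or tail_s2_on > tail_limit


def detect_stuck_failure(trace: SimulationTrace, params: NeuronCircuitParams,
                         i_in: float,
                         isi_multiplier: float = STUCK_ISI_MULTIPLIER,
                         width_multiplier: float = STUCK_WIDTH_MULTIPLIER
                         ) -> FailureMode:
    """Classify a trace as stuck_on or none.

    stuck_on iff S2 stayed on continuously for longer than
    ``isi_multiplier`` times the noise-free mean ISI at the same drive, or
    is still on at the end of the trace after more than
    ``width_multiplier`` times the noise-free spike width.  A trace with
    no switching events is silent, not stuck.
    """
    s2 = [(t, tr) for t, sw, tr in trace.events if sw == "S2"]
    if not trace.events:
        return "none"
    duration = float(trace.times[-1])
    max_on = 0.0
    tail_on = 0.0
    on_since: float | None = None
    for t, tr in s2:
        if tr == "on":
            on_since = t
        elif tr == "off" and on_since is not None:
            max_on = max(max_on, t - on_since)
            on_since = None
    if on_since is not None:
        tail_on = duration - on_since
        max_on = max(max_on, tail_on)
    ref = noise_free_reference(params, i_in, duration)
    limits = _stuck_limits(ref, duration, isi_multiplier, width_multiplier)
    return "stuck_on" if _is_stuck(max_on, tail_on, len(trace.events), limits) else "none"


def simulate_noisy(
    params: NeuronCircuitParams,
    noise: NoiseSpec,
    current: CurrentProfile,
    duration: float,
    dt: float = DEFAULT_DT,
    seed: int | None = None,
    window: float | None = None,
) -> tuple[SimulationTrace, TrialOutcome]:
    """One noisy trial with full trace recording.

    With all deviations zero the result is identical to the noise-free
    ``simulate``.  ``seed`` overrides ``noise.seed``.  The trial fails as
    stuck_on per ``detect_stuck_failure``; success additionally requires
    at least one spike.
    """
    use_seed = noise.seed if seed is None else seed
    means = np.vstack([noise.means, noise.means])
    devs = np.vstack([noise.devs, noise.devs])
    res = raw_run(params, current, duration, dt, noisy=noise.is_noisy,
                  init_resample=noise.sample_initial,
                  means=means, devs=devs, seed=use_seed, record=True)
    n_steps = int(round(duration / dt))
    v1_out, v2_out, rs1_out, rs2_out = res.trace_arrays
    trace = SimulationTrace(
        times=np.arange(n_steps + 1) * dt,
        v1=v1_out, v2=v2_out, r_s1=rs1_out, r_s2=rs2_out,
        events=_events_to_list(res.events),
    )
    train = detect_spikes(trace, duration if window is None else window)
    i_ref = _reference_drive(current)
    ref = noise_free_reference(params, i_ref, duration, dt)
    limits = _stuck_limits(ref, duration)
    stuck = _is_stuck(res.max_s2_on, res.tail_s2_on, res.n_events, limits)
    mode: FailureMode = "stuck_on" if stuck else "none"
    return trace, TrialOutcome(
        success=(train.activity >= 1 and mode == "none"),
        spike_train=train, failure_mode=mode,
    )


def _reference_drive(current: CurrentProfile) -> float:
    """Constant current equivalent used to look up the noise-free rhythm."""
    if isinstance(current, (int, float)):
        return float(current)
    from .circuit import PulseCurrent

    if isinstance(current, PulseCurrent):
        return current.amplitude
    raise TypeError(
        "stuck-on detection on non-constant drives requires an explicit "
        "reference current"
    )


def _trial_seeds(seed: int, n: int) -> np.ndarray:
    """Counter-based substream seeds (uint32, < 2**31) from one root seed."""
    return np.random.SeedSequence(seed).generate_state(n) % np.uint32(2**31)


def noisy_activity(
    params: NeuronCircuitParams,
    noise: NoiseSpec,
    i_in: float,
    n_trials: int,
    seed: int,
    duration: float = 30e-3,
    dt: float = DEFAULT_DT,
    window: float | None = None,
    collect_spikes: bool = False,
) -> dict:
    """Seeded batch of independent noisy trials at a constant drive.

    Returns dict with 'counts' (activity per trial), 'stuck' (bool per
    trial) and optionally 'spike_trains'.
    """
    win = duration if window is None else window
    means = np.vstack([noise.means, noise.means])
    devs = np.vstack([noise.devs, noise.devs])
    ref = noise_free_reference(params, i_in, duration, dt)
    limits = _stuck_limits(ref, duration)
    seeds = _trial_seeds(seed, n_trials)
    counts = np.zeros(n_trials, dtype=int)
    stuck = np.zeros(n_trials, dtype=bool)
    trains: list[SpikeTrain] = []
    for k in range(n_trials):
        res = raw_run(params, i_in, duration, dt, noisy=noise.is_noisy,
                      init_resample=noise.sample_initial,
                      means=means, devs=devs, seed=int(seeds[k]))
        counts[k] = np.count_nonzero(res.spike_times <= win)
        stuck[k] = _is_stuck(res.max_s2_on, res.tail_s2_on, res.n_events, limits)
        if collect_spikes:
            trains.append(SpikeTrain(res.spike_times, win))
    out = {"counts": counts, "stuck": stuck}
    if collect_spikes:
        out["spike_trains"] = trains
    return out


def success_rate_scan(
    params: NeuronCircuitParams,
    varied_param: str,
    dev_grid: Iterable[float],
    i_in_set: Iterable[float],
    trials: int = 100,
    seed: int = 0,
    duration: float = 30e-3,
    dt: float = DEFAULT_DT,
    sample_initial: bool = False,
) -> pd.DataFrame:
    """Tolerance scan: success rate vs deviation of one switch parameter.

    Only ``varied_param`` (one of r_on, r_off, v_on, v_off) fluctuates;
    success = at least one spike and no stuck-on failure.  Every trial
    starts from the nominal parameters by default so the scan isolates the
    *in-operation* (event-driven) variability of the named parameter: an
    initial draw would act as per-trial heterogeneity and, for r_off or
    v_on, mostly measures whether the drawn starting point can fire at
    all rather than whether spiking survives the switching noise.
    Returns a long DataFrame with columns dev, i_in, rate, n_success,
    trials.
    """
    if varied_param not in PARAM_NAMES:
        raise ValueError(f"varied_param must be one of {PARAM_NAMES}")
    if trials < 1:
        raise ValueError("trials must be >= 1")
    rows = []
    for d_idx, dev in enumerate(dev_grid):
        base = NoiseSpec(**{f"dev_{varied_param}": float(dev)},
                         sample_initial=sample_initial)
        for i_idx, i_in in enumerate(i_in_set):
            point_seed = int(
                np.random.SeedSequence((seed, d_idx, i_idx)).generate_state(1)[0]
                % 2**31
            )
            batch = noisy_activity(params, base, float(i_in), trials,
                                   point_seed, duration, dt)
            ok = (batch["counts"] >= 1) & ~batch["stuck"]
            rows.append({
                "dev": float(dev), "i_in": float(i_in),
                "rate": float(np.mean(ok)), "n_success": int(np.sum(ok)),
                "trials": trials,
            })
    return pd.DataFrame(rows)
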