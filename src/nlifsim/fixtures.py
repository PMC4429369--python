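"""Golden reference artifacts for regression testing.

``make_fixtures`` regenerates, deterministically from one seed, a small
set of files that pin down the simulator's behavior: the noise-free
reference trace and its spike train, the resting fixed point, a seeded
noisy trace, and a mini-population likelihood table.  Running it twice
with the same seed must produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .circuit import detect_spikes, simulate, steady_state
from .noise import NoiseSpec, simulate_noisy
from .params import NeuronCircuitParams
from .population import build_population, estimate_likelihood

__all__ = ["make_fixtures"]

#: trace decimation factor for the CSV artifacts (keeps files small)
TRACE_STRIDE = 20


def _write_trace(trace, path: Path) -> None:
    frame = trace.to_frame().iloc[::TRACE_STRIDE]
    frame.to_csv(path, index=False, float_format="%.9g")


def make_fixtures(out_dir: str | Path, seed: int = 0) -> list[Path]:
    """Write the fixture set into ``out_dir``; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = NeuronCircuitParams()
    written: list[Path] = []

    # noise-free reference trace at 1 uA, 30 ms, and its spikes
    trace = simulate(params, 1e-6, 30e-3)
    p = out / "trace_reference.csv"
    _write_trace(trace, p)
    written.append(p)
    train = detect_spikes(trace, 30e-3)
    p = out / "spikes_reference.json"
    p.write_text(json.dumps({"window_s": 30e-3,
                             "spike_times_s": train.spike_times.tolist()},
                            indent=1))
    written.append(p)

    # resting fixed point
    v1, v2 = steady_state(params, False, False, 0.0)
    p = out / "fixed_point.json"
    p.write_text(json.dumps({"v1": v1, "v2": v2}, indent=1))
    written.append(p)

    # seeded noisy trace, 10% resistance deviation
    noisy_trace, outcome = simulate_noisy(
        params, NoiseSpec.resistance_noise(0.10, seed=seed), 1e-6, 30e-3)
    p = out / "trace_noisy_dev10.csv"
    _write_trace(noisy_trace, p)
    written.append(p)
    p = out / "outcome_noisy_dev10.json"
    p.write_text(json.dumps({
        "success": outcome.success,
        "failure_mode": outcome.failure_mode,
        "activity": outcome.spike_train.activity,
    }, indent=1))
    written.append(p)

    # mini-population likelihood table (5 neurons, coarse grid)
    pop = build_population(5)
    lik = estimate_likelihood(
        pop, NoiseSpec.resistance_noise(0.10),
        stimulus_grid=np.linspace(-180.0, 180.0, 13, endpoint=False),
        repeats=50, seed=seed)
    rows = ["neuron,stimulus_deg,count,probability"]
    n, s, c = lik.table.shape
    for a in range(n):
        for j in range(s):
            for k in range(c):
                rows.append(f"{a},{lik.stimulus_grid[j]:.6g},{k},"
                            f"{lik.table[a, j, k]:.9g}")
    p = out / "likelihood_minipop.csv"
    p.write_text("\n".join(rows) + "\n")
    written.append(p)
    return written
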