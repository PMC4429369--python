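"""Operational-window search for successful spiking.

Two windows are computed.  The *static* window comes from four DC
requirements evaluated with the capacitors removed; it is a prerequisite
(necessary condition) for spiking:

  i   both switches off: the drop across S1 exceeds v_on (S1 can turn on),
  ii  S1 on / S2 off:    the drop across S2 exceeds v_on (S2 can turn on),
  iii S1 off / S2 on:    the drop across S2 falls below v_off (S2 can turn off),
  iv  both on:           the drop across S2 falls below v_off regardless of S1.

The *dynamic* (capacitance) window additionally requires that a full
time-domain simulation actually produces at least one completed S2
flicker within the drive window: the capacitors set the speed of voltage
redistribution, and an oversized C2 lets S1 recover its off-state before
S2 ever reaches its on-threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .circuit import DEFAULT_DT, raw_run, steady_state
from .params import NeuronCircuitParams, ThresholdSwitchSpec

__all__ = [
    "RequirementReport",
    "WindowGrid",
    "check_static_requirements",
    "scan_r2_window",
    "scan_capacitance_window",
]


@dataclass(frozen=True)
class RequirementReport:
    req_i: bool
    req_ii: bool
    req_iii: bool
    req_iv: bool

    @property
    def all_met(self) -> bool:
        return self.req_i and self.req_ii and self.req_iii and self.req_iv


@dataclass
class WindowGrid:
    """Boolean pass/fail mask over a two-parameter grid."""

    axis1_values: np.ndarray
    axis2_values: np.ndarray
    pass_mask: np.ndarray
    axis_labels: tuple[str, str]

    def __post_init__(self) -> None:
        expected = (len(self.axis1_values), len(self.axis2_values))
        if self.pass_mask.shape != expected:
            raise ValueError(f"pass_mask shape {self.pass_mask.shape} != {expected}")

    @property
    def pass_fraction(self) -> float:
        return float(np.mean(self.pass_mask))

    def to_long_frame(self):
        import pandas as pd

        a1, a2 = np.meshgrid(self.axis1_values, self.axis2_values, indexing="ij")
        return pd.DataFrame({
            self.axis_labels[0]: a1.ravel(),
            self.axis_labels[1]: a2.ravel(),
            "pass": self.pass_mask.ravel(),
        })


def check_static_requirements(params: NeuronCircuitParams,
                              i_in: float) -> RequirementReport:
    """Evaluate requirements i-iv via DC steady states (strict inequalities)."""

    def drop_s1(s1_on: bool, s2_on: bool) -> float:
        v1, _ = steady_state(params, s1_on, s2_on, i_in)
        return abs(v1 - params.v_dc1)

    def drop_s2(s1_on: bool, s2_on: bool) -> float:
        _, v2 = steady_state(params, s1_on, s2_on, i_in)
        return abs(v2 - params.v_dc2)

    return RequirementReport(
        req_i=drop_s1(False, False) > params.s1.v_on,
        req_ii=drop_s2(True, False) > params.s2.v_on,
        req_iii=drop_s2(False, True) < params.s2.v_off,
        req_iv=drop_s2(True, True) < params.s2.v_off,
    )


def scan_r2_window(
    params_template: NeuronCircuitParams,
    i_in_grid: np.ndarray,
    r2_grid: np.ndarray,
    roff_ron_ratio: float,
    voff_von_ratio: float,
    r_off: float = 1e6,
    v_on: float = 1.0,
) -> WindowGrid:
    """Static (I_in x R2) window at given switch-parameter ratios.

    R_off and v_on are held at their reference values; r_on = r_off/ratio
    and v_off = ratio * v_on.  A unit resistance ratio (no contrast) or a
    unit voltage ratio (no hysteresis) yields an empty window.
    """
    i_in_grid = np.asarray(i_in_grid, dtype=float)
    r2_grid = np.asarray(r2_grid, dtype=float)
    if i_in_grid.size == 0 or r2_grid.size == 0:
        raise ValueError("grids must be nonempty")
    if roff_ron_ratio <= 1 or not (0 < voff_von_ratio < 1):
        # degenerate switch: requirements ii and iii cannot both hold
        mask = np.zeros((i_in_grid.size, r2_grid.size), dtype=bool)
        return WindowGrid(i_in_grid, r2_grid, mask, ("i_in", "r2"))
    spec = ThresholdSwitchSpec(
        r_on=r_off / roff_ron_ratio, r_off=r_off,
        v_on=v_on, v_off=voff_von_ratio * v_on,
    )
    mask = np.zeros((i_in_grid.size, r2_grid.size), dtype=bool)
    for j, i_in in enumerate(i_in_grid):
        for k, r2 in enumerate(r2_grid):
            p = replace(params_template, r2=float(r2), s1=spec, s2=spec)
            mask[j, k] = check_static_requirements(p, float(i_in)).all_met
    return WindowGrid(i_in_grid, r2_grid, mask, ("i_in", "r2"))


def scan_capacitance_window(
    params_template: NeuronCircuitParams,
    i_in: float,
    c1_grid: np.ndarray,
    c2_grid: np.ndarray,
    duration: float = 30e-3,
    dt: float = DEFAULT_DT,
) -> WindowGrid:
    """Dynamic (C1 x C2) window: pass = at least one spike within the drive."""
    c1_grid = np.asarray(c1_grid, dtype=float)
    c2_grid = np.asarray(c2_grid, dtype=float)
    if c1_grid.size == 0 or c2_grid.size == 0:
        raise ValueError("grids must be nonempty")
    mask = np.zeros((c1_grid.size, c2_grid.size), dtype=bool)
    for j, c1 in enumerate(c1_grid):
        for k, c2 in enumerate(c2_grid):
            p = params_template.with_capacitances(float(c1), float(c2))
            res = raw_run(p, i_in, duration, dt)
            mask[j, k] = len(res.spike_times) >= 1
    return WindowGrid(c1_grid, c2_grid, mask, ("c1", "c2"))
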