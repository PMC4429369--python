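"""Phase-plane analysis on the (V2, V1) plane.

Because the switch resistances are binary, the vector field is piecewise
linear: each of the four switch configurations has its own pair of linear
nullclines and its own fixed point.  Spiking corresponds to a limit cycle
that hops between configurations as the trajectory crosses the four
threshold lines; the cycle is confined to a rectangle fixed by the dc
biases and the switching thresholds.

Lines are stored in the plot orientation used throughout (abscissa V2,
ordinate V1), i.e. V1 = slope * V2 + intercept.
"""

from __future__ import annotations

from dataclasses import dataclass

from .circuit import steady_state
from .params import NeuronCircuitParams, NeuronState

__all__ = [
    "Line",
    "NullclineSet",
    "LimitCycleBox",
    "nullclines",
    "fixed_point",
    "classify_point",
    "limit_cycle_box",
]


@dataclass(frozen=True)
class Line:
    """V1 = slope * V2 + intercept."""

    slope: float
    intercept: float

    def __call__(self, v2: float) -> float:
        return self.slope * v2 + self.intercept


@dataclass(frozen=True)
class NullclineSet:
    v1_nullcline: Line
    v2_nullcline: Line
    s1_on: bool
    s2_on: bool
    i_in: float


@dataclass(frozen=True)
class LimitCycleBox:
    """Confinement rectangle of the spiking limit cycle."""

    v2_min: float
    v2_max: float
    v1_min: float
    v1_max: float

    def contains(self, v2: float, v1: float, tol: float = 0.0) -> bool:
        return (self.v2_min - tol <= v2 <= self.v2_max + tol
                and self.v1_min - tol <= v1 <= self.v1_max + tol)


def nullclines(params: NeuronCircuitParams, s1_on: bool, s2_on: bool,
               i_in: float) -> NullclineSet:
    """Nullclines of the configuration's linear vector field.

    Setting dV1/dt = 0 gives V1 = [V2/R2 + V_dc1/R_S1 + I_in] / (1/R_S1 + 1/R2);
    a constant drive therefore shifts the V1-nullcline upward without
    changing its slope.  Setting dV2/dt = 0 gives
    V1 = R2 [(1/R2 + 1/R_S2 + 1/R_L) V2 - V_dc2/R_S2].
    """
    rs1 = params.s1.resistance(s1_on)
    rs2 = params.s2.resistance(s2_on)
    g1 = 1.0 / rs1 + 1.0 / params.r2
    v1_null = Line(
        slope=(1.0 / params.r2) / g1,
        intercept=(params.v_dc1 / rs1 + i_in) / g1,
    )
    g2 = 1.0 / params.r2 + 1.0 / rs2 + 1.0 / params.r_load
    v2_null = Line(
        slope=params.r2 * g2,
        intercept=-params.r2 * params.v_dc2 / rs2,
    )
    return NullclineSet(v1_null, v2_null, s1_on, s2_on, i_in)


def fixed_point(ncl: NullclineSet) -> tuple[float, float]:
    """Intersection (v2, v1) of the two nullclines.

    Raises on (near-)parallel lines.  Agrees with the DC steady state of
    the same switch configuration.
    """
    d = ncl.v1_nullcline.slope - ncl.v2_nullcline.slope
    if d == 0.0:
        raise ValueError("nullclines are parallel; no unique fixed point")
    v2 = (ncl.v2_nullcline.intercept - ncl.v1_nullcline.intercept) / d
    v1 = ncl.v1_nullcline(v2)
    return v2, v1


def classify_point(state: NeuronState, params: NeuronCircuitParams) -> str:
    """Label a phase-plane point by which on-thresholds it exceeds.

    Returns one of 'sub-threshold', 'S1-above', 'S2-above', 'both-above'.
    The S1 on-condition is |V1 - V_dc1| >= v_on, the S2 on-condition is
    |V2 - V_dc2| >= v_on.
    """
    s1_above = abs(state.v1 - params.v_dc1) >= params.s1.v_on
    s2_above = abs(state.v2 - params.v_dc2) >= params.s2.v_on
    if s1_above and s2_above:
        return "both-above"
    if s1_above:
        return "S1-above"
    if s2_above:
        return "S2-above"
    return "sub-threshold"


def limit_cycle_box(params: NeuronCircuitParams) -> LimitCycleBox:
    """Threshold rectangle confining the noise-free spiking limit cycle:
    -v_on + V_dc2 <= V2 <= -v_off + V_dc2 and v_off + V_dc1 <= V1 <= v_on + V_dc1.
    """
    return LimitCycleBox(
        v2_min=-params.s2.v_on + params.v_dc2,
        v2_max=-params.s2.v_off + params.v_dc2,
        v1_min=params.s1.v_off + params.v_dc1,
        v1_max=params.s1.v_on + params.v_dc1,
    )


def fixed_point_check(params: NeuronCircuitParams, s1_on: bool, s2_on: bool,
                      i_in: float) -> tuple[float, float]:
    """Convenience: nullcline intersection cross-checked against steady_state."""
    v2, v1 = fixed_point(nullclines(params, s1_on, s2_on, i_in))
    v1_dc, v2_dc = steady_state(params, s1_on, s2_on, i_in)
    if abs(v1 - v1_dc) > 1e-6 or abs(v2 - v2_dc) > 1e-6:
        raise AssertionError("nullcline intersection disagrees with DC solve")
    return v2, v1
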