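"""Domain types for the NLIF (neuristor-based leaky integrate-and-fire) neuron circuit.

The neuron is a two-node RC circuit in which each node is clamped to a dc
bias through a volatile threshold switch.  A threshold switch is a
two-terminal hysteretic element: it jumps from a high-resistance off-state
(``r_off``) to a low-resistance on-state (``r_on``) when the magnitude of
the voltage across it reaches ``v_on``, and relaxes back when it drops to
``v_off`` (with ``v_off < v_on``, the hysteresis band).  Both I-V branches
are taken as linear, so the switch is fully described by four parameters.

All quantities are SI (volts, amperes, seconds, farads, ohms).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "ThresholdSwitchSpec",
    "SwitchState",
    "NeuronCircuitParams",
    "NeuronState",
]


@dataclass(frozen=True)
class ThresholdSwitchSpec:
    """Parameters of a volatile threshold switch.

    Defaults are the reference device used throughout: 50 kΩ on-state,
    1 MΩ off-state (resistance contrast 20), thresholds 1.0 V / 0.5 V.
    """

    r_on: float = 50e3
    r_off: float = 1e6
    v_on: float = 1.0
    v_off: float = 0.5

    def __post_init__(self) -> None:
        if not (self.r_off > self.r_on > 0):
            raise ValueError(
                f"require r_off > r_on > 0, got r_on={self.r_on!r}, r_off={self.r_off!r}"
            )
        if not (self.v_on > self.v_off > 0):
            raise ValueError(
                f"require v_on > v_off > 0, got v_on={self.v_on!r}, v_off={self.v_off!r}"
            )

    def resistance(self, is_on: bool) -> float:
        return self.r_on if is_on else self.r_off


@dataclass(frozen=True)
class SwitchState:
    """A threshold switch together with its current binary state."""

    is_on: bool
    spec: ThresholdSwitchSpec

    @property
    def resistance(self) -> float:
        """Effective resistance: exactly ``spec.r_on`` when on, else ``spec.r_off``."""
        return self.spec.resistance(self.is_on)


@dataclass(frozen=True)
class NeuronCircuitParams:
    """Full parameterization of the NLIF neuron circuit.

    ``r1`` sits in series with the (ideal) input current source and hence
    carries no dynamic role; it is stored for completeness only.  The two
    dc sources are antisymmetric by default, ``v_dc2 = -v_dc1 = 0.9 V``,
    chosen at 90% of ``v_on`` so a small input current can trigger the
    switches.  Default values are the reference operating point used for
    the response-function and tuning simulations (the 3 nF / 2 nF
    capacitance pair inside the operational window).
    """

    r1: float = 100e3
    r2: float = 100e3
    r_load: float = 1e9
    c1: float = 3e-9
    c2: float = 2e-9
    v_dc1: float = -0.9
    v_dc2: float = 0.9
    s1: ThresholdSwitchSpec = field(default_factory=ThresholdSwitchSpec)
    s2: ThresholdSwitchSpec = field(default_factory=ThresholdSwitchSpec)

    def __post_init__(self) -> None:
        for name in ("c1", "c2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("r2", "r_load"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def with_capacitances(self, c1: float, c2: float) -> "NeuronCircuitParams":
        return replace(self, c1=c1, c2=c2)

    def with_switches(
        self,
        s1: ThresholdSwitchSpec | None = None,
        s2: ThresholdSwitchSpec | None = None,
    ) -> "NeuronCircuitParams":
        return replace(self, s1=s1 or self.s1, s2=s2 or self.s2)


@dataclass(frozen=True)
class NeuronState:
    """Instantaneous circuit state: the membrane potential ``v2``, the
    auxiliary node voltage ``v1``, both switch states and the time."""

    v1: float
    v2: float
    s1_state: SwitchState
    s2_state: SwitchState
    t: float = 0.0
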