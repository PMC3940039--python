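"""Population thermodynamics for two-state conformational equilibria.

A measured population ratio converts to a free-energy difference via
DeltaG = -R T ln(p_minor / p_major), positive when the minor state lies
higher in free energy.  Differences of DeltaG across variants (DeltaDeltaG)
quantify how a substitution shifts the equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

from .errors import ConfigurationError

R_GAS = 8.314  # J mol^-1 K^-1


@dataclass(frozen=True)
class PopulationPair:
    """Minor/major state populations at a temperature (K)."""

    p_minor: float
    p_major: float | None = None
    temperature: float = 298.15

    def __post_init__(self):
        if self.p_major is None:
            object.__setattr__(self, "p_major", 1.0 - self.p_minor)
        if not (0.0 < self.p_minor < 1.0 and 0.0 < self.p_major < 1.0):
            raise ValueError("populations must lie strictly inside (0, 1)")
        if abs(self.p_minor + self.p_major - 1.0) > 1e-9:
            raise ValueError("populations must sum to 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def delta_g(populations: PopulationPair) -> float:
    """Free-energy gap of the minor state, kJ/mol."""
    return (
        -R_GAS
        * populations.temperature
        * math.log(populations.p_minor / populations.p_major)
        / 1000.0
    )


def delta_delta_g(state1: PopulationPair, state2: PopulationPair) -> float:
    """DeltaG(state1) - DeltaG(state2) at a shared temperature, kJ/mol."""
    if abs(state1.temperature - state2.temperature) > 1e-9:
        raise ConfigurationError(
            f"temperature mismatch: {state1.temperature} K vs {state2.temperature} K"
        )
    return delta_g(state1) - delta_g(state2)
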