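"""Gibbs relations: -RT ln(K_a) = ΔG° = ΔH° - TΔS°."""

from __future__ import annotations

import math
from dataclasses import dataclass

# Gas constant, kcal mol^-1 K^-1 (1.9872 cal mol^-1 K^-1).
R_KCAL = 1.9872e-3


@dataclass(frozen=True)
class ThermoState:
    """Standard-state binding thermodynamics at temperature T (kcal/mol)."""

    temperature: float
    delta_g: float
    delta_h: float | None = None
    delta_s: float | None = None  # kcal mol^-1 K^-1

    def __post_init__(self) -> None:
        if self.delta_h is not None and self.delta_s is not None:
            gap = abs(self.delta_g - (self.delta_h - self.temperature * self.delta_s))
            if gap > 1e-9:
                raise ValueError(f"ΔG° != ΔH° - TΔS° (gap {gap:.3e} kcal/mol)")

    @property
    def ka(self) -> float:
        return math.exp(-self.delta_g / (R_KCAL * self.temperature))

    @property
    def kd(self) -> float:
        return 1.0 / self.ka


def gibbs(ka: float, temperature: float, delta_h: float | None = None) -> ThermoState:
    """Thermodynamic state from an association constant.

    ΔG° = -RT ln(K_a); if ΔH° is supplied, ΔS° = (ΔH° - ΔG°)/T.
    """
    if ka <= 0:
        raise ValueError("K_a must be > 0")
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    dg = -R_KCAL * temperature * math.log(ka)
    ds = None if delta_h is None else (delta_h - dg) / temperature
    return ThermoState(
        temperature=temperature, delta_g=dg, delta_h=delta_h, delta_s=ds
    )
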