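"""Differential scanning calorimetry: two-state excess heat capacity.

The baseline-subtracted thermogram of a two-state unfolding transition is

    ΔC_p(T) = K(T) ΔH_cal ΔH_vH / [(1 + K(T))² R T²]

where K(T) is the two-state equilibrium constant, parameterized by the
van't Hoff law anchored at the midpoint, K(T) = exp[(ΔH_vH/R)(1/T_m - 1/T)],
so that K(T_m) = 1 and the curve peaks at T_m with height
ΔH_cal·ΔH_vH/(4 R T_m²).  The integral of the curve over temperature is
ΔH_cal; the ratio ΔH_vH/ΔH_cal is the usual two-state cooperativity check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize as lm_minimize

from .base import FitConvergenceError, FitResults
from .thermo import R_KCAL

CELSIUS = 273.15


@dataclass(frozen=True)
class DSCParams:
    """Two-state unfolding parameters: T_m (K), ΔH_cal and ΔH_vH (kcal/mol)."""

    tm: float
    delta_h_cal: float
    delta_h_vh: float | None = None  # defaults to ΔH_cal (pure two-state)

    def __post_init__(self) -> None:
        if self.tm <= 0:
            raise ValueError("T_m must be > 0 K")
        if self.delta_h_cal <= 0:
            raise ValueError("ΔH_cal must be > 0")
        if self.delta_h_vh is None:
            object.__setattr__(self, "delta_h_vh", self.delta_h_cal)
        if self.delta_h_vh <= 0:
            raise ValueError("ΔH_vH must be > 0")

    @property
    def tm_celsius(self) -> float:
        return self.tm - CELSIUS

    @property
    def peak_height(self) -> float:
        """ΔC_p at T_m: ΔH_cal·ΔH_vH/(4 R T_m²), kcal mol⁻¹ K⁻¹."""
        return self.delta_h_cal * self.delta_h_vh / (4.0 * R_KCAL * self.tm**2)


def excess_heat_capacity(temperature, params: DSCParams):
    """ΔC_p(T) (kcal mol⁻¹ K⁻¹) of the two-state transition."""
    t = np.asarray(temperature, dtype=float)
    k = np.exp((params.delta_h_vh / R_KCAL) * (1.0 / params.tm - 1.0 / t))
    return k * params.delta_h_cal * params.delta_h_vh / (
        (1.0 + k) ** 2 * R_KCAL * t**2
    )


def simulate_thermogram(
    params: DSCParams,
    t_min_c: float = 20.0,
    t_max_c: float = 120.0,
    step: float = 0.1,
    noise: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic baseline-subtracted thermogram on a Celsius scan range.

    ``noise`` is the Gaussian σ as a fraction of the peak height (e.g.
    0.005 for 0.5% peak noise)."""
    t = np.arange(t_min_c, t_max_c + step / 2, step) + CELSIUS
    cp = excess_heat_capacity(t, params)
    if noise > 0:
        rng = np.random.default_rng(seed)
        cp = cp + rng.normal(0.0, noise * params.peak_height, len(t))
    return pd.DataFrame({"temperature_K": t, "excess_cp": cp})


class DscModel:
    """Two-state DSC model bound to a thermogram (columns ``temperature_K``
    and ``excess_cp``); ``fit()`` recovers T_m, ΔH_cal and ΔH_vH."""

    def __init__(self, data: pd.DataFrame):
        if len(data) < 20:
            raise ValueError("thermogram too short to fit")
        self.data = data.reset_index(drop=True)

    @classmethod
    def from_simulation(
        cls, params: DSCParams, noise: float = 0.0, seed: int | None = None, **kw
    ) -> "DscModel":
        return cls(simulate_thermogram(params, noise=noise, seed=seed, **kw))

    def _initial_guess(self) -> DSCParams:
        t = self.data["temperature_K"].to_numpy()
        cp = self.data["excess_cp"].to_numpy()
        tm0 = float(t[np.argmax(cp)])
        dh_cal0 = float(max(np.trapezoid(cp, t), 1.0))
        dh_vh0 = float(max(4.0 * R_KCAL * tm0**2 * cp.max() / dh_cal0, 1.0))
        return DSCParams(tm=tm0, delta_h_cal=dh_cal0, delta_h_vh=dh_vh0)

    def fit(self, start: DSCParams | None = None) -> FitResults:
        t = self.data["temperature_K"].to_numpy()
        cp = self.data["excess_cp"].to_numpy()
        start = start or self._initial_guess()

        pars = Parameters()
        pars.add("tm", value=start.tm, min=t.min(), max=t.max())
        pars.add("dh_cal", value=start.delta_h_cal, min=1e-3)
        pars.add("dh_vh", value=start.delta_h_vh, min=1e-3)

        def residual(p):
            model = excess_heat_capacity(
                t, DSCParams(p["tm"].value, p["dh_cal"].value, p["dh_vh"].value)
            )
            return model - cp

        out = lm_minimize(residual, pars, method="leastsq", xtol=1e-12, ftol=1e-12)
        if not out.success:
            raise FitConvergenceError(f"DSC fit failed: {out.message}")
        fitted = DSCParams(
            out.params["tm"].value, out.params["dh_cal"].value,
            out.params["dh_vh"].value,
        )
        return FitResults(
            model="two-state DSC",
            params={
                "tm": fitted.tm,
                "delta_h_cal": fitted.delta_h_cal,
                "delta_h_vh": fitted.delta_h_vh,
            },
            stderr={
                "tm": out.params["tm"].stderr,
                "delta_h_cal": out.params["dh_cal"].stderr,
                "delta_h_vh": out.params["dh_vh"].stderr,
            },
            success=bool(out.success),
            redchi=out.redchi,
            extra={
                "tm_celsius": fitted.tm_celsius,
                "cooperativity_ratio": fitted.delta_h_vh / fitted.delta_h_cal,
                "peak_height": fitted.peak_height,
            },
            minimizer_result=out,
        )
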