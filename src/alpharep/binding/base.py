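"""Shared results container for the binding-model fits."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FitResults:
    """Parameter estimates with uncertainties from a model fit.

    ``params``/``stderr`` map parameter names to values; ``extra`` carries
    derived quantities (e.g. K_d from SPR rates).  ``minimizer_result``
    keeps the underlying lmfit object for diagnostics.
    """

    model: str
    params: dict[str, float]
    stderr: dict[str, float | None]
    success: bool
    redchi: float | None = None
    extra: dict[str, float] = field(default_factory=dict)
    minimizer_result: object | None = None

    def __getitem__(self, name: str) -> float:
        return self.params[name]

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "parameter": name,
                "value": value,
                "stderr": self.stderr.get(name),
            }
            for name, value in self.params.items()
        ]
        rows += [
            {"parameter": f"{name} (derived)", "value": value, "stderr": None}
            for name, value in self.extra.items()
        ]
        return pd.DataFrame(rows)

    def __repr__(self) -> str:
        lines = [f"<FitResults: {self.model} "
                 f"({'converged' if self.success else 'NOT CONVERGED'})>"]
        for name, value in self.params.items():
            se = self.stderr.get(name)
            se_txt = f" +/- {se:.3g}" if se is not None and np.isfinite(se) else ""
            lines.append(f"  {name} = {value:.6g}{se_txt}")
        for name, value in self.extra.items():
            lines.append(f"  {name} = {value:.6g} (derived)")
        return "\n".join(lines)


class FitConvergenceError(RuntimeError):
    """Raised when a nonlinear fit fails to converge; carries diagnostics."""
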