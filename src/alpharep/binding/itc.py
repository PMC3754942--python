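"""Isothermal titration calorimetry: one-site and competitive-displacement
models.

The one-site model tracks the exact 1:1 equilibrium in the calorimeter cell
across a titration.  Concentrations follow the perfusion (overflow)
convention: each injection of volume dv into a constant cell volume V0
displaces a fraction dv/V0 of the current cell contents, so existing
species are diluted by (1 - dv/V0) while the titrant gains
[syringe]·dv/V0.  The heat of injection i is the change in total
bound-complex heat content, counting complex carried out in the overflow:

    q_i = V0 · ΔH · ([RL]_i - [RL]_{i-1} · (1 - dv_i/V0))

For very tight binders the direct titration is too steep to resolve K_d;
the displacement experiment titrates the tight ligand into receptor
pre-bound to a characterized weaker ligand.  The apparent association
constant is K_app = K_a_tight / (1 + K_a_weak [weak]), which moves the
effective affinity into the measurable range.  The full ternary
equilibrium (receptor R, tight ligand A, weak ligand B competing for the
same site) is solved exactly by bracketed root-finding on the receptor
mass balance, and the fit recovers the tight ligand's K_d and ΔH with the
weak ligand's parameters held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize as lm_minimize
from scipy.optimize import brentq

from .base import FitConvergenceError, FitResults


@dataclass(frozen=True)
class OneSiteParams:
    """1:1 binding parameters: K_d (M), stoichiometry n, ΔH (kcal/mol)."""

    kd: float
    n: float = 1.0
    delta_h: float = -10.0

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("K_d must be > 0")
        if self.n <= 0:
            raise ValueError("stoichiometry must be > 0")

    @property
    def ka(self) -> float:
        return 1.0 / self.kd


@dataclass(frozen=True)
class CompetitionParams:
    """Displacement-titration parameters.

    The tight (titrated) ligand is characterized by ``strong``; the weak
    ligand pre-loaded in the cell has fixed ``weak`` parameters and initial
    cell concentration ``weak_conc`` (M).
    """

    strong: OneSiteParams
    weak: OneSiteParams
    weak_conc: float

    def __post_init__(self) -> None:
        if self.weak_conc < 0:
            raise ValueError("weak-ligand concentration must be >= 0")


@dataclass(frozen=True)
class ITCExperiment:
    """Titration geometry: cell volume (L), concentrations (M), injection
    volumes (L), temperature (K)."""

    cell_volume: float = 200e-6
    cell_conc: float = 30e-6
    syringe_conc: float = 350e-6
    injection_volumes: tuple[float, ...] = field(default=tuple([2e-6] * 20))
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if min(self.cell_volume, self.cell_conc, self.syringe_conc) <= 0:
            raise ValueError("volumes and concentrations must be > 0")
        if any(v <= 0 for v in self.injection_volumes):
            raise ValueError("injection volumes must be > 0")


def wiseman_c(params: OneSiteParams, expt: ITCExperiment) -> float:
    """Wiseman parameter c = n·[cell]/K_d, governing isotherm shape."""
    return params.n * expt.cell_conc / params.kd


def apparent_ka(comp: CompetitionParams) -> float:
    """Apparent association constant of the tight ligand in the presence of
    the weak competitor: K_app = K_a_tight / (1 + K_a_weak [weak])."""
    return comp.strong.ka / (1.0 + comp.weak.ka * comp.weak_conc)


def bound_complex(r_total: float, l_total: float, kd: float) -> float:
    """Exact 1:1 complex concentration from the binding quadratic."""
    s = r_total + l_total + kd
    disc = s * s - 4.0 * r_total * l_total
    return 0.5 * (s - np.sqrt(np.maximum(disc, 0.0)))


def ternary_equilibrium(
    r_total: float,
    a_total: float,
    b_total: float,
    ka_a: float,
    ka_b: float,
    tol: float = 1e-12,
) -> tuple[float, float, float]:
    """Free receptor and both complexes for two ligands sharing one site.

    Solves the receptor mass balance (a cubic in free receptor) by
    bracketed root-finding; the balance is strictly increasing in free R,
    so the root on [0, R_total] is unique.
    """
    if min(r_total, a_total, b_total) < 0 or min(ka_a, ka_b) <= 0:
        raise ValueError("concentrations must be >= 0 and K_a values > 0")
    if r_total == 0:
        return 0.0, 0.0, 0.0

    def balance(r: float) -> float:
        ra = ka_a * r * a_total / (1.0 + ka_a * r)
        rb = ka_b * r * b_total / (1.0 + ka_b * r)
        return r + ra + rb - r_total

    lo, hi = 0.0, r_total
    if balance(hi) < 0:
        raise FitConvergenceError("receptor mass balance not bracketed")
    r_free = brentq(balance, lo, hi, xtol=tol * max(r_total, 1e-30), rtol=8.9e-16)
    ra = ka_a * r_free * a_total / (1.0 + ka_a * r_free)
    rb = ka_b * r_free * b_total / (1.0 + ka_b * r_free)
    return float(r_free), float(ra), float(rb)


def _titration_concentrations(expt: ITCExperiment):
    """Per-injection dilution factors and titrant increments."""
    dv = np.asarray(expt.injection_volumes, dtype=float)
    d = dv / expt.cell_volume
    return d


def one_site_heats(params: OneSiteParams, expt: ITCExperiment) -> pd.DataFrame:
    """Noise-free per-injection heats (kcal) for the one-site model."""
    d = _titration_concentrations(expt)
    m_tot = expt.cell_conc
    x_tot = 0.0
    rl_prev = 0.0
    rows = []
    for i, di in enumerate(d, start=1):
        f = 1.0 - di
        m_tot *= f
        x_tot = x_tot * f + expt.syringe_conc * di
        rl = bound_complex(params.n * m_tot, x_tot, params.kd)
        q = expt.cell_volume * params.delta_h * (rl - rl_prev * f)
        rows.append(
            {
                "injection": i,
                "volume": expt.injection_volumes[i - 1],
                "molar_ratio": x_tot / m_tot,
                "heat": q,
                "ndh": q / (expt.syringe_conc * expt.injection_volumes[i - 1]),
            }
        )
        rl_prev = rl
    return pd.DataFrame(rows)


def simulate_itc(
    params: OneSiteParams,
    expt: ITCExperiment,
    noise: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulated titration; ``noise`` is the Gaussian σ as a fraction of the
    largest absolute injection heat (e.g. 0.02 for 2% peak noise)."""
    df = one_site_heats(params, expt)
    if noise > 0:
        rng = np.random.default_rng(seed)
        sigma = noise * np.abs(df["heat"]).max()
        df["heat"] = df["heat"] + rng.normal(0.0, sigma, len(df))
        df["ndh"] = df["heat"] / (expt.syringe_conc * df["volume"])
    return df


def competition_heats(comp: CompetitionParams, expt: ITCExperiment) -> pd.DataFrame:
    """Noise-free displacement-titration heats (kcal).

    The cell holds receptor at ``expt.cell_conc`` pre-mixed with the weak
    ligand; the syringe titrates the tight ligand.
    """
    d = _titration_concentrations(expt)
    r_tot = expt.cell_conc
    b_tot = comp.weak_conc
    a_tot = 0.0
    ra_prev = rb_prev = 0.0
    # heat reference state: cell before the first injection
    _, _, rb_prev = ternary_equilibrium(
        comp.strong.n * r_tot, 0.0, b_tot, comp.strong.ka, comp.weak.ka
    )
    rows = []
    for i, di in enumerate(d, start=1):
        f = 1.0 - di
        r_tot *= f
        b_tot *= f
        a_tot = a_tot * f + expt.syringe_conc * di
        _, ra, rb = ternary_equilibrium(
            comp.strong.n * r_tot, a_tot, b_tot, comp.strong.ka, comp.weak.ka
        )
        q = expt.cell_volume * (
            comp.strong.delta_h * (ra - ra_prev * f)
            + comp.weak.delta_h * (rb - rb_prev * f)
        )
        rows.append(
            {
                "injection": i,
                "volume": expt.injection_volumes[i - 1],
                "molar_ratio": a_tot / r_tot,
                "heat": q,
                "ndh": q / (expt.syringe_conc * expt.injection_volumes[i - 1]),
            }
        )
        ra_prev, rb_prev = ra, rb
    return pd.DataFrame(rows)


def simulate_competition(
    comp: CompetitionParams,
    expt: ITCExperiment,
    noise: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    df = competition_heats(comp, expt)
    if noise > 0:
        rng = np.random.default_rng(seed)
        sigma = noise * np.abs(df["heat"]).max()
        df["heat"] = df["heat"] + rng.normal(0.0, sigma, len(df))
        df["ndh"] = df["heat"] / (expt.syringe_conc * df["volume"])
    return df


class OneSiteItcModel:
    """One-binding-site ITC model bound to a titration data set.

    ``data`` needs columns ``injection`` and ``heat`` (kcal); the
    experiment supplies geometry and concentrations.  ``fit()`` runs
    Levenberg-Marquardt least squares from curve-shape heuristics and
    returns a :class:`FitResults` with K_d, n and ΔH.
    """

    def __init__(self, data: pd.DataFrame, experiment: ITCExperiment):
        if len(data) < 10:
            raise ValueError("one-site fit needs at least 10 injections")
        self.data = data.reset_index(drop=True)
        self.experiment = experiment

    @classmethod
    def from_simulation(
        cls,
        params: OneSiteParams,
        experiment: ITCExperiment,
        noise: float = 0.0,
        seed: int | None = None,
    ) -> "OneSiteItcModel":
        return cls(simulate_itc(params, experiment, noise, seed), experiment)

    def _initial_guess(self) -> OneSiteParams:
        expt = self.experiment
        heats = self.data["heat"].to_numpy()
        dv = np.asarray(expt.injection_volumes[: len(heats)])
        # early injections: essentially all injectant binds
        dh0 = float(heats[0] / (expt.syringe_conc * dv[0]))
        # stoichiometry: molar ratio where cumulative heat crosses half-total
        ratio = self.data["molar_ratio"].to_numpy() if "molar_ratio" in self.data \
            else np.cumsum(expt.syringe_conc * dv) / expt.cell_conc
        cum = np.cumsum(heats)
        half = 0.5 * cum[-1]
        idx = int(np.argmin(np.abs(cum - half)))
        n0 = float(np.clip(ratio[idx], 0.2, 5.0))
        return OneSiteParams(kd=0.05 * expt.cell_conc, n=n0, delta_h=dh0)

    def fit(self, start: OneSiteParams | None = None) -> FitResults:
        expt = self.experiment
        heats = self.data["heat"].to_numpy()
        start = start or self._initial_guess()

        pars = Parameters()
        pars.add("log10_kd", value=np.log10(start.kd), min=-12.0, max=-2.0)
        pars.add("n", value=start.n, min=1e-3, max=10.0)
        pars.add("delta_h", value=start.delta_h)

        def residual(p):
            model = one_site_heats(
                OneSiteParams(10.0 ** p["log10_kd"].value, p["n"].value,
                              p["delta_h"].value),
                expt,
            )["heat"].to_numpy()
            return model - heats

        out = lm_minimize(residual, pars, method="leastsq",
                          xtol=1e-10, ftol=1e-10)
        if not out.success:
            raise FitConvergenceError(f"one-site ITC fit failed: {out.message}")
        kd = 10.0 ** out.params["log10_kd"].value
        se_log = out.params["log10_kd"].stderr
        kd_se = kd * np.log(10.0) * se_log if se_log is not None else None
        return FitResults(
            model="one-site ITC",
            params={
                "kd": kd,
                "n": out.params["n"].value,
                "delta_h": out.params["delta_h"].value,
            },
            stderr={
                "kd": kd_se,
                "n": out.params["n"].stderr,
                "delta_h": out.params["delta_h"].stderr,
            },
            success=bool(out.success),
            redchi=out.redchi,
            extra={"ka": 1.0 / kd, "wiseman_c": expt.cell_conc
                   * out.params["n"].value / kd},
            minimizer_result=out,
        )


class CompetitionItcModel:
    """Displacement-titration model: recovers the tight ligand's K_d and ΔH
    with the weak ligand's K_d, ΔH and concentration held fixed."""

    def __init__(
        self,
        data: pd.DataFrame,
        experiment: ITCExperiment,
        weak: OneSiteParams,
        weak_conc: float,
    ):
        if len(data) < 10:
            raise ValueError("competition fit needs at least 10 injections")
        self.data = data.reset_index(drop=True)
        self.experiment = experiment
        self.weak = weak
        self.weak_conc = weak_conc

    @classmethod
    def from_simulation(
        cls,
        comp: CompetitionParams,
        experiment: ITCExperiment,
        noise: float = 0.0,
        seed: int | None = None,
    ) -> "CompetitionItcModel":
        return cls(
            simulate_competition(comp, experiment, noise, seed),
            experiment,
            comp.weak,
            comp.weak_conc,
        )

    def fit(self, start: OneSiteParams | None = None) -> FitResults:
        expt = self.experiment
        heats = self.data["heat"].to_numpy()
        if start is None:
            # apparent one-site estimate, then undo the competition factor
            apparent = OneSiteItcModel(self.data, expt)._initial_guess()
            ka_app = 1.0 / apparent.kd
            ka0 = ka_app * (1.0 + self.weak.ka * self.weak_conc)
            start = OneSiteParams(kd=1.0 / ka0, n=apparent.n,
                                  delta_h=apparent.delta_h)

        pars = Parameters()
        pars.add("log10_kd", value=np.log10(start.kd), min=-13.0, max=-3.0)
        pars.add("n", value=start.n, min=1e-3, max=10.0)
        pars.add("delta_h", value=start.delta_h)

        def residual(p):
            comp = CompetitionParams(
                strong=OneSiteParams(10.0 ** p["log10_kd"].value, p["n"].value,
                                     p["delta_h"].value),
                weak=self.weak,
                weak_conc=self.weak_conc,
            )
            return competition_heats(comp, expt)["heat"].to_numpy() - heats

        out = lm_minimize(residual, pars, method="leastsq",
                          xtol=1e-10, ftol=1e-10)
        if not out.success:
            raise FitConvergenceError(f"competition ITC fit failed: {out.message}")
        kd = 10.0 ** out.params["log10_kd"].value
        se_log = out.params["log10_kd"].stderr
        comp = CompetitionParams(
            strong=OneSiteParams(kd, out.params["n"].value,
                                 out.params["delta_h"].value),
            weak=self.weak,
            weak_conc=self.weak_conc,
        )
        return FitResults(
            model="competitive-displacement ITC",
            params={
                "kd": kd,
                "n": out.params["n"].value,
                "delta_h": out.params["delta_h"].value,
            },
            stderr={
                "kd": kd * np.log(10.0) * se_log if se_log is not None else None,
                "n": out.params["n"].stderr,
                "delta_h": out.params["delta_h"].stderr,
            },
            success=bool(out.success),
            redchi=out.redchi,
            extra={"ka": 1.0 / kd, "k_app": apparent_ka(comp),
                   "kd_app": 1.0 / apparent_ka(comp)},
            minimizer_result=out,
        )
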