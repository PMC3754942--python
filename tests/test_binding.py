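"""Binding-model simulators, equilibrium solvers, and fit recoveries."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from alpharep.binding import (
    CompetitionItcModel,
    CompetitionParams,
    DSCParams,
    DscModel,
    ITCExperiment,
    OneSiteItcModel,
    OneSiteParams,
    R_KCAL,
    SPRKinetics,
    SprModel,
    apparent_ka,
    bound_complex,
    excess_heat_capacity,
    gibbs,
    simulate_competition,
    simulate_itc,
    simulate_sensorgrams,
    simulate_thermogram,
    spr_kd,
    ternary_equilibrium,
    wiseman_c,
)
from alpharep.binding.dsc import CELSIUS
from alpharep.binding.itc import competition_heats, one_site_heats


class TestEquilibriumSolvers:
    def test_quadratic_vs_numerical_root_oracle(self):
        rng = np.random.default_rng(41)
        for _ in range(5):
            rt = 10.0 ** rng.uniform(-7, -4)
            lt = 10.0 ** rng.uniform(-7, -4)
            kd = 10.0 ** rng.uniform(-9, -5)
            rl = bound_complex(rt, lt, kd)

            # independent oracle: minimize the squared mass-action residual
            def residual(x, rt=rt, lt=lt, kd=kd):
                return ((rt - x) * (lt - x) - kd * x) ** 2

            opt = minimize_scalar(residual, bounds=(0.0, min(rt, lt)),
                                  method="bounded",
                                  options={"xatol": 1e-18})
            assert rl == pytest.approx(opt.x, rel=1e-6, abs=1e-15)
            # physical bounds
            assert 0 <= rl <= min(rt, lt)

    def test_ternary_vs_brute_force_mass_balance(self):
        rng = np.random.default_rng(43)
        for _ in range(5):
            rt, at, bt = (10.0 ** rng.uniform(-6, -4) for _ in range(3))
            ka_a = 10.0 ** rng.uniform(6, 9)
            ka_b = 10.0 ** rng.uniform(5, 8)
            r, ra, rb = ternary_equilibrium(rt, at, bt, ka_a, ka_b)
            # mass balances close to 1e-9 relative
            assert r + ra + rb == pytest.approx(rt, rel=1e-9)
            a_free = at - ra
            b_free = bt - rb
            assert ra == pytest.approx(ka_a * r * a_free, rel=1e-6)
            assert rb == pytest.approx(ka_b * r * b_free, rel=1e-6)

    def test_ternary_degenerates_to_one_site(self):
        # no competing strong ligand: complex equals the binding quadratic
        rt, bt, kd_b = 25e-6, 43e-6, 141e-9
        _, ra, rb = ternary_equilibrium(rt, 0.0, bt, 1e9, 1.0 / kd_b)
        assert ra == 0.0
        assert rb == pytest.approx(bound_complex(rt, bt, kd_b), rel=1e-9)


class TestOneSiteItc:
    def test_heats_vanish_past_saturation(self, a3_ba317_setup):
        params, expt = a3_ba317_setup
        expt = ITCExperiment(cell_conc=expt.cell_conc, syringe_conc=expt.syringe_conc,
                             injection_volumes=tuple([2e-6] * 40))
        heats = one_site_heats(params, expt)["heat"].to_numpy()
        assert abs(heats[-1]) < 0.01 * abs(heats[0])

    def test_cumulative_heat_approaches_site_capacity(self, a3_ba317_setup):
        params, expt = a3_ba317_setup
        heats = one_site_heats(params, expt)["heat"].to_numpy()
        capacity = params.n * expt.cell_conc * expt.cell_volume * params.delta_h
        # within dilution corrections the total heat matches the site capacity
        assert heats.sum() == pytest.approx(capacity, rel=0.12)

    def test_wiseman_c_for_direct_titration(self, a3_ba317_setup):
        params, expt = a3_ba317_setup
        assert wiseman_c(params, expt) == pytest.approx(191, abs=1)

    def test_sigmoid_inflection_near_stoichiometry(self, a3_ba317_setup):
        params, expt = a3_ba317_setup
        df = one_site_heats(params, expt)
        steps = np.abs(np.diff(df["heat"].to_numpy()))
        ratio_at_steepest = df["molar_ratio"].to_numpy()[np.argmax(steps)]
        assert ratio_at_steepest == pytest.approx(params.n, abs=0.2)

    def test_zero_noise_exact_recovery(self, a3_ba317_setup):
        params, expt = a3_ba317_setup
        res = OneSiteItcModel.from_simulation(params, expt).fit()
        assert res["kd"] == pytest.approx(params.kd, rel=1e-6)
        assert res["n"] == pytest.approx(params.n, rel=1e-6)
        assert res["delta_h"] == pytest.approx(params.delta_h, rel=1e-6)

    def test_simulation_seeded(self, a3_ba317_setup):
        params, expt = a3_ba317_setup
        a = simulate_itc(params, expt, noise=0.02, seed=5)
        b = simulate_itc(params, expt, noise=0.02, seed=5)
        assert np.allclose(a["heat"], b["heat"])

    def test_too_few_injections_rejected(self, a3_ba317_setup):
        params, expt = a3_ba317_setup
        short = ITCExperiment(cell_conc=30e-6, syringe_conc=350e-6,
                              injection_volumes=tuple([2e-6] * 5))
        with pytest.raises(ValueError):
            OneSiteItcModel(simulate_itc(params, short), short)


class TestCompetition:
    def test_apparent_ka_printed_arithmetic(self):
        comp = CompetitionParams(
            strong=OneSiteParams(3.7e-9), weak=OneSiteParams(141e-9),
            weak_conc=43e-6,
        )
        assert apparent_ka(comp) == pytest.approx(8.8e5, rel=0.01)
        assert 1.0 / apparent_ka(comp) == pytest.approx(1.13e-6, rel=0.01)

    def test_apparent_ka_limits(self):
        strong = OneSiteParams(3.7e-9)
        none = CompetitionParams(strong, OneSiteParams(141e-9), 0.0)
        assert apparent_ka(none) == pytest.approx(strong.ka)
        feeble = CompetitionParams(strong, OneSiteParams(1e3), 43e-6)
        assert apparent_ka(feeble) == pytest.approx(strong.ka, rel=1e-3)

    def test_apparent_ka_monotone_in_competitor(self):
        strong, weak = OneSiteParams(3.7e-9), OneSiteParams(141e-9)
        kas = [apparent_ka(CompetitionParams(strong, weak, c))
               for c in (0.0, 1e-6, 1e-5, 1e-4)]
        assert all(a > b for a, b in zip(kas, kas[1:]))

    def test_no_strong_ligand_reduces_to_one_site(self):
        weak = OneSiteParams(141e-9, 1.0, -10.0)
        expt = ITCExperiment(cell_conc=25e-6, syringe_conc=350e-6)
        comp = CompetitionParams(
            strong=OneSiteParams(1e-3, 1.0, 0.0),  # never binds, no heat
            weak=weak, weak_conc=0.0,
        )
        # cell pre-loaded with nothing: heats all come from the (absent) weak
        # ligand, so the titration of a non-binding, heat-free ligand is flat
        heats = competition_heats(comp, expt)["heat"].to_numpy()
        assert np.allclose(heats, 0.0, atol=1e-12)

    def test_zero_noise_exact_recovery(self):
        comp = CompetitionParams(
            strong=OneSiteParams(3.7e-9, 1.0, -12.0),
            weak=OneSiteParams(141e-9, 1.0, -10.0),
            weak_conc=43e-6,
        )
        expt = ITCExperiment(cell_conc=25e-6, syringe_conc=350e-6)
        res = CompetitionItcModel.from_simulation(comp, expt).fit()
        assert res["kd"] == pytest.approx(3.7e-9, rel=1e-5)
        assert res["delta_h"] == pytest.approx(-12.0, rel=1e-5)

    def test_simulation_seeded(self):
        comp = CompetitionParams(
            strong=OneSiteParams(3.7e-9, 1.0, -12.0),
            weak=OneSiteParams(141e-9, 1.0, -10.0),
            weak_conc=43e-6,
        )
        expt = ITCExperiment(cell_conc=25e-6, syringe_conc=350e-6)
        a = simulate_competition(comp, expt, noise=0.02, seed=3)
        b = simulate_competition(comp, expt, noise=0.02, seed=3)
        assert np.allclose(a["heat"], b["heat"])


class TestDsc:
    B_A32 = DSCParams(tm=84.60 + CELSIUS, delta_h_cal=80.2)

    def test_peak_at_tm_with_closed_form_height(self):
        p = self.B_A32
        assert excess_heat_capacity(p.tm, p) == pytest.approx(p.peak_height)
        assert p.peak_height == pytest.approx(6.3, abs=0.1)
        t = np.linspace(p.tm - 30, p.tm + 30, 2001)
        cp = excess_heat_capacity(t, p)
        # the 1/T^2 factor shifts the maximum ~0.1 K below T_m
        assert t[np.argmax(cp)] == pytest.approx(p.tm, abs=0.2)

    def test_equilibrium_factor_quarter_at_tm(self):
        p = self.B_A32
        # K(T_m) = 1 so K/(1+K)^2 = 1/4 exactly
        assert excess_heat_capacity(p.tm, p) == pytest.approx(
            0.25 * p.delta_h_cal * p.delta_h_vh / (R_KCAL * p.tm**2)
        )

    def test_area_conserves_calorimetric_enthalpy(self):
        p = self.B_A32
        t = np.arange(p.tm - 30, p.tm + 30, 0.01)
        area = np.trapezoid(excess_heat_capacity(t, p), t)
        assert area == pytest.approx(p.delta_h_cal, rel=1e-3)

    def test_zero_noise_exact_recovery(self):
        res = DscModel.from_simulation(self.B_A32).fit()
        assert res["tm"] == pytest.approx(self.B_A32.tm, abs=1e-6)
        assert res["delta_h_cal"] == pytest.approx(80.2, rel=1e-6)
        assert res["delta_h_vh"] == pytest.approx(80.2, rel=1e-6)

    def test_cooperativity_ratio_recovered_on_noisy_data(self):
        truth = DSCParams(tm=75.90 + CELSIUS, delta_h_cal=85.8, delta_h_vh=70.0)
        res = DscModel.from_simulation(truth, noise=0.01, seed=8).fit()
        ratio = res.extra["cooperativity_ratio"]
        assert ratio == pytest.approx(70.0 / 85.8, rel=0.10)

    def test_thermogram_seeded(self):
        a = simulate_thermogram(self.B_A32, noise=0.005, seed=2)
        b = simulate_thermogram(self.B_A32, noise=0.005, seed=2)
        assert np.allclose(a["excess_cp"], b["excess_cp"])


class TestSpr:
    KIN = SPRKinetics(k_on=3e4, k_off=1.7e-4, r_max=120.0)

    def test_kd_from_printed_rates(self):
        kd = spr_kd(self.KIN)
        assert kd == pytest.approx(5.7e-9, abs=0.05e-9)
        # rounds to 6 nM at one significant figure
        assert round(kd * 1e9) == 6

    def test_kd_limit_fast_association(self):
        assert spr_kd(SPRKinetics(1e12, 1.7e-4)) < 1e-15

    def test_zero_noise_exact_recovery(self):
        res = SprModel.from_simulation(self.KIN).fit()
        assert res["k_on"] == pytest.approx(3e4, rel=1e-4)
        assert res["k_off"] == pytest.approx(1.7e-4, rel=1e-6)
        assert res.extra["kd"] == pytest.approx(self.KIN.kd, rel=1e-4)

    def test_koff_recovered_within_10pct_at_1pct_noise(self):
        res = SprModel.from_simulation(self.KIN, noise=0.01, seed=4).fit()
        assert res["k_off"] == pytest.approx(1.7e-4, rel=0.10)

    def test_sensorgram_structure(self):
        df = simulate_sensorgrams(self.KIN)
        assert set(df["phase"]) == {"association", "dissociation"}
        assert df["concentration"].nunique() == 6


class TestGibbs:
    def test_unit_association_zero_free_energy(self):
        assert gibbs(1.0, 298.15).delta_g == 0.0

    def test_printed_affinity_free_energy(self):
        state = gibbs(1.0 / 3.7e-9, 298.15)
        assert state.delta_g == pytest.approx(-11.5, abs=0.05)
        assert state.kd == pytest.approx(3.7e-9, rel=1e-9)

    def test_entropy_from_enthalpy(self):
        state = gibbs(1.0 / 3.7e-9, 298.15, delta_h=-12.0)
        assert state.delta_s == pytest.approx((-12.0 - state.delta_g) / 298.15)
        iso = gibbs(np.exp(-(-5.0) / (R_KCAL * 300.0)), 300.0, delta_h=-5.0)
        assert iso.delta_s == pytest.approx(0.0, abs=1e-12)

    def test_identity_enforced(self):
        from alpharep.binding.thermo import ThermoState
        with pytest.raises(ValueError):
            ThermoState(temperature=298.15, delta_g=-10.0, delta_h=-5.0,
                        delta_s=0.0)
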