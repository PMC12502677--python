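import dataclasses
import math

import numpy as np
import pytest

from trichodiel import _kernel as K
from trichodiel.calibration_fit import calibrated_for
from trichodiel.diel_simulator import (compute_fluxes, light_sine, pack_params,
                                       run_diel, run_experiment,
                                       state_to_array, step)
from trichodiel.model_core import (CalibratedParams, CellState, Environment,
                                   EnergyParams, ModelParams, Scenario)
from conftest import make_fast_params, run_case


class TestLightSine:
    def test_midday_peak(self):
        assert light_sine(6 * 3600.0, 500.0, 12.0) == pytest.approx(500.0)

    def test_dawn_and_dusk_zero(self):
        assert light_sine(0.0, 500.0, 12.0) == 0.0
        assert light_sine(12 * 3600.0, 500.0, 12.0) == 0.0

    def test_quarter_period(self):
        assert light_sine(3 * 3600.0, 500.0, 12.0) == \
            pytest.approx(500.0 * math.sin(math.pi / 4), rel=1e-12)


class TestStep:
    def test_dark_sealed_empty_cell_only_starves(self):
        """Without light, stores, or O2, nothing moves except the
        maintenance starvation penalty."""
        p = ModelParams()
        env = Environment(Fe_diss=0.0)
        cal = CalibratedParams(v_RP_max=0.0, T_PS_max_BF=0.0,
                               T_BF_max_PS=0.0, T_NF_max_BF=0.0)
        s = CellState(CH2O=0.0, CS=0.0, N=0.0, O2=0.0, Fe_PS=0.0, Fe_NF=0.0,
                      Fe_NF_inact=0.0, Fe_buffer=0.0, Fe_storage=0.0,
                      Fe_maint=0.0)
        env = dataclasses.replace(env, O2_ext=0.0)
        s2, rec = step(s, env, p, dt=60.0, mode="dynamic",
                       t=13 * 3600.0, calibrated=cal)
        assert rec.maint_deficit > 0.0
        assert rec.G < 0.0
        for name in ("CH2O", "CS", "N", "Fe_PS", "Fe_NF", "Fe_buffer"):
            assert getattr(s2, name) == 0.0

    def test_pure_diffusion_relaxes_like_exponential(self):
        """With only physical exchange active, O2 relaxes toward O2_ext as
        exp(-g t) and never overshoots for dt below the stability bound."""
        p = ModelParams()
        env = Environment(Fe_diss=0.0)
        cal = CalibratedParams(v_RP_max=0.0, T_PS_max_BF=0.0,
                               T_BF_max_PS=0.0, T_NF_max_BF=0.0)
        s = CellState(CH2O=0.0, CS=0.0, N=100.0, O2=0.05, Fe_PS=0.0,
                      Fe_NF=0.0, Fe_NF_inact=0.0, Fe_buffer=0.0,
                      Fe_storage=0.0, Fe_maint=0.0)
        from trichodiel.membrane_o2 import o2_conductance
        g = o2_conductance(p.permeability.eps_fixed, p.geometry,
                           p.permeability.d_O2)
        dt, nsteps = 1.0, 300
        o2 = s.O2
        prev_gap = env.O2_ext - o2
        for i in range(nsteps):
            s, rec = step(s, env, p, dt=dt, mode="fixed", t=13 * 3600.0,
                          calibrated=cal)
            gap = env.O2_ext - s.O2
            assert 0.0 <= gap <= prev_gap  # monotone, no overshoot
            prev_gap = gap
        expected = env.O2_ext + (0.05 - env.O2_ext) * math.exp(-g * dt * nsteps)
        assert s.O2 == pytest.approx(expected, rel=2e-3)

    def test_o2_mass_balance_resummation(self):
        """The O2 update applied by a step equals the re-summed source
        terms of its flux record to ~machine precision."""
        p = ModelParams()
        env = Environment(Fe_diss=40.0)
        s = CellState(O2=0.25)
        s2, rec = step(s, env, p, dt=1.0, mode="dynamic", t=2 * 3600.0)
        rho = p.carbon.rho_C
        net = (rho * (rec.J_O2_evolution - rec.V_O2_PR
                      - p.resp_prot.q_O2_resp * (rec.V_RP + rec.V_OR))
               + rec.T_O2)
        gross = (rho * (abs(rec.J_O2_evolution) + rec.V_O2_PR
                        + rec.V_RP + rec.V_OR) + abs(rec.T_O2))
        applied = (s2.O2 - s.O2) / 1.0
        assert abs(applied - net) <= 1e-10 * max(gross, 1e-30)

    def test_energy_closure_per_step(self):
        """ATP and NADPH production equal consumption + dissipation."""
        p = ModelParams()
        env = Environment(Fe_diss=400.0)
        rng = np.random.default_rng(7)
        en = p.energy
        for _ in range(50):
            s = CellState(
                CH2O=float(rng.uniform(0, 1)), CS=float(rng.uniform(0, 1)),
                N=float(rng.uniform(0, 0.3)), O2=float(rng.uniform(0.01, 1.0)),
                Fe_PS=float(rng.uniform(1, 200)),
                Fe_NF=float(rng.uniform(0, 50)))
            rec, _ = compute_fluxes(s, env, p, "dynamic",
                                    I=float(rng.uniform(10, 800)))
            maint_pet = min(en.e_maint, rec.V_ATP)
            atp_cons = (maint_pet + rec.V_ATP_PR
                        + en.q_ATP_NF * rec.V_NF
                        + (en.q_ATP_CF + en.q_ATP_CCM) * rec.V_CF
                        + rec.diss_ATP)
            nadph_cons = (rec.V_NADPH_PR + en.q_NADPH_NF * rec.V_NF
                          + en.q_NADPH_CF * rec.V_CF + rec.diss_NADPH)
            assert atp_cons == pytest.approx(rec.V_ATP, rel=1e-10, abs=1e-22)
            assert nadph_cons == pytest.approx(rec.V_NADPH, rel=1e-10,
                                               abs=1e-22)
            assert rec.V_LPET + rec.V_AET == pytest.approx(rec.V_PET,
                                                           rel=1e-12,
                                                           abs=1e-25)
            assert rec.V_PR <= rec.V_PR_max * (1 + 1e-12)
            assert rec.V_NF <= rec.V_NF_max * (1 + 1e-12)


class TestQssAgainstFullIntegration:
    def test_morning_trajectories_agree(self, params_fast, base_env,
                                        diel_outputs):
        """The quasi-steady O2 diagnosis reproduces the explicitly
        integrated (sub-stepped) trajectory over a morning window."""
        out = diel_outputs[("dynamic", 40.0)]
        y0 = out.states[6].copy()  # mid-morning converged state
        y0[K.Y_LNB] = 0.0
        P = pack_params(params_fast, dataclasses.replace(base_env,
                                                         Fe_diss=40.0),
                        "dynamic", calibrated_for("dynamic", 40.0))
        dt_out, nsteps = 300.0, 24  # 2 h
        empty = np.empty(0)
        # QSS path
        yq = y0.copy()
        ts = np.empty(nsteps); ys = np.empty((nsteps, K.NY))
        o2s = np.empty(nsteps); Fs = np.empty((nsteps, K.NF))
        integ = np.zeros(K.NACC)
        K.run_day(yq, P, dt_out, nsteps, P[K.P_O2_EXT], empty, True,
                  ts, ys, o2s, Fs, integ)
        # full path
        dt_sub = 0.25
        ntot = int(nsteps * dt_out / dt_sub)
        yf = y0.copy()
        tsf = np.empty(ntot); ysf = np.empty((ntot, K.NY))
        o2f = np.empty(ntot); Ff = np.empty((ntot, K.NF))
        K.run_day_full(yf, float(o2s[0]), P, dt_sub, ntot, empty, True,
                       tsf, ysf, o2f, Ff)
        # slow stores agree closely; O2 agrees after the initial transient
        for j in (K.Y_CH2O, K.Y_CS, K.Y_N, K.Y_FE_PS):
            assert yf[j] == pytest.approx(yq[j], rel=1e-2, abs=1e-6)
        sub = slice(ntot // 4, None, int(dt_out / dt_sub))
        qss_tail = o2s[nsteps // 4:]
        full_tail = o2f[sub][: qss_tail.size]
        assert np.allclose(full_tail, qss_tail, rtol=0.05, atol=2e-3)


class TestRunDiel:
    def test_perpetual_darkness_cannot_grow(self, base_env):
        p = make_fast_params(dt=600.0, max_cycles=40, growth_tol=1e-6)
        env = dataclasses.replace(base_env, light_mode="constant", I_max=0.0)
        sc = Scenario(name="dark", mode="dynamic", environment=env)
        out = run_diel(sc, p)
        assert out.daily["growth_rate_d"] <= 0.0

    def test_more_iron_never_hurts(self, params_fast, base_env):
        """Converged growth responds monotonically to dissolved Fe on a
        coarse grid (each level runs its own calibrated parameters)."""
        lo = run_case("dynamic", 40.0, params_fast, base_env)
        hi = run_case("dynamic", 1250.0, params_fast, base_env)
        assert hi.daily["growth_rate_d"] >= lo.daily["growth_rate_d"] - 1e-4

    def test_step_halving_converged_integrals(self, base_env):
        """Daily integrals move by <0.1% when the default step is halved
        (block-averaged over the diel attractor)."""
        coarse = make_fast_params(dt=120.0, max_cycles=150, avg_days=8)
        fine = make_fast_params(dt=60.0, max_cycles=150, avg_days=8)
        out_c = run_case("dynamic", 40.0, coarse, base_env)
        out_f = run_case("dynamic", 40.0, fine, base_env)
        for key in ("gross_c_fixation", "resp_protection_c",
                    "biosynthesis_c", "growth_rate_d"):
            assert out_c.daily[key] == pytest.approx(out_f.daily[key],
                                                     rel=1e-3)

    def test_daily_budget_closes(self, diel_outputs):
        for out in diel_outputs.values():
            assert out.daily["budget_residual_rel"] < 5e-3
            assert 0.0 <= out.daily["carbon_use_efficiency"] <= 1.0

    def test_o2_exchange_changes_sign_over_photoperiod(self, diel_outputs):
        """Efflux in the early photoperiod, influx during the low-O2
        window."""
        for (mode, fe), out in diel_outputs.items():
            t_h = out.time / 3600.0
            to2 = out.flux("T_O2")
            light = to2[t_h < 12.0]
            assert light.min() < 0.0, (mode, fe)  # high-O2 production phase
            ws, we = out.daily["window_start_h"], out.daily["window_end_h"]
            if we >= ws:
                in_win = (t_h > ws) & (t_h < we)
            else:  # window wraps through midnight
                in_win = (t_h > ws) | (t_h < we)
            win = to2[in_win]
            assert win.size and win.max() > 0.0, (mode, fe)


class TestExperiments:
    def test_unknown_experiment_lists_options(self):
        with pytest.raises(ValueError, match="fe_gradient"):
            run_experiment("warp_drive", ModelParams())

    def test_external_o2_scan_amplifies_dynamic_benefit(self, params_fast,
                                                        base_env):
        """Supersaturated external O2 strengthens the growth advantage of
        the O2-regulated membrane (more influx for the fixed case to burn
        off, more photorespiration to avoid)."""
        df = run_experiment("o2_scan", params_fast, base_env,
                            o2_levels=(0.213, 0.32), fe_pm=40.0)
        promo = df["growth_promotion_pct"].to_numpy()
        assert np.all(np.isfinite(promo))
        assert promo[1] > promo[0]
        assert df["frac_pr_fixed"].iloc[1] > df["frac_pr_fixed"].iloc[0]

    def test_epsmax_scan_structure(self, params_fast, base_env):
        df = run_experiment("epsmax_scan", params_fast, base_env,
                            factors=(0.5, 2.0), fe_pm=40.0)
        assert len(df) == 2
        assert np.all(np.isfinite(df["growth_dynamic_d"]))
        # at the reference eps_max the dynamic membrane beats the fixed one
        assert (df["growth_vs_fixed_pct"] > 0).all()

    def test_compare_permeability_budget_rows(self, params_fast, base_env):
        df = run_experiment("compare_permeability", params_fast, base_env,
                            fe_levels=(40.0,))
        assert len(df) == 2  # both modes at one Fe level
        frac_cols = ["frac_photorespiration", "frac_resp_protection",
                     "frac_ordinary_resp", "frac_biosynthesis",
                     "frac_store_change"]
        sums = df[frac_cols].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=5e-3)
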