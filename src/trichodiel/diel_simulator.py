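"""Diel time integration to a periodic steady state and the scenario engine.

The slow state (stores, Fe pools, log biomass) is advanced with fixed-step
RK4; intracellular O2 -- the only fast variable, relaxing on the O2
exchange timescale -- is either diagnosed quasi-steady within each stage
(default) or integrated explicitly with sub-steps.  A simulation spins
repeated diel cycles until the daily growth rate is periodic, then records
one full cycle with RK4-consistent daily flux integrals, from which the
carbon and Fe budgets are assembled.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import _kernel as K
from .model_core import (SECONDS_PER_DAY, CalibratedParams, CellState,
                         Environment, FluxRecord, ModelParams, Scenario,
                         FLUX_FIELDS)

logger = logging.getLogger("trichodiel")

EXPERIMENTS = ("fe_gradient", "compare_permeability", "o2_scan",
               "epsmax_scan", "pr_substitution")

FE_GRADIENT_PM = tuple(np.geomspace(20.0, 1800.0, 10).round(1))
FOCAL_FE_PM = (40.0, 1250.0)


def light_sine(t: float, I_max: float, photoperiod: float = 12.0) -> float:
    """Irradiance at ``t`` seconds past dawn: ``I_max*sin(pi*t/T)`` during
    the light period of length ``photoperiod`` hours, 0 in the dark."""
    if I_max < 0 or photoperiod <= 0:
        raise ValueError("I_max >= 0 and photoperiod > 0 required")
    tp = photoperiod * 3600.0
    if t < 0 or t >= tp:
        return 0.0
    return I_max * math.sin(math.pi * t / tp)


def pack_params(params: ModelParams, env: Environment, mode: str,
                calibrated: CalibratedParams | None = None) -> np.ndarray:
    """Flatten the parameter bundle + environment into the kernel vector."""
    if mode not in ("dynamic", "fixed"):
        raise ValueError(f"unknown permeability mode {mode!r}")
    g = params.geometry
    pe = params.permeability
    pr = params.photorespiration
    nf = params.nfix
    en = params.energy
    rp = params.resp_prot
    cb = params.carbon
    fe = params.iron
    ca = calibrated if calibrated is not None else params.calibrated
    P = np.empty(K.NP)
    P[K.P_EPS_MAX] = pe.eps_max
    P[K.P_K_O2_DIFF] = pe.k_O2_diff
    P[K.P_EPS_FIXED] = pe.eps_fixed
    P[K.P_D_O2] = pe.d_O2
    P[K.P_GEOM_LV] = g.L / g.V
    P[K.P_GEOM_MEM] = math.log((g.R + g.Lg) / g.R)
    P[K.P_GEOM_BL] = math.log((g.R + g.Lg + g.Lb) / (g.R + g.Lg))
    P[K.P_Q_ATP_PR] = pr.q_ATP_PR
    P[K.P_Q_NADPH_PR] = pr.q_NADPH_PR
    P[K.P_Q_O2_PR] = pr.q_O2_PR
    P[K.P_K_CH2O_PR] = pr.k_CH2O_PR
    P[K.P_K_O2_PR] = pr.k_O2_PR
    P[K.P_K_FE_NF] = nf.k_Fe_NF
    P[K.P_K_O2_NF] = nf.k_O2_NF
    P[K.P_Y_NADPH] = en.y_NADPH_per_e
    P[K.P_Y_ATP_L] = en.y_ATP_LPET_per_e
    P[K.P_Y_ATP_A] = en.y_ATP_AET_per_e
    P[K.P_Y_O2] = en.y_O2_per_e
    P[K.P_Q_ATP_CF] = en.q_ATP_CF
    P[K.P_Q_NADPH_CF] = en.q_NADPH_CF
    P[K.P_Q_ATP_CCM] = en.q_ATP_CCM
    P[K.P_Q_ATP_NF] = en.q_ATP_NF
    P[K.P_Q_NADPH_NF] = en.q_NADPH_NF
    P[K.P_E_MAINT] = en.e_maint
    P[K.P_Q_ATP_OR] = en.q_ATP_OR
    P[K.P_K_CH2O_OR] = en.k_CH2O_OR
    P[K.P_K_O2_OR] = en.k_O2_OR
    P[K.P_PHI_PET] = en.phi_PET
    P[K.P_K_I] = en.k_I
    P[K.P_K_RP_INHIB] = en.k_RP_inhib
    P[K.P_K_O2_RP] = rp.k_O2_RP
    P[K.P_K_CH2O_RP] = rp.k_CH2O_RP
    P[K.P_Q_O2_RESP] = rp.q_O2_resp
    P[K.P_K_N_DEM] = rp.k_N_demand
    P[K.P_V_CS_MAX] = cb.v_CS_max
    P[K.P_K_CH2O_CS] = cb.k_CH2O_CS
    P[K.P_K_CS_INH] = cb.k_CS_inh
    P[K.P_V_BIO_MAX] = cb.v_BIO_max
    P[K.P_K_CS_BIO] = cb.k_CS_BIO
    P[K.P_K_N_BIO] = cb.k_N_BIO
    P[K.P_Q_N_BIO] = cb.q_N_BIO
    P[K.P_RHO_C] = cb.rho_C
    P[K.P_V_FE_MAX] = fe.v_Fe_max
    P[K.P_K_FE_DISS] = fe.k_Fe_diss
    P[K.P_K_FE_B] = fe.k_Fe_B
    P[K.P_K_FE_PS] = fe.k_Fe_PS
    P[K.P_K_O2_NFSYN] = fe.k_O2_NFsyn
    P[K.P_K_NF_INACT] = fe.k_NF_inact
    P[K.P_K_O2_INACT] = fe.k_O2_inact
    P[K.P_K_NFI_REC] = fe.k_NFi_recycle
    P[K.P_K_STO] = fe.k_sto
    P[K.P_K_STO_BACK] = fe.k_sto_back
    P[K.P_FRAC_MAINT] = fe.frac_maint
    P[K.P_K_MAINT] = fe.k_maint
    P[K.P_V_RP_MAX] = ca.v_RP_max
    P[K.P_T_PS_MAX] = ca.T_PS_max_BF
    P[K.P_T_BF_MAX] = ca.T_BF_max_PS
    P[K.P_T_NF_MAX] = ca.T_NF_max_BF
    P[K.P_O2_EXT] = env.O2_ext
    P[K.P_FE_DISS] = env.Fe_diss
    P[K.P_I_MAX] = env.I_max
    P[K.P_PHOTOPERIOD_S] = env.photoperiod * 3600.0
    P[K.P_LIGHT_MODE] = 0.0 if env.light_mode == "sine" else 1.0
    P[K.P_MODE_DYNAMIC] = 1.0 if mode == "dynamic" else 0.0
    P[K.P_DAY_S] = params.sim.day_hours * 3600.0
    return P


def state_to_array(state: CellState) -> np.ndarray:
    y = np.empty(K.NY)
    y[K.Y_CH2O] = state.CH2O
    y[K.Y_CS] = state.CS
    y[K.Y_N] = state.N
    y[K.Y_FE_PS] = state.Fe_PS
    y[K.Y_FE_NF] = state.Fe_NF
    y[K.Y_FE_NFI] = state.Fe_NF_inact
    y[K.Y_FE_B] = state.Fe_buffer
    y[K.Y_FE_STO] = state.Fe_storage
    y[K.Y_FE_M] = state.Fe_maint
    y[K.Y_LNB] = math.log(state.biomass)
    return y


def array_to_state(y: np.ndarray, O2: float) -> CellState:
    return CellState(
        CH2O=float(y[K.Y_CH2O]), CS=float(y[K.Y_CS]), N=float(y[K.Y_N]),
        O2=float(O2), Fe_PS=float(y[K.Y_FE_PS]), Fe_NF=float(y[K.Y_FE_NF]),
        Fe_NF_inact=float(y[K.Y_FE_NFI]), Fe_buffer=float(y[K.Y_FE_B]),
        Fe_storage=float(y[K.Y_FE_STO]), Fe_maint=float(y[K.Y_FE_M]),
        biomass=float(math.exp(y[K.Y_LNB])),
    )


def compute_fluxes(state: CellState, env: Environment, params: ModelParams,
                   mode: str, I: float,
                   calibrated: CalibratedParams | None = None
                   ) -> tuple[FluxRecord, float]:
    """All instantaneous rates at the given state, O2 and irradiance.

    Returns the flux record and the net intracellular O2 tendency
    (mol O2 m^-3 s^-1).
    """
    P = pack_params(params, env, mode, calibrated)
    y = state_to_array(state)
    F = np.empty(K.NF)
    net = K.fluxes(y, state.O2, I, P, F, -1.0)
    rec = FluxRecord.from_array(F)
    _check_finite(rec)
    return rec, float(net)


def _check_finite(rec: FluxRecord) -> None:
    for name in FLUX_FIELDS:
        v = getattr(rec, name)
        if not math.isfinite(v):
            raise ArithmeticError(f"non-finite flux term: {name} = {v!r}")


def step(state: CellState, env: Environment, params: ModelParams, dt: float,
         mode: str = "dynamic", t: float | None = None,
         calibrated: CalibratedParams | None = None
         ) -> tuple[CellState, FluxRecord]:
    """One explicit step of the full state, O2 included.

    Every store is updated by its net flux (forward Euler at ``dt``); no
    store goes negative (clamped, logged).  ``t`` is seconds past dawn
    (default: midday).  Returns the updated state and the flux snapshot.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    P = pack_params(params, env, mode, calibrated)
    if t is None:
        t = 0.5 * P[K.P_PHOTOPERIOD_S]
    I = K.irradiance(t, P)
    y = state_to_array(state)
    F = np.empty(K.NF)
    net = K.fluxes(y, state.O2, I, P, F, -1.0)
    rec = FluxRecord.from_array(F)
    _check_finite(rec)
    dy = np.empty(K.NY)
    K.derivs(y, F, P, dy)
    y2 = y + dt * dy
    clipped = [i for i in range(K.NY)
               if i != K.Y_LNB and y2[i] < 0.0]
    if clipped:
        logger.debug("step: clipped negative store(s) at indices %s", clipped)
        y2[clipped] = 0.0
    O2_new = state.O2 + dt * net
    if O2_new < 0.0:
        logger.debug("step: clipped negative O2")
        O2_new = 0.0
    return array_to_state(y2, O2_new), rec


# ---------------------------------------------------------------------------
# Diel runs
# ---------------------------------------------------------------------------


@dataclass
class DielOutput:
    """Recorded periodic diel cycle: series, daily integrals, and budgets."""

    scenario: Scenario
    time: np.ndarray                 # s past dawn, one entry per step
    states: np.ndarray               # (n, 10) slow-state series
    o2: np.ndarray                   # intracellular O2 (mol m^-3)
    fluxes: np.ndarray               # (n, len(FLUX_FIELDS))
    daily: dict[str, Any] = field(default_factory=dict)
    converged: bool = True
    cycles: int = 0

    def timeseries(self) -> pd.DataFrame:
        cols = {
            "time_s": self.time,
            "CH2O": self.states[:, K.Y_CH2O],
            "CS": self.states[:, K.Y_CS],
            "N": self.states[:, K.Y_N],
            "Fe_PS": self.states[:, K.Y_FE_PS],
            "Fe_NF": self.states[:, K.Y_FE_NF],
            "Fe_NF_inact": self.states[:, K.Y_FE_NFI],
            "Fe_buffer": self.states[:, K.Y_FE_B],
            "Fe_storage": self.states[:, K.Y_FE_STO],
            "Fe_maint": self.states[:, K.Y_FE_M],
            "O2": self.o2,
        }
        for j, name in enumerate(FLUX_FIELDS):
            cols[name] = self.fluxes[:, j]
        return pd.DataFrame(cols)

    def flux(self, name: str) -> np.ndarray:
        return self.fluxes[:, FLUX_FIELDS.index(name)]


def _window_metrics(out_t: np.ndarray, o2: np.ndarray, vnf: np.ndarray,
                    o2_ext: float, dt: float) -> dict[str, Any]:
    """Longest contiguous low-O2 interval (O2 < O2_ext) and the fraction of
    daily N2 fixation occurring inside it.

    The diel cycle is circular: an interval running through midnight into
    the next dawn is one window, so the scan wraps around the day
    boundary.  "Below" means meaningfully below the far-field level
    (0.1% margin), so that dark-period equilibration at O2_ext itself does
    not count as part of the window.
    """
    n = o2.size
    below = o2 < 0.999 * o2_ext
    total_nf = float(np.sum(vnf) * dt)
    if not below.any() or total_nf <= 0.0:
        return {"window_start_h": math.nan, "window_end_h": math.nan,
                "nf_in_window_frac": 0.0 if total_nf > 0 else math.nan}
    if below.all():
        return {"window_start_h": 0.0,
                "window_end_h": float((out_t[-1] + dt) / 3600.0),
                "nf_in_window_frac": 1.0}
    ext = np.concatenate([below, below])  # circular scan
    best_len, best_start = 0, -1
    cur_len = 0
    for i in range(2 * n):
        if ext[i]:
            cur_len = min(cur_len + 1, n)
            start = i - cur_len + 1
            if cur_len > best_len and start < n:
                best_len, best_start = cur_len, start
        else:
            cur_len = 0
    idx = (best_start + np.arange(best_len)) % n
    frac = float(np.sum(vnf[idx]) * dt / total_nf)
    return {
        "window_start_h": float(out_t[best_start] / 3600.0),
        "window_end_h": float(
            (out_t[(best_start + best_len - 1) % n] + dt) / 3600.0),
        "nf_in_window_frac": frac,
    }


def run_diel(scenario: Scenario, params: ModelParams,
             calibrated: CalibratedParams | None = None,
             initial: CellState | None = None,
             vpr_forced: np.ndarray | None = None) -> DielOutput:
    """Integrate a scenario over repeated diel cycles to periodicity.

    Cycles run until the daily growth rate changes by less than
    ``params.sim.growth_tol`` (d^-1) between cycles, capped at
    ``params.sim.max_cycles`` (warning on non-convergence; the last cycle
    is returned).  The recorded cycle carries per-step series plus
    RK4-consistent daily integrals and the carbon/Fe budget decomposition.
    """
    scenario.validate()
    params.validate()
    sim = params.sim
    P = pack_params(params, scenario.environment, scenario.mode, calibrated)
    day_s = P[K.P_DAY_S]
    nsteps = int(round(day_s / sim.dt))
    if abs(nsteps * sim.dt - day_s) > 1e-9:
        raise ValueError("sim.dt must divide the diel period exactly")
    y = state_to_array(initial if initial is not None else CellState())
    vf = (np.asarray(vpr_forced, dtype=float) if vpr_forced is not None
          else np.empty(0))
    if vf.shape[0] not in (0, nsteps):
        raise ValueError("vpr_forced must have one value per step")
    ts = np.empty(nsteps)
    ys = np.empty((nsteps, K.NY))
    o2s = np.empty(nsteps)
    Fs = np.empty((nsteps, K.NF))
    integ = np.zeros(K.NACC)

    if sim.o2_mode == "full":
        nsub = max(1, int(round(sim.dt / sim.o2_substep)))
        mu, cycles, converged = _run_cycles_full(y, P, sim, nsteps, nsub, vf,
                                                 ts, ys, o2s, Fs, integ)
        nclip, period, drift = 0, 1, 0.0
    else:
        mu, cycles, converged, nclip, period, drift = K.run_cycles(
            y, P, sim.dt, nsteps, sim.max_cycles,
            sim.growth_tol * day_s / SECONDS_PER_DAY, vf,
            ts, ys, o2s, Fs, integ, sim.avg_days)
    if not converged:
        logger.warning("run_diel(%s): not periodic after %d cycles",
                       scenario.name, cycles)
    if nclip:
        logger.debug("run_diel(%s): %d negative-store clip events",
                     scenario.name, nclip)

    to_daily = SECONDS_PER_DAY / day_s
    gross = integ[K.F_V_CF] * to_daily
    pr = integ[K.F_V_PR] * to_daily
    rp = integ[K.F_V_RP] * to_daily
    orr = integ[K.F_V_OR] * to_daily
    bio = (integ[K.F_V_BIO] + integ[K.ACC_STORE_DILUTION]) * to_daily
    # net change of the free carbon stores over the recorded block (zero at
    # a perfectly periodic state; kept in the closure identity)
    d_stores = ((y[K.Y_CH2O] + y[K.Y_CS])
                - (ys[0, K.Y_CH2O] + ys[0, K.Y_CS])) / period * to_daily
    nfix = integ[K.F_V_NF] * to_daily
    growth = mu
    metabolic_fe = float(np.mean(ys[:, K.Y_FE_PS] + ys[:, K.Y_FE_NF]
                                 + ys[:, K.Y_FE_NFI] + ys[:, K.Y_FE_B]
                                 + ys[:, K.Y_FE_M]))
    total_fe = metabolic_fe + float(np.mean(ys[:, K.Y_FE_STO]))
    resid = gross - (pr + rp + orr + bio + d_stores)
    daily = {
        "growth_rate_d": float(growth),
        "gross_c_fixation": float(gross),
        "photorespiration_c": float(pr),
        "resp_protection_c": float(rp),
        "ordinary_resp_c": float(orr),
        "biosynthesis_c": float(bio),
        "n2_fixation": float(nfix),
        "frac_photorespiration": float(pr / gross) if gross > 0 else math.nan,
        "frac_resp_protection": float(rp / gross) if gross > 0 else math.nan,
        "frac_ordinary_resp": float(orr / gross) if gross > 0 else math.nan,
        "frac_biosynthesis": float(bio / gross) if gross > 0 else math.nan,
        "frac_store_change": float(d_stores / gross) if gross > 0 else math.nan,
        "carbon_use_efficiency": float(bio / gross) if gross > 0 else math.nan,
        "budget_residual_rel": float(abs(resid) / gross) if gross > 0 else 0.0,
        "metabolic_fe": metabolic_fe,
        "total_fe": total_fe,
        "fe_use_efficiency": float(nfix / metabolic_fe) if metabolic_fe > 0
        else math.nan,
        "attractor_period": int(period),
        "growth_drift_d": float(min(drift, 1.0) if not converged else 0.0),
    }
    daily.update(_window_metrics(ts, o2s, Fs[:, K.F_V_NF],
                                 scenario.environment.O2_ext, sim.dt))
    return DielOutput(scenario=scenario, time=ts, states=ys, o2=o2s,
                      fluxes=Fs, daily=daily, converged=converged,
                      cycles=cycles)


def _run_cycles_full(y, P, sim, nsteps, nsub, vf, ts, ys, o2s, Fs, integ):
    """Cycle loop for the explicit (sub-stepped) O2 mode.

    Records at the outer-step cadence; daily integrals use the recorded
    snapshots (rectangle rule at the sub-step within the kernel is
    unnecessary here because the sub-step already resolves all dynamics).
    """
    day_s = sim.dt * nsteps
    ntot = nsteps * nsub
    dts = sim.dt / nsub
    vf_sub = (np.repeat(vf, nsub) if vf.shape[0] else np.empty(0))
    t_sub = np.empty(ntot)
    y_sub = np.empty((ntot, K.NY))
    o2_sub = np.empty(ntot)
    F_sub = np.empty((ntot, K.NF))
    O2 = P[K.P_O2_EXT]
    prev_mu = 1.0e30
    converged = False
    cycles = 0
    mu = 0.0
    tol = sim.growth_tol * day_s / SECONDS_PER_DAY
    for c in range(sim.max_cycles):
        cycles = c + 1
        y[K.Y_LNB] = 0.0
        O2, _ = K.run_day_full(y, O2, P, dts, ntot, vf_sub, True,
                               t_sub, y_sub, o2_sub, F_sub)
        mu = y[K.Y_LNB] * SECONDS_PER_DAY / day_s
        if abs(mu - prev_mu) < tol:
            converged = True
            break
        prev_mu = mu
    ts[:] = t_sub[::nsub]
    ys[:] = y_sub[::nsub]
    o2s[:] = o2_sub[::nsub]
    Fs[:] = F_sub[::nsub]
    integ[:K.NF] = F_sub.sum(axis=0) * dts
    integ[K.ACC_STORE_DILUTION] = float(np.sum(
        (y_sub[:, K.Y_CH2O] + y_sub[:, K.Y_CS]) * F_sub[:, K.F_G]) * dts)
    integ[K.ACC_G] = float(np.sum(F_sub[:, K.F_G]) * dts)
    return mu, cycles, converged


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------


def _scenario(mode: str, fe_pm: float, base_env: Environment,
              name: str | None = None, **env_over) -> Scenario:
    env = dataclasses.replace(base_env, Fe_diss=fe_pm, **env_over)
    return Scenario(name=name or f"{mode}_{fe_pm:g}pM", mode=mode,
                    environment=env)


def _calib_for(params: ModelParams, mode: str, fe_pm: float
               ) -> CalibratedParams:
    from .calibration_fit import calibrated_for  # local import: no cycle
    return calibrated_for(mode, fe_pm, params)


def _run_case(params: ModelParams, mode: str, fe_pm: float,
              base_env: Environment, vpr_forced=None, **env_over
              ) -> DielOutput:
    sc = _scenario(mode, fe_pm, base_env, **env_over)
    cal = _calib_for(params, mode, fe_pm)
    return run_diel(sc, params, calibrated=cal, vpr_forced=vpr_forced)


def compare_permeability(params: ModelParams, base_env: Environment,
                         fe_levels=FOCAL_FE_PM) -> pd.DataFrame:
    """Daily budget comparison of fixed vs dynamic permeability.

    One row per (mode, Fe level) with the carbon-budget fractions
    (photorespiration, respiratory protection, ordinary respiration,
    biosynthesis; summing to ~1), carbon and Fe use efficiency, N2
    fixation, and growth.
    """
    rows = []
    for fe_pm in fe_levels:
        for mode in ("fixed", "dynamic"):
            out = _run_case(params, mode, fe_pm, base_env)
            d = out.daily
            rows.append({
                "mode": mode, "fe_pm": fe_pm,
                "growth_rate_d": d["growth_rate_d"],
                "n2_fixation": d["n2_fixation"],
                "gross_c_fixation": d["gross_c_fixation"],
                "frac_photorespiration": d["frac_photorespiration"],
                "frac_resp_protection": d["frac_resp_protection"],
                "frac_ordinary_resp": d["frac_ordinary_resp"],
                "frac_biosynthesis": d["frac_biosynthesis"],
                "frac_store_change": d["frac_store_change"],
                "carbon_use_efficiency": d["carbon_use_efficiency"],
                "fe_use_efficiency": d["fe_use_efficiency"],
                "nf_in_window_frac": d["nf_in_window_frac"],
                "converged": out.converged,
            })
    return pd.DataFrame(rows)


def fe_gradient(params: ModelParams, base_env: Environment,
                fe_levels=FE_GRADIENT_PM) -> pd.DataFrame:
    """Both permeability modes across the dissolved-Fe gradient; reports the
    growth promotion (%) of dynamic over fixed permeability per level."""
    rows = []
    for fe_pm in fe_levels:
        out_f = _run_case(params, "fixed", fe_pm, base_env)
        out_d = _run_case(params, "dynamic", fe_pm, base_env)
        gf = out_f.daily["growth_rate_d"]
        gd = out_d.daily["growth_rate_d"]
        rows.append({
            "fe_pm": fe_pm,
            "growth_fixed_d": gf,
            "growth_dynamic_d": gd,
            "growth_promotion_pct": 100.0 * (gd - gf) / gf if gf > 0
            else math.nan,
            "nf_fixed": out_f.daily["n2_fixation"],
            "nf_dynamic": out_d.daily["n2_fixation"],
            "quota_fixed": out_f.daily["total_fe"],
            "quota_dynamic": out_d.daily["total_fe"],
        })
    return pd.DataFrame(rows)


def o2_scan(params: ModelParams, base_env: Environment,
            o2_levels=(0.10, 0.16, 0.213, 0.30, 0.40),
            fe_pm: float = 40.0) -> pd.DataFrame:
    """Growth under a range of external O2 concentrations, both modes."""
    rows = []
    for o2e in o2_levels:
        out_f = _run_case(params, "fixed", fe_pm, base_env, O2_ext=o2e)
        out_d = _run_case(params, "dynamic", fe_pm, base_env, O2_ext=o2e)
        gf = out_f.daily["growth_rate_d"]
        gd = out_d.daily["growth_rate_d"]
        rows.append({
            "o2_ext": o2e, "fe_pm": fe_pm,
            "growth_fixed_d": gf, "growth_dynamic_d": gd,
            "growth_promotion_pct": 100.0 * (gd - gf) / gf if gf > 0
            else math.nan,
            "frac_pr_fixed": out_f.daily["frac_photorespiration"],
            "frac_pr_dynamic": out_d.daily["frac_photorespiration"],
        })
    return pd.DataFrame(rows)


def epsmax_scan(params: ModelParams, base_env: Environment,
                factors=(0.5, 1.0, 2.0, 4.0), fe_pm: float = 40.0
                ) -> pd.DataFrame:
    """Sensitivity of the dynamic case to the maximal relative diffusivity."""
    base_eps = params.permeability.eps_max
    out_fix = _run_case(params, "fixed", fe_pm, base_env)
    rows = []
    for fac in factors:
        p2 = dataclasses.replace(
            params, permeability=dataclasses.replace(
                params.permeability, eps_max=base_eps * fac))
        out = _run_case(p2, "dynamic", fe_pm, base_env)
        gd = out.daily["growth_rate_d"]
        gf = out_fix.daily["growth_rate_d"]
        rows.append({
            "eps_max": base_eps * fac, "factor": fac, "fe_pm": fe_pm,
            "growth_dynamic_d": gd,
            "growth_vs_fixed_pct": 100.0 * (gd - gf) / gf if gf > 0
            else math.nan,
        })
    return pd.DataFrame(rows)


def pr_substitution(params: ModelParams, base_env: Environment,
                    fe_levels=FOCAL_FE_PM) -> pd.DataFrame:
    """Replay the dynamic case with the fixed case's photorespiration.

    The fixed-permeability run's V_PR(t) trajectory is imposed on the
    dynamic-permeability case (still capped by substrate/energy
    availability); reports the resulting growth change.
    """
    rows = []
    for fe_pm in fe_levels:
        out_fix = _run_case(params, "fixed", fe_pm, base_env)
        vpr_traj = out_fix.flux("V_PR").copy()
        out_dyn = _run_case(params, "dynamic", fe_pm, base_env)
        out_sub = _run_case(params, "dynamic", fe_pm, base_env,
                            vpr_forced=vpr_traj)
        gd = out_dyn.daily["growth_rate_d"]
        gs = out_sub.daily["growth_rate_d"]
        rows.append({
            "fe_pm": fe_pm,
            "growth_dynamic_d": gd,
            "growth_substituted_d": gs,
            "growth_change_pct": 100.0 * (gs - gd) / gd if gd > 0
            else math.nan,
        })
    return pd.DataFrame(rows)


def run_experiment(name: str, params: ModelParams,
                   base_env: Environment | None = None, **kwargs
                   ) -> pd.DataFrame:
    """Dispatch a named model experiment; returns its result table."""
    if base_env is None:
        base_env = Environment()
    if name == "fe_gradient":
        return fe_gradient(params, base_env, **kwargs)
    if name == "compare_permeability":
        return compare_permeability(params, base_env, **kwargs)
    if name == "o2_scan":
        return o2_scan(params, base_env, **kwargs)
    if name == "epsmax_scan":
        return epsmax_scan(params, base_env, **kwargs)
    if name == "pr_substitution":
        return pr_substitution(params, base_env, **kwargs)
    raise ValueError(
        f"unknown experiment {name!r}; options: {', '.join(EXPERIMENTS)}")
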