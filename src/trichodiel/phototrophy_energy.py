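"""Photosynthetic electron transport, LPET/AET partitioning, O2 evolution,
the per-step ATP/NADPH closure, and carbon-skeleton production.

Two electron-transport pathways are modeled: linear PET (LPET) reduces
NADPH, pumps protons for ATP, and evolves O2 at photosystem II; alternative
electron transport (AET) yields ATP only and evolves no O2.  At every time
step the LPET fraction is chosen so that the immediate ATP and NADPH
requirements of the cell are met, and all production is promptly consumed
(any stoichiometrically unusable surplus is recorded as dissipation).
"""

from __future__ import annotations

import logging

from .model_core import CarbonParams, EnergyParams

logger = logging.getLogger("trichodiel")


def pet_rate(I: float, Fe_PS: float, V_RP: float,
             params: EnergyParams) -> float:
    """Total photosynthetic electron transport rate (mol e- (mol C)^-1 s^-1).

    Light-saturating and proportional to photosystem Fe; inhibited by
    respiratory protection (hyperbolic in V_RP with scale ``k_RP_inhib``).
    """
    if I < 0 or Fe_PS < 0 or V_RP < 0:
        raise ValueError("inputs must be >= 0")
    return (params.phi_PET * Fe_PS * I / (I + params.k_I)
            / (1.0 + V_RP / params.k_RP_inhib))


def partition_electrons(V_PET: float, atp_demand: float, nadph_demand: float,
                        params: EnergyParams) -> tuple[float, float]:
    """Split total PET into (V_LPET, V_AET) matching the demand ratio.

    With per-electron yields ``yN`` (NADPH, LPET only), ``yAL`` (ATP, LPET)
    and ``yAA`` (ATP, AET), the LPET fraction solving

        ATP produced / NADPH produced = atp_demand / nadph_demand

    is ``f = yAA / (rho*yN - yAL + yAA)`` with ``rho`` the demand ratio,
    clipped to [0, 1].  Zero NADPH demand routes everything through AET;
    zero total demand with positive PET defaults to all-AET (logged).
    """
    if V_PET < 0 or atp_demand < 0 or nadph_demand < 0:
        raise ValueError("inputs must be >= 0")
    yN = params.y_NADPH_per_e
    yAL = params.y_ATP_LPET_per_e
    yAA = params.y_ATP_AET_per_e
    if nadph_demand == 0.0:
        if atp_demand == 0.0 and V_PET > 0.0:
            logger.debug("partition_electrons: zero demand with V_PET > 0; "
                         "all-AET by convention")
        f = 0.0
    else:
        rho = atp_demand / nadph_demand
        f = yAA / (rho * yN - yAL + yAA)
        f = min(1.0, max(0.0, f))
    return f * V_PET, (1.0 - f) * V_PET


def energy_production(V_LPET: float, V_AET: float,
                      params: EnergyParams) -> tuple[float, float]:
    """(V_ATP, V_NADPH) produced by the two pathways."""
    atp = V_LPET * params.y_ATP_LPET_per_e + V_AET * params.y_ATP_AET_per_e
    nadph = V_LPET * params.y_NADPH_per_e
    return atp, nadph


def o2_evolution(V_LPET: float, V_AET: float, params: EnergyParams,
                 rho_C: float = 1.0) -> float:
    """Gross photosynthetic O2 production.

    O2 is evolved exclusively by LPET (water splitting at photosystem II),
    1/4 mol O2 per electron by default; AET contributes nothing.  With the
    default ``rho_C = 1`` the value is per biomass carbon
    (mol O2 (mol C)^-1 s^-1); pass the cytoplasm carbon density
    (mol C m^-3) for a volumetric rate.
    """
    if V_LPET < 0 or V_AET < 0:
        raise ValueError("rates must be >= 0")
    return params.y_O2_per_e * V_LPET * rho_C


def allocate_energy(V_ATP: float, V_NADPH: float, demands: dict,
                    params: EnergyParams) -> dict:
    """Waterfall allocation of one step's ATP/NADPH production.

    ``demands`` may contain (missing keys default to 0 / unbounded):

    * ``maintenance``: ATP demand (mol ATP (mol C)^-1 s^-1), served first;
    * ``photorespiration``: carbon-rate demand (the substrate-limited rate
      from the photorespiration law), costing ``q_ATP_PR``/``q_NADPH_PR``
      per C -- pass those in ``demands['q_ATP_PR']``/``['q_NADPH_PR']`` or
      the defaults 7 and 4 are used;
    * ``n2_fixation``: N-rate cap, costing ``q_ATP_NF``/``q_NADPH_NF``;
    * ``carbon_fixation``: optional C-rate cap (default unbounded); carbon
      fixation receives the residual co-limited by both currencies, paying
      the Calvin-cycle cost plus the carbon-concentrating (CCM) ATP
      overhead.

    Returns realized rates, a starvation flag (maintenance unmet), and the
    dissipated surplus of each currency.  Total consumption plus
    dissipation equals total production to machine precision.
    """
    if V_ATP < 0 or V_NADPH < 0:
        raise ValueError("supplies must be >= 0")
    q_atp_pr = demands.get("q_ATP_PR", 7.0)
    q_nadph_pr = demands.get("q_NADPH_PR", 4.0)
    maint_demand = demands.get("maintenance", 0.0)
    pr_demand = demands.get("photorespiration", 0.0)
    nf_demand = demands.get("n2_fixation", 0.0)
    cf_cap = demands.get("carbon_fixation", float("inf"))

    atp = V_ATP
    nadph = V_NADPH
    maint = min(maint_demand, atp)
    atp -= maint
    starved = maint < maint_demand

    v_pr = min(pr_demand, atp / q_atp_pr if q_atp_pr > 0 else pr_demand,
               nadph / q_nadph_pr if q_nadph_pr > 0 else pr_demand)
    v_pr = max(0.0, v_pr)
    atp -= q_atp_pr * v_pr
    nadph -= q_nadph_pr * v_pr

    v_nf = min(nf_demand, atp / params.q_ATP_NF, nadph / params.q_NADPH_NF)
    v_nf = max(0.0, v_nf)
    atp -= params.q_ATP_NF * v_nf
    nadph -= params.q_NADPH_NF * v_nf

    q_atp_cf = params.q_ATP_CF + params.q_ATP_CCM
    v_cf = min(cf_cap, atp / q_atp_cf, nadph / params.q_NADPH_CF)
    v_cf = max(0.0, v_cf)
    atp -= q_atp_cf * v_cf
    nadph -= params.q_NADPH_CF * v_cf

    return {
        "maintenance": maint,
        "photorespiration": v_pr,
        "n2_fixation": v_nf,
        "carbon_fixation": v_cf,
        "diss_ATP": atp,
        "diss_NADPH": nadph,
        "starved": starved,
    }


def carbon_skeleton_production(CH2O: float, CS: float,
                               params: CarbonParams) -> float:
    """Carbon-skeleton production rate (mol C (mol C)^-1 s^-1).

    Stimulated by the carbohydrate store and down-regulated by carbon
    skeleton accumulation; saturates below ``v_CS_max``.
    """
    if CH2O < 0 or CS < 0:
        raise ValueError("stores must be >= 0")
    return (params.v_CS_max * CH2O / (CH2O + params.k_CH2O_CS)
            * params.k_CS_inh / (params.k_CS_inh + CS))
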