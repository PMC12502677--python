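"""N2 fixation rate law and respiratory protection.

N2 fixation is limited by the Fe allocated to (active) nitrogenase and
inhibited by intracellular O2.  Respiratory protection is deliberate,
wasteful respiration of carbohydrate that draws down intracellular O2 to
shelter nitrogenase: it rises with the demand for N2 fixation and falls as
intracellular O2 rises (at high O2 protection is futile; it ramps once O2
is low enough to be held down).
"""

from __future__ import annotations

from .model_core import NFixParams, RespProtParams


def n2_fixation_rate(V_NF_max: float, Fe_NF: float, O2: float,
                     params: NFixParams) -> float:
    """N2 fixation rate (mol N (mol C)^-1 s^-1).

    ``V_NF_max`` is the energy-limited cap (ATP/NADPH available after
    higher-priority consumers); the realized rate is scaled by nitrogenase
    Fe saturation and by O2 inhibition ``1 - O2/(O2 + k_O2_NF)``.
    """
    if V_NF_max < 0 or Fe_NF < 0 or O2 < 0:
        raise ValueError("inputs must be >= 0")
    return (V_NF_max * Fe_NF / (Fe_NF + params.k_Fe_NF)
            * (1.0 - O2 / (O2 + params.k_O2_NF)))


def respiratory_protection_rate(v_RP_max: float, nf_demand: float, O2: float,
                                CH2O: float, params: RespProtParams) -> float:
    """Respiratory protection rate (mol C (mol C)^-1 s^-1).

    ``nf_demand`` is a dimensionless demand signal in [0, 1] (in the diel
    model: saturation of the fixed-N deficit).  The law is monotone
    increasing in the demand, monotone decreasing in O2, zero without
    carbohydrate, and capped by the calibrated ``v_RP_max``.  The functional
    form is a single swappable function; the O2 stock limit (respiration
    cannot consume more O2 than is instantaneously available) is enforced
    at the integrator level.
    """
    if v_RP_max < 0 or nf_demand < 0 or O2 < 0 or CH2O < 0:
        raise ValueError("inputs must be >= 0")
    return (v_RP_max * nf_demand
            * params.k_O2_RP / (params.k_O2_RP + O2)
            * CH2O / (CH2O + params.k_CH2O_RP))


def rp_o2_consumption(V_RP: float, rho_C: float,
                      q_O2_resp: float = 1.0) -> float:
    """O2 drawdown of respiratory protection (mol O2 m^-3 s^-1).

    Converts a per-biomass carbon respiration rate to a volumetric O2
    consumption via the cytoplasm carbon density ``rho_C`` (mol C m^-3) and
    the respiratory quotient ``q_O2_resp`` (mol O2 per mol C, 1.0 for
    carbohydrate oxidation).
    """
    if V_RP < 0:
        raise ValueError(f"V_RP must be >= 0, got {V_RP}")
    if rho_C <= 0 or q_O2_resp <= 0:
        raise ValueError("rho_C and q_O2_resp must be positive")
    return V_RP * q_O2_resp * rho_C
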