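"""Fe uptake, storage/buffer dynamics, and diurnal photosystem/nitrogenase
Fe translocation.

Intracellular Fe is split into photosystem Fe, active and inactive
nitrogenase Fe, a buffer pool (the only source for enzyme synthesis), a
storage pool in slow exchange with the buffer, and a maintenance pool held
as a fixed fraction of metabolic Fe.  All transfers conserve total Fe;
only uptake adds Fe.
"""

from __future__ import annotations

import dataclasses
import logging

from .model_core import (CalibratedParams, CellState, IronParams,
                         RespProtParams)

logger = logging.getLogger("trichodiel")


def fe_uptake(Fe_diss: float, params: IronParams) -> float:
    """Fe uptake rate (umol Fe (mol C)^-1 s^-1).

    Increasing and saturating in dissolved inorganic Fe (pM); the default
    half-saturation is far above oligotrophic levels, so uptake is
    near-linear over the 20-1,800 pM scenario range and maps that range to
    an equilibrium cell quota of roughly 10-1,000 umol Fe (mol C)^-1 at the
    model's growth rates.
    """
    if Fe_diss < 0:
        raise ValueError(f"Fe_diss must be >= 0, got {Fe_diss}")
    return params.v_Fe_max * Fe_diss / (Fe_diss + params.k_Fe_diss)


def nf_demand_signal(N: float, params: RespProtParams) -> float:
    """Dimensionless N2-fixation demand in (0, 1]: saturation of the
    fixed-N deficit (a depleted N store signals demand)."""
    if N < 0:
        raise ValueError("N must be >= 0")
    return params.k_N_demand / (N + params.k_N_demand)


def translocate_fe(state: CellState, rates: CalibratedParams,
                   iron: IronParams, dt: float, I: float = 0.0,
                   nf_demand: float = 0.0, k_I: float = 100.0) -> CellState:
    """Apply one step of Fe translocation between pools (no uptake).

    Photosystem and nitrogenase synthesis draw only from the buffer pool
    and are capped by ``T_PS_max_BF*dt`` and ``T_NF_max_BF*dt``;
    photosystem decomposition (cap ``T_BF_max_PS*dt``) returns Fe to the
    buffer; O2 exposure moves active nitrogenase Fe to the inactive pool,
    which recycles slowly to the buffer; buffer and storage exchange
    first-order; maintenance Fe relaxes toward a fixed fraction of
    metabolic Fe.  Any transfer that would overdraw its source pool is
    clamped to the pool content (logged).  Total Fe is conserved exactly.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    s = state
    lightfac = I / (I + k_I) if I > 0 else 0.0
    fB = s.Fe_buffer / (s.Fe_buffer + iron.k_Fe_B) if s.Fe_buffer > 0 else 0.0

    d_ps_syn = rates.T_PS_max_BF * fB * lightfac * dt
    d_nf_syn = (rates.T_NF_max_BF * fB * nf_demand
                * iron.k_O2_NFsyn / (iron.k_O2_NFsyn + s.O2) * dt)
    d_ps_dec = (rates.T_BF_max_PS * s.Fe_PS / (s.Fe_PS + iron.k_Fe_PS)
                * (1.0 - lightfac) * dt)
    d_inact = (iron.k_NF_inact * s.Fe_NF
               * s.O2 / (s.O2 + iron.k_O2_inact) * dt)
    d_rec = iron.k_NFi_recycle * s.Fe_NF_inact * dt
    d_sto = (iron.k_sto * s.Fe_buffer - iron.k_sto_back * s.Fe_storage) * dt
    metabolic = s.Fe_PS + s.Fe_NF + s.Fe_NF_inact + s.Fe_buffer
    d_mnt = iron.k_maint * (iron.frac_maint * metabolic - s.Fe_maint) * dt

    # source clamps
    draw_buffer = d_ps_syn + d_nf_syn + max(d_sto, 0.0) + max(d_mnt, 0.0)
    if draw_buffer > s.Fe_buffer:
        scale = s.Fe_buffer / draw_buffer if draw_buffer > 0 else 0.0
        logger.debug("translocate_fe: buffer overdraw clamped (scale %.3g)",
                     scale)
        d_ps_syn *= scale
        d_nf_syn *= scale
        if d_sto > 0:
            d_sto *= scale
        if d_mnt > 0:
            d_mnt *= scale
    if d_ps_dec > s.Fe_PS:
        logger.debug("translocate_fe: photosystem overdraw clamped")
        d_ps_dec = s.Fe_PS
    if d_inact > s.Fe_NF:
        d_inact = s.Fe_NF
    if d_rec > s.Fe_NF_inact:
        d_rec = s.Fe_NF_inact
    if d_sto < 0 and -d_sto > s.Fe_storage:
        d_sto = -s.Fe_storage
    if d_mnt < 0 and -d_mnt > s.Fe_maint:
        d_mnt = -s.Fe_maint

    return dataclasses.replace(
        s,
        Fe_PS=s.Fe_PS + d_ps_syn - d_ps_dec,
        Fe_NF=s.Fe_NF + d_nf_syn - d_inact,
        Fe_NF_inact=s.Fe_NF_inact + d_inact - d_rec,
        Fe_buffer=(s.Fe_buffer - d_ps_syn - d_nf_syn + d_ps_dec + d_rec
                   - d_sto - d_mnt),
        Fe_storage=s.Fe_storage + d_sto,
        Fe_maint=s.Fe_maint + d_mnt,
    )
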