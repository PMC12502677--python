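"""Photorespiration: energy-set cap, substrate-limited rate, and stoichiometry.

Photorespiration is modeled as a single lumped flux of carbohydrate carbon
oxygenated by RuBisCO, consuming ATP, NADPH and O2 at fixed ratios; its cap
is the rate at which the instantaneous ATP production of photosynthetic
electron transport would be entirely consumed by photorespiration.
"""

from __future__ import annotations

from .model_core import PhotorespirationParams


def max_photorespiration(V_ATP: float, q_ATP_PR: float = 7.0) -> float:
    """Photorespiration cap V_PR_max = V_ATP / q_ATP_PR.

    ``V_ATP`` is the total instantaneous ATP production rate of PET before
    allocation (mol ATP (mol C)^-1 s^-1); the cap corresponds to all of it
    being spent on photorespiration.  The realized rate is additionally
    limited by substrates and by the energy-closure allocation.
    """
    if V_ATP < 0:
        raise ValueError(f"V_ATP must be >= 0, got {V_ATP}")
    if q_ATP_PR <= 0:
        raise ValueError("q_ATP_PR must be positive")
    return V_ATP / q_ATP_PR


def photorespiration_rate(V_PR_max: float, CH2O: float, O2: float,
                          params: PhotorespirationParams) -> float:
    """Substrate-limited photorespiration rate (mol C (mol C)^-1 s^-1).

    Michaelis-Menten in both carbohydrate and intracellular O2;
    0 <= V_PR <= V_PR_max.
    """
    if V_PR_max < 0 or CH2O < 0 or O2 < 0:
        raise ValueError("inputs must be >= 0")
    return (V_PR_max * CH2O / (CH2O + params.k_CH2O_PR)
            * O2 / (O2 + params.k_O2_PR))


def photorespiration_demands(V_PR: float, params: PhotorespirationParams
                             ) -> tuple[float, float, float]:
    """Resource demands (V_NADPH_PR, V_ATP_PR, V_O2_PR) of a rate V_PR."""
    if V_PR < 0:
        raise ValueError(f"V_PR must be >= 0, got {V_PR}")
    return (params.q_NADPH_PR * V_PR, params.q_ATP_PR * V_PR,
            params.q_O2_PR * V_PR)
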