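"""Membrane O2 permeability and physical O2 exchange for a cylindrical trichome.

The membrane's relative O2 diffusivity ``eps`` (dimensionless, relative to
seawater) is either held fixed or regulated by intracellular O2 through a
Michaelis-Menten law; physical exchange across the membrane plus diffusive
boundary layer follows the series-resistance solution for a cylinder.
"""

from __future__ import annotations

import logging
import math

from .model_core import MembraneGeometry, PermeabilityParams

logger = logging.getLogger("trichodiel")

EPS_SEALED = 1.0e-12


def relative_permeability(O2: float, params: PermeabilityParams,
                          mode: str = "dynamic",
                          lag_state: float | None = None,
                          lag_tau: float | None = None,
                          dt: float | None = None) -> float:
    """Relative O2 diffusivity of the cell membrane.

    In ``fixed`` mode returns ``eps_fixed`` regardless of O2.  In
    ``dynamic`` mode returns ``eps_max * O2 / (O2 + k_O2_diff)``, an
    increasing, saturating function of intracellular O2 -- high O2 opens the
    membrane (venting), low O2 closes it (shielding nitrogenase).

    The response is instantaneous by default.  For sensitivity use, a
    first-order relaxation toward the instantaneous target is available by
    passing the previous value ``lag_state``, a time constant ``lag_tau``
    (s) and the elapsed ``dt`` (s).
    """
    if O2 < 0:
        raise ValueError(f"O2 must be >= 0, got {O2}")
    if mode == "fixed":
        target = params.eps_fixed
    elif mode == "dynamic":
        target = params.eps_max * O2 / (O2 + params.k_O2_diff)
    else:
        raise ValueError(f"unknown permeability mode {mode!r}")
    if lag_state is not None:
        if lag_tau is None or dt is None or lag_tau <= 0 or dt <= 0:
            raise ValueError("lagged permeability needs lag_tau > 0 and dt > 0")
        target = target + (lag_state - target) * math.exp(-dt / lag_tau)
    return target


def o2_conductance(eps: float, geom: MembraneGeometry, d_O2: float) -> float:
    """Series conductance of membrane + boundary layer (s^-1).

    Multiplying by the concentration difference (O2_ext - O2) gives the
    volumetric exchange rate.  Positive for all valid geometry and
    ``eps > 0``.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0; a sealed membrane is singular "
                         f"(use eps = {EPS_SEALED:g} as a sealed surrogate)")
    geom.validate()
    if d_O2 <= 0:
        raise ValueError("d_O2 must be positive")
    r_mem = math.log((geom.R + geom.Lg) / geom.R) / eps
    r_bl = math.log((geom.R + geom.Lg + geom.Lb) / (geom.R + geom.Lg))
    return 2.0 * math.pi * d_O2 * (geom.L / geom.V) / (r_mem + r_bl)


def o2_exchange_flux(O2: float, O2_ext: float, eps: float,
                     geom: MembraneGeometry, d_O2: float) -> float:
    """Physical O2 exchange rate T_O2 (mol O2 m^-3 s^-1, positive = influx).

    Linear in the gradient (O2_ext - O2) at fixed ``eps``; antisymmetric
    under swapping the two concentrations.
    """
    if O2 < 0 or O2_ext < 0:
        raise ValueError("O2 concentrations must be >= 0")
    return o2_conductance(eps, geom, d_O2) * (O2_ext - O2)


def sealed_membrane_eps() -> float:
    """Surrogate eps for a sealed-membrane scenario (logged)."""
    logger.warning("sealed membrane requested; using eps = %g surrogate",
                   EPS_SEALED)
    return EPS_SEALED
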