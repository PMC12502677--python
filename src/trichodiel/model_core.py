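"""Domain types, parameter registry, and configuration I/O.

Units convention (used everywhere; conversions happen only at I/O edges):

* time: seconds internally; growth rates reported in d^-1
* intracellular stores: mol (mol biomass C)^-1  (carbohydrate, carbon
  skeletons in mol C; fixed N in mol N)
* O2 concentrations: mol O2 m^-3
* Fe pools and Fe fluxes: umol Fe (mol biomass C)^-1
* irradiance: umol photons m^-2 s^-1
* dissolved inorganic Fe: pM

The registry of defaults below holds every constant of the rate laws.
Constants with established published values are fixed at those values;
constants that the antecedent models do not state openly are exposed as
documented, physically motivated defaults and may be overridden in the
configuration file.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

logger = logging.getLogger("trichodiel")

CONFIG_SCHEMA_VERSION = 1

SECONDS_PER_DAY = 86400.0


class ConfigError(ValueError):
    """Raised for malformed, unknown, or invariant-violating configuration."""


# ---------------------------------------------------------------------------
# Parameter blocks
# ---------------------------------------------------------------------------


@dataclass
class MembraneGeometry:
    """Cylindrical trichome geometry for the O2 diffusion law.

    The cell interior is a cylinder of radius ``R`` wrapped by a membrane of
    thickness ``Lg`` and a diffusive boundary layer of thickness ``Lb``;
    ``L`` and ``V`` are the trichome length and volume.
    """

    L: float = 1.0e-3        # trichome length (m)
    R: float = 7.0e-6        # cytoplasm radius (m)
    Lg: float = 6.0e-7       # effective membrane/envelope thickness (m)
    Lb: float = 2.0e-5       # boundary-layer thickness (m)
    V: float = 0.0           # trichome volume (m^3); 0 -> cylinder volume

    def __post_init__(self) -> None:
        if self.V == 0.0:
            self.V = math.pi * (self.R + self.Lg) ** 2 * self.L
        self.validate()

    def validate(self) -> None:
        for name in ("L", "R", "Lg", "Lb", "V"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"geometry.{name} must be strictly positive")
        if self.Lg > 0.1 * self.R:
            raise ConfigError("geometry.Lg must be small compared with R (Lg <= R/10)")
        v_cyl = math.pi * (self.R + self.Lg) ** 2 * self.L
        if not (0.8 * v_cyl <= self.V <= 1.2 * v_cyl):
            raise ConfigError(
                "geometry.V inconsistent with cylinder of radius R+Lg and length L "
                f"(got {self.V:.3e}, cylinder {v_cyl:.3e})"
            )


@dataclass
class PermeabilityParams:
    """Membrane O2 permeability: fixed value or O2-regulated (dynamic) law."""

    eps_max: float = 2.0e-4      # maximal relative diffusivity (-)
    k_O2_diff: float = 0.213     # half-saturation O2 for dynamic permeability (mol m^-3)
    eps_fixed: float = 1.0e-4    # fixed-case relative diffusivity (-)
    d_O2: float = 2.1e-9         # O2 diffusivity in seawater, 25 degC / 34 PSU (m^2 s^-1)

    def validate(self) -> None:
        if not (0.0 < self.eps_fixed <= self.eps_max):
            raise ConfigError("require 0 < eps_fixed <= eps_max")
        if self.k_O2_diff <= 0:
            raise ConfigError("permeability.k_O2_diff must be positive")
        if self.d_O2 <= 0:
            raise ConfigError("permeability.d_O2 must be positive")


@dataclass
class PhotorespirationParams:
    """Photorespiration stoichiometry and substrate half-saturations."""

    q_ATP_PR: float = 7.0        # mol ATP (mol C)^-1
    q_NADPH_PR: float = 4.0      # mol NADPH (mol C)^-1
    q_O2_PR: float = 3.0         # mol O2 (mol C)^-1
    k_CH2O_PR: float = 0.4       # mol C (mol C)^-1
    k_O2_PR: float = 1.92        # mol O2 m^-3

    def validate(self) -> None:
        for f_ in fields(self):
            if getattr(self, f_.name) <= 0:
                raise ConfigError(f"photorespiration.{f_.name} must be positive")


@dataclass
class NFixParams:
    """N2-fixation limitation constants."""

    k_Fe_NF: float = 20.0        # half-saturation of nitrogenase Fe (umol Fe (mol C)^-1)
    k_O2_NF: float = 0.02        # O2 half-inhibition (mol m^-3)

    def validate(self) -> None:
        if self.k_Fe_NF <= 0 or self.k_O2_NF <= 0:
            raise ConfigError("nfix constants must be positive")


@dataclass
class EnergyParams:
    """Electron-transport yields, consumer stoichiometries, and maintenance.

    Yields are per mol electron through the respective pathway: linear
    electron transport (LPET) reduces NADPH (2 e- each) and pumps protons
    for ATP at a canonical ATP:NADPH of ~1.28; alternative electron
    transport (AET) is ATP-only.  O2 evolution at photosystem II is
    1/4 mol O2 per electron and belongs to LPET exclusively.
    """

    y_NADPH_per_e: float = 0.5     # mol NADPH per mol e- (LPET)
    y_ATP_LPET_per_e: float = 0.64  # mol ATP per mol e- (LPET); 1.28 ATP:NADPH
    y_ATP_AET_per_e: float = 1.0   # mol ATP per mol e- (AET)
    y_O2_per_e: float = 0.25       # mol O2 evolved per mol e- through LPET
    q_ATP_CF: float = 3.0          # mol ATP per mol C fixed (Calvin cycle)
    q_NADPH_CF: float = 2.0        # mol NADPH per mol C fixed
    q_ATP_CCM: float = 1.0         # carbon-concentrating overhead, mol ATP per mol C
    q_ATP_NF: float = 8.0          # mol ATP per mol N fixed
    q_NADPH_NF: float = 2.0        # mol NADPH per mol N fixed
    e_maint: float = 2.0e-6        # maintenance ATP demand (mol ATP (mol C)^-1 s^-1)
    q_ATP_OR: float = 5.0          # ATP yield of ordinary respiration (mol ATP per mol C)
    k_CH2O_OR: float = 0.05        # carbohydrate half-saturation of ordinary respiration
    k_O2_OR: float = 0.005         # O2 half-saturation of ordinary respiration (mol m^-3)
    phi_PET: float = 5.0e-6        # PET capacity per photosystem Fe (mol e- (umol Fe)^-1 s^-1)
    k_I: float = 100.0             # light half-saturation (umol photons m^-2 s^-1)
    k_RP_inhib: float = 5.0e-5     # respiratory-protection inhibition scale on PET

    def validate(self) -> None:
        for f_ in fields(self):
            if getattr(self, f_.name) <= 0:
                raise ConfigError(f"energy.{f_.name} must be positive")
        if self.y_ATP_AET_per_e <= self.y_ATP_LPET_per_e:
            raise ConfigError(
                "energy: AET must out-yield LPET in ATP per electron "
                "(y_ATP_AET_per_e > y_ATP_LPET_per_e)"
            )


@dataclass
class RespProtParams:
    """Respiratory-protection rate law constants (swappable functional form)."""

    k_O2_RP: float = 0.1        # O2 down-regulation scale (mol m^-3)
    k_CH2O_RP: float = 0.1      # carbohydrate half-saturation
    q_O2_resp: float = 1.0      # mol O2 per mol C respired (protection and ordinary)
    k_N_demand: float = 0.1     # fixed-N store scale of the N2-fixation demand signal

    def validate(self) -> None:
        for f_ in fields(self):
            if getattr(self, f_.name) <= 0:
                raise ConfigError(f"resp_prot.{f_.name} must be positive")


@dataclass
class CarbonParams:
    """Carbon-skeleton production, biosynthesis, and cytoplasm carbon density."""

    v_CS_max: float = 5.0e-5    # max carbon-skeleton production (mol C (mol C)^-1 s^-1)
    k_CH2O_CS: float = 0.3      # carbohydrate half-saturation for skeleton production
    k_CS_inh: float = 0.3       # product inhibition scale of skeleton accumulation
    v_BIO_max: float = 2.0e-5   # max biosynthesis rate (mol C (mol C)^-1 s^-1)
    k_CS_BIO: float = 0.1       # skeleton half-saturation of biosynthesis
    k_N_BIO: float = 0.05       # fixed-N half-saturation of biosynthesis
    q_N_BIO: float = 0.15       # mol N per mol C of new biomass
    rho_C: float = 1250.0       # biomass carbon per cytoplasm volume (mol C m^-3)

    def validate(self) -> None:
        for f_ in fields(self):
            if getattr(self, f_.name) <= 0:
                raise ConfigError(f"carbon.{f_.name} must be positive")


@dataclass
class IronParams:
    """Fe uptake and pool-translocation constants (swappable functional forms)."""

    v_Fe_max: float = 2.0e-2     # max uptake (umol Fe (mol C)^-1 s^-1)
    k_Fe_diss: float = 5000.0    # dissolved-Fe half-saturation (pM)
    k_Fe_B: float = 20.0         # buffer-pool half-saturation for synthesis draws
    k_Fe_PS: float = 50.0        # photosystem-Fe half-saturation (PET and decomposition)
    k_O2_NFsyn: float = 0.02     # O2 gate on nitrogenase synthesis (mol m^-3)
    k_NF_inact: float = 2.0e-3   # nitrogenase inactivation rate scale (s^-1)
    k_O2_inact: float = 0.05     # O2 half-saturation of inactivation (mol m^-3)
    k_NFi_recycle: float = 1.0e-4  # inactive-nitrogenase Fe recycling to buffer (s^-1)
    k_sto: float = 1.0e-5        # buffer -> storage rate (s^-1)
    k_sto_back: float = 1.0e-5   # storage -> buffer rate (s^-1)
    frac_maint: float = 0.1      # maintenance Fe as fraction of metabolic Fe
    k_maint: float = 1.0e-4      # relaxation rate of maintenance Fe (s^-1)

    def validate(self) -> None:
        for f_ in fields(self):
            if getattr(self, f_.name) <= 0:
                raise ConfigError(f"iron.{f_.name} must be positive")


@dataclass
class CalibratedParams:
    """The four growth-maximized parameters.

    Defaults are the shipped calibration for the dynamic-permeability case at
    the low-Fe focal level; scenario-specific calibrations live in the
    packaged calibration table and are selected by the experiment drivers.
    """

    v_RP_max: float = 1.0e-4     # maximal respiratory protection (mol C (mol C)^-1 s^-1)
    T_PS_max_BF: float = 8.0e-3  # maximal photosystem synthesis (umol Fe (mol C)^-1 s^-1)
    T_BF_max_PS: float = 8.0e-3  # maximal photosystem decomposition (umol Fe (mol C)^-1 s^-1)
    T_NF_max_BF: float = 2.0e-3  # maximal nitrogenase synthesis (umol Fe (mol C)^-1 s^-1)

    def validate(self) -> None:
        for f_ in fields(self):
            if getattr(self, f_.name) < 0:
                raise ConfigError(f"calibrated.{f_.name} must be non-negative")

    def as_array(self):
        return [self.v_RP_max, self.T_PS_max_BF, self.T_BF_max_PS, self.T_NF_max_BF]


@dataclass
class SimSettings:
    """Numerical settings of the diel integrator."""

    dt: float = 60.0             # outer step (s); slow variables, RK4
    max_cycles: int = 100        # cap on diel cycles to periodic steady state
    growth_tol: float = 1.0e-6   # convergence tolerance on daily growth (d^-1)
    o2_mode: str = "qss"         # "qss" (diagnosed O2) or "full" (sub-stepped)
    o2_substep: float = 0.25     # sub-step (s) for the full O2 integration
    day_hours: float = 24.0      # diel period; set equal to photoperiod for light-only days
    avg_days: int = 4            # recording-block length for daily metrics (>= attractor period)

    def validate(self) -> None:
        if self.dt <= 0 or self.o2_substep <= 0:
            raise ConfigError("sim steps must be positive")
        if self.o2_mode not in ("qss", "full"):
            raise ConfigError("sim.o2_mode must be 'qss' or 'full'")
        if self.max_cycles < 1:
            raise ConfigError("sim.max_cycles must be >= 1")
        if self.avg_days < 1:
            raise ConfigError("sim.avg_days must be >= 1")
        if self.day_hours <= 0:
            raise ConfigError("sim.day_hours must be positive")


@dataclass
class ModelParams:
    """Bundle of every parameter block."""

    geometry: MembraneGeometry = field(default_factory=MembraneGeometry)
    permeability: PermeabilityParams = field(default_factory=PermeabilityParams)
    photorespiration: PhotorespirationParams = field(default_factory=PhotorespirationParams)
    nfix: NFixParams = field(default_factory=NFixParams)
    energy: EnergyParams = field(default_factory=EnergyParams)
    resp_prot: RespProtParams = field(default_factory=RespProtParams)
    carbon: CarbonParams = field(default_factory=CarbonParams)
    iron: IronParams = field(default_factory=IronParams)
    calibrated: CalibratedParams = field(default_factory=CalibratedParams)
    sim: SimSettings = field(default_factory=SimSettings)

    def validate(self) -> None:
        for f_ in fields(self):
            getattr(self, f_.name).validate()


# ---------------------------------------------------------------------------
# Environment / scenario / state
# ---------------------------------------------------------------------------


@dataclass
class Environment:
    """External forcing: far-field O2, dissolved Fe, and the light regime."""

    O2_ext: float = 0.213        # far-field O2 (mol m^-3); air saturation 25 degC / 34 PSU
    Fe_diss: float = 40.0        # dissolved inorganic Fe (pM)
    light_mode: str = "sine"     # "sine" or "constant"
    I_max: float = 500.0         # peak (sine) or level (constant) irradiance
    photoperiod: float = 12.0    # light-period length (h)

    def validate(self) -> None:
        if self.O2_ext < 0:
            raise ConfigError("environment.O2_ext must be >= 0")
        if self.Fe_diss < 0:
            raise ConfigError("environment.Fe_diss must be >= 0")
        if self.light_mode not in ("sine", "constant"):
            raise ConfigError("environment.light_mode must be 'sine' or 'constant'")
        if self.I_max < 0:
            raise ConfigError("environment.I_max must be >= 0")
        if self.photoperiod <= 0:
            raise ConfigError("environment.photoperiod must be positive")


@dataclass
class Scenario:
    """One model experiment condition."""

    name: str = "baseline"
    mode: str = "dynamic"        # permeability mode: "dynamic" or "fixed"
    environment: Environment = field(default_factory=Environment)

    def validate(self) -> None:
        if self.mode not in ("dynamic", "fixed"):
            raise ConfigError(f"scenario '{self.name}': mode must be 'dynamic' or 'fixed'")
        self.environment.validate()


FE_POOL_NAMES = ("Fe_PS", "Fe_NF", "Fe_NF_inact", "Fe_buffer", "Fe_storage", "Fe_maint")


@dataclass
class CellState:
    """Per-biomass stores, intracellular O2, and the intracellular Fe pools.

    ``Fe_NF`` is Fe in active nitrogenase; ``Fe_NF_inact`` holds Fe of
    O2-inactivated nitrogenase awaiting recycling to the buffer.
    """

    CH2O: float = 0.05           # carbohydrate store (mol C (mol C)^-1)
    CS: float = 0.05             # carbon-skeleton store (mol C (mol C)^-1)
    N: float = 0.05              # fixed-N store (mol N (mol C)^-1)
    O2: float = 0.213            # intracellular O2 (mol m^-3)
    Fe_PS: float = 5.0           # photosystem Fe (umol Fe (mol C)^-1)
    Fe_NF: float = 1.0           # active nitrogenase Fe
    Fe_NF_inact: float = 0.0     # inactive nitrogenase Fe
    Fe_buffer: float = 5.0       # buffer Fe
    Fe_storage: float = 5.0      # storage Fe
    Fe_maint: float = 1.0        # maintenance Fe
    biomass: float = 1.0         # relative biomass (mol C, normalized)

    def fe_total(self) -> float:
        return float(sum(getattr(self, n) for n in FE_POOL_NAMES))


def validate_state(state: CellState, fe_total: float | None = None,
                   fe_tol: float = 1.0e-9) -> list[str]:
    """Return a list of invariant violations (empty iff the state is valid).

    Each violation names the offending field and the violated bound.  If
    ``fe_total`` is given, the sum of the Fe pools is checked against it to
    within ``fe_tol`` (absolute) -- total Fe may change only through uptake.
    """
    violations: list[str] = []
    for f_ in fields(state):
        v = getattr(state, f_.name)
        if not math.isfinite(v):
            violations.append(f"{f_.name}: not finite")
        elif v < 0:
            violations.append(f"{f_.name}: must be >= 0, got {v!r}")
    if fe_total is not None:
        s = state.fe_total()
        if abs(s - fe_total) > fe_tol:
            violations.append(
                f"Fe pools: sum {s!r} differs from recorded total {fe_total!r} "
                f"by more than {fe_tol!r}"
            )
    return violations


# ---------------------------------------------------------------------------
# Flux record and diel output containers
# ---------------------------------------------------------------------------

FLUX_FIELDS = (
    "V_PET", "V_LPET", "V_AET", "V_ATP", "V_NADPH",
    "V_CF", "V_PR", "V_PR_max", "V_ATP_PR", "V_NADPH_PR", "V_O2_PR",
    "V_NF", "V_NF_max", "V_RP", "V_OR", "T_O2", "G",
    "V_CS", "V_BIO", "J_O2_evolution", "diss_ATP", "diss_NADPH",
    "maint_deficit", "eps", "V_Fe_uptake",
    "T_PS_syn", "T_PS_dec", "T_NF_syn", "T_NF_inact", "T_NFi_recycle",
    "T_Fe_storage", "T_Fe_maint",
)


@dataclass
class FluxRecord:
    """Snapshot of all instantaneous rates at one time point.

    Electron-transport rates in mol e- (mol C)^-1 s^-1; carbon/N fluxes per
    biomass C per second; ``T_O2`` in mol O2 m^-3 s^-1 (positive = influx);
    ``G`` is the instantaneous growth rate (s^-1).
    """

    V_PET: float = 0.0
    V_LPET: float = 0.0
    V_AET: float = 0.0
    V_ATP: float = 0.0
    V_NADPH: float = 0.0
    V_CF: float = 0.0
    V_PR: float = 0.0
    V_PR_max: float = 0.0
    V_ATP_PR: float = 0.0
    V_NADPH_PR: float = 0.0
    V_O2_PR: float = 0.0
    V_NF: float = 0.0
    V_NF_max: float = 0.0
    V_RP: float = 0.0
    V_OR: float = 0.0
    T_O2: float = 0.0
    G: float = 0.0
    V_CS: float = 0.0
    V_BIO: float = 0.0
    J_O2_evolution: float = 0.0
    diss_ATP: float = 0.0
    diss_NADPH: float = 0.0
    maint_deficit: float = 0.0
    eps: float = 0.0
    V_Fe_uptake: float = 0.0
    T_PS_syn: float = 0.0
    T_PS_dec: float = 0.0
    T_NF_syn: float = 0.0
    T_NF_inact: float = 0.0
    T_NFi_recycle: float = 0.0
    T_Fe_storage: float = 0.0
    T_Fe_maint: float = 0.0

    @classmethod
    def from_array(cls, arr) -> "FluxRecord":
        return cls(**{name: float(arr[i]) for i, name in enumerate(FLUX_FIELDS)})


# ---------------------------------------------------------------------------
# Configuration I/O
# ---------------------------------------------------------------------------

_BLOCK_TYPES: dict[str, type] = {
    "geometry": MembraneGeometry,
    "permeability": PermeabilityParams,
    "photorespiration": PhotorespirationParams,
    "nfix": NFixParams,
    "energy": EnergyParams,
    "resp_prot": RespProtParams,
    "carbon": CarbonParams,
    "iron": IronParams,
    "calibrated": CalibratedParams,
    "sim": SimSettings,
}


def _build_block(cls: type, data: dict[str, Any], path: str):
    known = {f_.name for f_ in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in '{path}': {sorted(unknown)}")
    defaults = cls()
    missing = known - set(data)
    if missing and data:
        logger.info("config '%s': defaults applied for %s", path, sorted(missing))
    obj = cls(**{k: data.get(k, getattr(defaults, k)) for k in known})
    return obj


def _scenario_from_dict(data: dict[str, Any], idx: int) -> Scenario:
    if "mode" not in data:
        raise ConfigError(f"scenario #{idx}: missing required field 'mode'")
    env_data = dict(data.get("environment", {}))
    if "fe_pm" in data:  # shorthand
        env_data["Fe_diss"] = data.pop("fe_pm")
    known = {"name", "mode", "environment"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in scenario #{idx}: {sorted(unknown)}")
    env = _build_block(Environment, env_data, f"scenario[{idx}].environment")
    sc = Scenario(name=data.get("name", f"scenario{idx}"), mode=data["mode"], environment=env)
    sc.validate()
    return sc


def load_config(path: str | Path) -> tuple[ModelParams, Environment, list[Scenario]]:
    """Load a YAML configuration.

    Returns the fully populated parameter bundle (defaults filled for
    unspecified values, logged), the base environment, and the scenario
    list.  Unknown keys anywhere are rejected with a ``ConfigError`` naming
    the offending section.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top-level configuration must be a mapping")
    version = raw.pop("schema_version", CONFIG_SCHEMA_VERSION)
    if version != CONFIG_SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {version!r}")
    params_data = raw.pop("params", {}) or {}
    env_data = raw.pop("environment", {}) or {}
    scen_data = raw.pop("scenarios", []) or []
    if raw:
        raise ConfigError(f"unknown top-level key(s): {sorted(raw)}")

    unknown_blocks = set(params_data) - set(_BLOCK_TYPES)
    if unknown_blocks:
        raise ConfigError(f"unknown parameter block(s): {sorted(unknown_blocks)}")
    blocks = {
        name: _build_block(cls, params_data.get(name, {}) or {}, f"params.{name}")
        for name, cls in _BLOCK_TYPES.items()
    }
    params = ModelParams(**blocks)
    params.validate()

    env = _build_block(Environment, env_data, "environment")
    env.validate()

    scenarios = [_scenario_from_dict(dict(s), i) for i, s in enumerate(scen_data)]
    return params, env, scenarios


def config_to_dict(params: ModelParams, env: Environment,
                   scenarios: list[Scenario] | None = None) -> dict[str, Any]:
    out: dict[str, Any] = {"schema_version": CONFIG_SCHEMA_VERSION}
    out["params"] = {
        name: dataclasses.asdict(getattr(params, name)) for name in _BLOCK_TYPES
    }
    out["environment"] = dataclasses.asdict(env)
    if scenarios:
        out["scenarios"] = [
            {"name": s.name, "mode": s.mode, "environment": dataclasses.asdict(s.environment)}
            for s in scenarios
        ]
    return out


def save_config(path: str | Path, params: ModelParams, env: Environment,
                scenarios: list[Scenario] | None = None) -> None:
    """Serialize a configuration so that ``load_config`` round-trips it."""
    Path(path).write_text(
        yaml.safe_dump(config_to_dict(params, env, scenarios), sort_keys=True)
    )
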