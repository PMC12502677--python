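import dataclasses

import pytest

from trichodiel.calibration_fit import calibrated_for
from trichodiel.diel_simulator import run_diel
from trichodiel.model_core import Environment, ModelParams, Scenario

# Coarser step than the production default keeps the suite quick; RK4 with
# quasi-steady O2 is step-size converged at this resolution (checked by the
# step-halving test).
FAST_DT = 300.0


def make_fast_params(dt: float = FAST_DT, max_cycles: int = 80,
                     growth_tol: float = 1.0e-6, **sim_over) -> ModelParams:
    p = ModelParams()
    return dataclasses.replace(
        p, sim=dataclasses.replace(p.sim, dt=dt, max_cycles=max_cycles,
                                   growth_tol=growth_tol, **sim_over))


def run_case(mode: str, fe_pm: float, params: ModelParams,
             env: Environment, **kw):
    sc = Scenario(name=f"{mode}_{fe_pm:g}", mode=mode,
                  environment=dataclasses.replace(env, Fe_diss=fe_pm))
    return run_diel(sc, params, calibrated=calibrated_for(mode, fe_pm), **kw)


@pytest.fixture(scope="session")
def params_fast() -> ModelParams:
    return make_fast_params()


@pytest.fixture(scope="session")
def base_env() -> Environment:
    return Environment()


@pytest.fixture(scope="session")
def diel_outputs(params_fast, base_env):
    """Converged diel cycles for both permeability modes at the two focal
    dissolved-Fe levels (shared across tests)."""
    return {
        (mode, fe): run_case(mode, fe, params_fast, base_env)
        for mode in ("fixed", "dynamic")
        for fe in (40.0, 1250.0)
    }
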