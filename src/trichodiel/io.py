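"""Result serialization: stable CSV/JSON outputs with provenance.

CSV columns are documented by their headers and floats are written with 12
significant digits; JSON scalars carry the configuration hash, package
version, and seed so any output can be traced to its inputs.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .model_core import Environment, ModelParams, config_to_dict

FLOAT_FORMAT = "%.12g"


def config_hash(params: ModelParams, env: Environment) -> str:
    """Stable hash of the full configuration (changes iff config changes)."""
    canon = yaml.safe_dump(config_to_dict(params, env), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _round12(x: Any) -> Any:
    if isinstance(x, float):
        return x if (math.isnan(x) or math.isinf(x)) else float(f"{x:.12g}")
    if isinstance(x, dict):
        return {k: _round12(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round12(v) for v in x]
    return x


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write an experiment table (header-only if empty) as CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def write_json(data: dict, path: str | Path, *, params: ModelParams | None = None,
               env: Environment | None = None, seed: int | None = None) -> Path:
    """Write a JSON result with provenance fields."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(_round12(data))
    payload["_provenance"] = {
        "package": "trichodiel",
        "version": __version__,
        "seed": seed,
        "config_hash": (config_hash(params, env)
                        if params is not None and env is not None else None),
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                               allow_nan=True) + "\n")
    return path


def write_outputs(output, outdir: str | Path, *, params: ModelParams,
                  env: Environment, seed: int | None = None,
                  thin: int = 1) -> dict[str, Path]:
    """Write a DielOutput: per-step time series as CSV (optionally thinned)
    and daily scalars as JSON.  Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ts = output.timeseries().iloc[::max(1, int(thin))]
    paths = {
        "timeseries": write_table(ts, outdir / "timeseries.csv"),
        "daily": write_json(
            {"scenario": {"name": output.scenario.name,
                          "mode": output.scenario.mode,
                          "fe_pm": output.scenario.environment.Fe_diss},
             "converged": bool(output.converged),
             "cycles": int(output.cycles),
             **output.daily},
            outdir / "daily.json", params=params, env=env, seed=seed),
    }
    return paths
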