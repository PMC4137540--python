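"""Model and trace serialization.

Models round-trip through a small documented JSON/YAML dialect::

    name: decay
    species: [x]
    initial_state: [1.0]
    parameters: {k: 0.5}
    inputs: {}
    input_ranges: {}          # optional, input -> [lo, hi]
    rates:
      x: "-k * x"

Traces write to tidy CSV (time + one column per species) or JSON with
metadata (inputs, integration tolerances).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .models import ReactionModel, Trace

__all__ = [
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
    "trace_to_csv",
    "trace_to_json",
    "trace_from_json",
]

_REQUIRED_KEYS = {"name", "species", "initial_state", "rates"}


def model_to_dict(model: ReactionModel) -> dict[str, Any]:
    return {
        "name": model.name,
        "species": list(model.species),
        "initial_state": [float(v) for v in model.initial_state],
        "parameters": {k: float(v) for k, v in model.parameters.items()},
        "inputs": {k: float(v) for k, v in model.inputs.items()},
        "input_ranges": {k: [float(a), float(b)] for k, (a, b) in model.input_ranges.items()},
        "rates": dict(model.rates),
    }


def model_from_dict(data: dict[str, Any]) -> ReactionModel:
    missing = _REQUIRED_KEYS - set(data)
    if missing:
        raise ValueError(f"model specification missing keys: {sorted(missing)}")
    ranges = {k: (float(v[0]), float(v[1])) for k, v in (data.get("input_ranges") or {}).items()}
    return ReactionModel(
        name=str(data["name"]),
        species=[str(s) for s in data["species"]],
        initial_state=[float(v) for v in data["initial_state"]],
        parameters=data.get("parameters") or {},
        inputs=data.get("inputs") or {},
        rates={str(k): str(v) for k, v in data["rates"].items()},
        input_ranges=ranges,
    )


def save_model(model: ReactionModel, path: str | Path) -> None:
    path = Path(path)
    data = model_to_dict(model)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))


def load_model(path: str | Path) -> ReactionModel:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return model_from_dict(data)


def trace_to_csv(trace: Trace, path: str | Path) -> None:
    import pandas as pd

    df = pd.DataFrame(trace.states, columns=list(trace.species))
    df.insert(0, "time", trace.times)
    df.to_csv(path, index=False)


def trace_to_json(trace: Trace, path: str | Path) -> None:
    payload = {
        "model_name": trace.model_name,
        "species": list(trace.species),
        "times": trace.times.tolist(),
        "states": trace.states.tolist(),
        "inputs_used": trace.inputs_used,
        "metadata": trace.metadata,
    }
    Path(path).write_text(json.dumps(payload))


def trace_from_json(path: str | Path) -> Trace:
    data = json.loads(Path(path).read_text())
    return Trace(
        times=np.asarray(data["times"]),
        states=np.asarray(data["states"]),
        species=tuple(data["species"]),
        inputs_used=data.get("inputs_used", {}),
        model_name=data.get("model_name", ""),
        metadata=data.get("metadata", {}),
    )
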