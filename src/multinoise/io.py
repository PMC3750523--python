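"""Serialization: trajectories as tidy CSV, models as YAML/JSON.

A trajectory is written as tidy (time, species, count) rows with a JSON
sidecar recording the seed, the species list and, when the model is
supplied, a content hash of the model so a result can be traced to the
exact reaction system and seed that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .stochastic_engine import (
    INSTANT,
    DelayDistribution,
    ReactionSpec,
    RepressionRate,
    TrajectorySample,
)

__all__ = [
    "save_trajectory",
    "load_trajectory",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
    "model_hash",
]


def _rate_to_json(rate):
    if rate is INSTANT:
        return "INSTANT"
    if isinstance(rate, RepressionRate):
        return {"law": "repression", "k_max": rate.k_max, "K": rate.K,
                "repressor": rate.repressor}
    if isinstance(rate, float):
        return rate
    raise ValueError("Python-callable rates cannot be serialized")


def _rate_from_json(obj):
    if obj == "INSTANT":
        return INSTANT
    if isinstance(obj, dict):
        if obj.get("law") != "repression":
            raise ValueError(f"unknown rate law {obj!r}")
        return RepressionRate(float(obj["k_max"]), float(obj["K"]), obj["repressor"])
    return float(obj)


def model_to_dict(model: Sequence[ReactionSpec]) -> list[dict]:
    out = []
    for rx in model:
        d = {
            "reactants": dict(rx.reactants),
            "products": dict(rx.products),
            "rate": _rate_to_json(rx.rate),
        }
        if rx.delays:
            d["delays"] = {
                sp: {"family": dd.family, "params": list(dd.params)}
                for sp, dd in rx.delays.items()
            }
        if rx.shared_delay:
            d["shared_delay"] = True
        if rx.tracked_deltas:
            d["tracked_deltas"] = dict(rx.tracked_deltas)
        if rx.priority:
            d["priority"] = rx.priority
        if rx.name:
            d["name"] = rx.name
        out.append(d)
    return out


def model_from_dict(data: Sequence[dict]) -> list[ReactionSpec]:
    model = []
    for d in data:
        delays = {
            sp: DelayDistribution(v["family"], tuple(v["params"]))
            for sp, v in d.get("delays", {}).items()
        }
        model.append(
            ReactionSpec(
                reactants=d.get("reactants", {}),
                products=d.get("products", {}),
                rate=_rate_from_json(d["rate"]),
                delays=delays,
                shared_delay=bool(d.get("shared_delay", False)),
                tracked_deltas=d.get("tracked_deltas", {}),
                priority=int(d.get("priority", 0)),
                name=d.get("name", ""),
            )
        )
    return model


def model_hash(model: Sequence[ReactionSpec]) -> str:
    """Content hash of a model (stable across sessions)."""
    blob = json.dumps(model_to_dict(model), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_model(model: Sequence[ReactionSpec], path) -> None:
    """Write a model as YAML (.yaml/.yml) or JSON (anything else)."""
    path = Path(path)
    data = model_to_dict(model)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))


def load_model(path) -> list[ReactionSpec]:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return model_from_dict(data)


def save_trajectory(sample: TrajectorySample, path, model=None, params: dict | None = None) -> None:
    """Tidy CSV (time, species, count) plus a JSON metadata sidecar."""
    path = Path(path)
    sample.to_dataframe().to_csv(path, index=False)
    meta = {
        "seed": sample.seed,
        "species": list(sample.species),
        "n_samples": int(len(sample.grid)),
        "sample_interval": float(sample.grid[1] - sample.grid[0]) if len(sample.grid) > 1 else None,
    }
    if model is not None:
        meta["model_hash"] = model_hash(model)
    if params:
        meta["params"] = params
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_trajectory(path) -> TrajectorySample:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    species = tuple(meta["species"])
    grid = np.sort(df["time"].unique())
    wide = df.pivot(index="species", columns="time", values="count")
    counts = wide.loc[list(species)].to_numpy(dtype=np.int64)
    return TrajectorySample(grid=grid, species=species, counts=counts, seed=int(meta["seed"]))
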