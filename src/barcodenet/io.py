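"""Serialization: activity snapshots, model fixtures, experiment manifests.

Arrays are stored as compressed ``.npz`` with a JSON sidecar recording the
resolved configuration and master seed, so any snapshot can be traced back to
the exact run that produced it.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from .config import ModelConfig
from .memory import BarcodeMemory

__all__ = [
    "save_arrays",
    "load_arrays",
    "ExperimentManifest",
    "save_model_snapshot",
    "load_model_snapshot",
    "make_fixture",
]


def save_arrays(
    path: str | Path,
    arrays: Dict[str, np.ndarray],
    config: Optional[ModelConfig] = None,
    seed: Optional[int] = None,
    extra: Optional[dict] = None,
) -> Path:
    """Write arrays to ``<path>.npz`` with a ``<path>.json`` sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    meta = {
        "arrays": {k: list(v.shape) for k, v in arrays.items()},
        "seed": seed,
        "config": config.to_dict() if config is not None else None,
    }
    if extra:
        meta.update(extra)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path.with_suffix(".npz")


def load_arrays(path: str | Path):
    """Load an ``.npz`` snapshot and its sidecar metadata (dict, dict)."""
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as f:
        arrays = {k: f[k] for k in f.files}
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return arrays, meta


@dataclass
class ExperimentManifest:
    """Record of an experiment invocation, written before computation."""

    experiment: str
    config: ModelConfig
    variant: str = "default"
    master_seed: int = 0
    outdir: str = "results"
    params: dict = field(default_factory=dict)
    version: str = "0.1.0"

    def digest(self) -> str:
        payload = json.dumps(
            {
                "experiment": self.experiment,
                "config": self.config.to_dict(),
                "variant": self.variant,
                "seed": self.master_seed,
                "params": self.params,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def write(self) -> Path:
        out = Path(self.outdir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / f"manifest_{self.experiment}.json"
        data = dataclasses.asdict(self)
        data["config"] = self.config.to_dict()
        data["hash"] = self.digest()
        data["written_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        path.write_text(json.dumps(data, indent=2))
        return path


# --------------------------------------------------------------------------
# model snapshots / fixtures
# --------------------------------------------------------------------------

def save_model_snapshot(model: BarcodeMemory, path: str | Path) -> Path:
    arrays = {
        "B": model.weights.B,
        "H": model.weights.H,
        "j_in": model.seed_path.j_in,
        "w_seed": model.readout.w_seed,
        "J_place": model.readout.J_place,
        "bank": model.bank.vectors,
        "preferred": model.bank.preferred_locations,
        "cache_locations": np.asarray(model.cache_locations, dtype=int),
    }
    if model.weights.M_pred is not None:
        arrays["M_pred"] = model.weights.M_pred
    return save_arrays(
        path, arrays, config=model.config, seed=model.streams.master_seed
    )


def load_model_snapshot(path: str | Path) -> BarcodeMemory:
    arrays, meta = load_arrays(path)
    config = ModelConfig(**meta["config"])
    model = BarcodeMemory(config, seed=meta["seed"])
    model.weights.B = arrays["B"]
    model.weights.H = arrays["H"]
    if "M_pred" in arrays:
        model.weights.M_pred = arrays["M_pred"]
    model.seed_path.j_in = arrays["j_in"]
    model.readout.w_seed = arrays["w_seed"]
    model.readout.J_place = arrays["J_place"]
    model.bank.vectors = arrays["bank"]
    model.bank.preferred_locations = arrays["preferred"]
    from .memory import EpisodeTrace

    for loc in arrays["cache_locations"]:
        model.traces.append(
            EpisodeTrace(
                location=int(loc),
                x_stored=np.zeros(config.N_x, dtype=config.np_dtype),
                p_stored=model.bank.vectors[int(loc)],
                s_used=config.lam,
            )
        )
    return model


def fixture_config(size: str = "small") -> ModelConfig:
    """Deterministic reduced configurations for fast tests and smoke runs."""
    if size == "small":
        return ModelConfig(N_p=200, N_x=200, N_y=200, N_s=20)
    if size == "default":
        return ModelConfig()
    raise ValueError(f"unknown fixture size {size!r}; use 'small' or 'default'")


def make_fixture(size: str = "small", seed: int = 0, path: Optional[str | Path] = None):
    """Build (and optionally save) a small model with two stored caches."""
    config = fixture_config(size)
    model = BarcodeMemory(config, seed=seed)
    for frac in (0.25, 0.7):
        model.store_cache(int(round(frac * config.N_s)))
    if path is not None:
        save_model_snapshot(model, path)
    return model
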