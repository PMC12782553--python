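"""Model configuration and random-stream management.

Every tunable hyperparameter of the barcode memory network lives in a single
validated :class:`ModelConfig` record.  Configs can be round-tripped through a
flat ``key = value`` text file; unknown keys are rejected so that typos fail
loudly rather than silently running defaults.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

__all__ = ["ModelConfig", "RandomStreams", "ConfigError"]


class ConfigError(ValueError):
    """Raised for invalid or unknown configuration values."""


# named substreams fanned out from the master seed; fixed indices ensure that
# toggling one randomness source never shifts the draws of another
_STREAM_INDEX = {
    "weights": 0,
    "seed_pathway": 1,
    "noise": 2,
    "spikes": 3,
    "gp_inputs": 4,
    "feedforward": 5,
    "task": 6,
}


@dataclass
class ModelConfig:
    """Hyperparameters of the barcode memory network.

    The network is a rate RNN receiving spatially tuned place input on a
    circular track of ``N_s`` discrete states.  Recurrent weights are random
    (mean ``mu / N_x``, scale ``sigma**2 / N_x``); shunting inhibition of
    strength ``alpha`` divisively normalizes activity; Hebbian plasticity with
    rate ``eta`` and bias ``beta`` stores cache events as attractors.

    Parameters are expressed per-N so that the network can be scaled down
    (e.g. for tests) while preserving the dynamical regime.
    """

    # place inputs
    nu: float = 0.2            # spatial scale of place input, fraction of track
    N_p: int = 5000            # place input neurons
    N_x: int = 5000            # recurrent neurons (must equal N_p: 1-to-1 wiring)
    N_y: int = 5000            # place-readout units
    N_s: int = 100             # discrete track states

    # recurrent weights
    mu: float = -40.0          # weight-mean scale; mean = mu / N_x
    sigma: float = 7.0         # weight-fluctuation scale (see network module)
    N_ref: int = 5000          # reference size anchoring the fluctuation scale

    # dynamics
    dt: float = 0.1            # Euler integration step
    alpha: float = 6.0         # divisive-normalization (shunting) strength
    T: int = 100               # length of recurrent dynamics (steps by default)
    T_in_time_units: bool = False  # if True, T counts time units (steps = T/dt)
    t_s: int = 5               # seed-input duration (steps) in caching mode

    # learning
    lam: float = 1.0           # seed-input strength during caching
    eta: float = 40.0          # Hebbian learning rate
    beta: float = -0.35        # inhibitory plasticity bias (negative)

    # readout / analysis
    kappa: float = 0.5         # seed-output decision threshold
    k_spike: float = 0.2       # Poisson rate scale for spike simulation
    K_offset: float = 0.2      # Poisson offset (visualization variant)

    # predictive-map (successor representation) variant
    gamma: float = 0.99        # temporal discount
    rho: float = 0.075         # SR scale
    delta_off: float = -0.015  # SR inhibitory offset
    D: int = 300               # SR series truncation (neuron-index steps)

    # feedforward variant
    M_hidden: int = 20000      # hidden expansion layer size
    theta: float = 0.01        # hidden-layer active fraction

    # bookkeeping
    rng_seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        for name in ("N_p", "N_x", "N_y", "N_s", "N_ref", "T", "t_s", "D", "M_hidden"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        if self.N_p != self.N_x:
            raise ConfigError(
                f"N_p ({self.N_p}) must equal N_x ({self.N_x}): place inputs are "
                "wired one-to-one onto recurrent units"
            )
        if self.nu <= 0:
            raise ConfigError(f"nu must be > 0, got {self.nu}")
        if self.dt <= 0:
            raise ConfigError(f"dt must be > 0, got {self.dt}")
        if self.beta >= 0:
            raise ConfigError(f"beta must be < 0, got {self.beta}")
        if self.eta <= 0:
            raise ConfigError(f"eta must be > 0, got {self.eta}")
        if not (0.0 < self.kappa < 1.0):
            raise ConfigError(f"kappa must lie in (0, 1), got {self.kappa}")
        if self.n_steps < self.t_s:
            raise ConfigError(
                f"T (={self.n_steps} steps) must be >= t_s (={self.t_s})"
            )
        if not (0.0 < self.gamma < 1.0):
            raise ConfigError(f"gamma must lie in (0, 1), got {self.gamma}")
        if not (0.0 < self.theta <= 1.0):
            raise ConfigError(f"theta must lie in (0, 1], got {self.theta}")
        if self.lam < 0:
            raise ConfigError(f"lam must be >= 0, got {self.lam}")

    # -- derived quantities -------------------------------------------------
    @property
    def n_steps(self) -> int:
        """Number of Euler steps per dynamics run."""
        if self.T_in_time_units:
            return int(round(self.T / self.dt))
        return int(self.T)

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)

    def replace(self, **kwargs) -> "ModelConfig":
        """Return a copy with selected fields changed (re-validated)."""
        return dataclasses.replace(self, **kwargs)

    # -- file I/O ------------------------------------------------------------
    @classmethod
    def from_file(cls, path: str | Path) -> "ModelConfig":
        """Read a flat ``key = value`` text config; unknown keys are rejected."""
        known = {f.name: f for f in fields(cls)}
        values: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in known:
                raise ConfigError(f"{path}:{lineno}: unknown config key {key!r}")
            values[key] = _coerce(val, known[key].type)
        return cls(**values)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _coerce(val: str, annot) -> object:
    txt = str(annot)
    if "bool" in txt:
        if val.lower() in ("true", "1", "yes"):
            return True
        if val.lower() in ("false", "0", "no"):
            return False
        raise ConfigError(f"cannot parse boolean from {val!r}")
    if "int" in txt:
        return int(val)
    if "float" in txt:
        return float(val)
    return val


class RandomStreams:
    """Named, independent random streams fanned out from one master seed.

    Each stream is an independent :class:`numpy.random.Generator` derived from
    ``SeedSequence(master_seed).spawn``; the mapping from name to spawn index
    is fixed, so enabling or disabling one source of randomness (e.g. spike
    simulation) never changes the draws of the others.
    """

    def __init__(self, master_seed: int):
        self.master_seed = int(master_seed)
        root = np.random.SeedSequence(self.master_seed)
        children = root.spawn(len(_STREAM_INDEX))
        self._gens = {
            name: np.random.default_rng(children[idx])
            for name, idx in _STREAM_INDEX.items()
        }

    def __getitem__(self, name: str) -> np.random.Generator:
        try:
            return self._gens[name]
        except KeyError:
            raise KeyError(
                f"unknown stream {name!r}; valid: {sorted(_STREAM_INDEX)}"
            ) from None

    def child_seed(self, index: int) -> int:
        """Deterministic per-replicate seed derived from the master (< 2**31)."""
        h = np.random.SeedSequence((self.master_seed, int(index)))
        return int(h.generate_state(1, np.uint32)[0] % (2**31))
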