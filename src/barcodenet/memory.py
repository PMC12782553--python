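"""Hebbian storage of cache events and plastic readouts.

A cache event runs caching-mode dynamics at a location, then binds the final
activity pattern into (i) the recurrent weights via the biased Hebbian rule

    dJ = (eta / N_x) * (x x^T + beta * x 1^T),   beta < 0

making the pattern a fixed-point attractor, and (ii) two plastic readouts: a
seed-output vector (reports whether a stored memory has been reactivated) and
a place-output matrix (reconstructs the place input bound to the memory).
The negative bias acts as an ignition gate at recall: activity must overlap a
stored pattern strongly enough, relative to total population activity, for
pattern completion to take hold; weaker cues are actively suppressed.
Readout increments carry the same eta/N_x scale as the recurrent rule, which
keeps the seed output O(1) and network-size invariant.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .config import ModelConfig, RandomStreams
from .network import (
    InputSchedule,
    NetworkState,
    NoiseSpec,
    PlaceInputBank,
    RecurrentWeights,
    SeedPathway,
    build_place_inputs,
    init_recurrent_weights,
    init_seed_pathway,
    run_mode,
)

__all__ = ["ReadoutWeights", "EpisodeTrace", "hebbian_update", "BarcodeMemory"]


@dataclass
class ReadoutWeights:
    """Plastic readouts, both exactly zero before the first cache."""

    w_seed: np.ndarray   # (N_x,)
    J_place: np.ndarray  # (N_p, N_x)

    @classmethod
    def zeros(cls, config: ModelConfig) -> "ReadoutWeights":
        return cls(
            w_seed=np.zeros(config.N_x, dtype=config.np_dtype),
            J_place=np.zeros((config.N_p, config.N_x), dtype=config.np_dtype),
        )


@dataclass
class EpisodeTrace:
    """Snapshot of one storage event, recorded before weights change."""

    location: int
    x_stored: np.ndarray
    p_stored: np.ndarray
    s_used: float


def hebbian_update(
    weights: RecurrentWeights, x: np.ndarray, config: ModelConfig
) -> RecurrentWeights:
    """Apply dJ_ij = (eta/N_x) * (x_i x_j + beta * x_i) to the accumulator H.

    The bias multiplies the postsynaptic factor: rows of dJ are nonzero only
    where x_i > 0, and every synapse onto an active neuron is weakened by
    |beta| * x_i regardless of presynaptic activity.
    """
    x = np.asarray(x)
    if x.ndim != 1 or x.shape[0] != config.N_x:
        raise ValueError(f"x must have shape ({config.N_x},), got {x.shape}")
    if np.any(x < 0):
        raise ValueError("activity vector must be nonnegative")
    scale = config.eta / config.N_x
    x = x.astype(weights.B.dtype, copy=False)
    # (eta/N)(x x^T + beta x 1^T) == scale * outer(x, x + beta)
    weights.H += scale * np.outer(x, x + config.beta)
    return weights


class BarcodeMemory:
    """The assembled memory model: network + seed pathway + readouts.

    Parameters
    ----------
    config
        Model hyperparameters.
    seed
        Master seed; fans out to named independent streams.
    bank, weights
        Optional pre-built place inputs or recurrent weights (used by the
        model variants); defaults are built from the config.
    noise
        Optional :class:`NoiseSpec` applied to every dynamics run.
    """

    def __init__(
        self,
        config: ModelConfig,
        seed: Optional[int] = None,
        bank: Optional[PlaceInputBank] = None,
        weights: Optional[RecurrentWeights] = None,
        noise: Optional[NoiseSpec] = None,
    ):
        self.config = config
        self.streams = RandomStreams(config.rng_seed if seed is None else seed)
        self.bank = bank if bank is not None else build_place_inputs(config)
        self.weights = (
            weights
            if weights is not None
            else init_recurrent_weights(config, self.streams["weights"])
        )
        self.seed_path = init_seed_pathway(config, self.streams["seed_pathway"])
        self.readout = ReadoutWeights.zeros(config)
        self.traces: List[EpisodeTrace] = []
        if noise is not None and noise.rng is None and (
            noise.dynamic_sd > 0 or noise.static_sd > 0
        ):
            noise.rng = self.streams["noise"]
        self.noise = noise

    # -- dynamics wrappers ---------------------------------------------------
    def run(self, location, schedule: InputSchedule) -> NetworkState:
        return run_mode(
            location, schedule, self.weights, self.seed_path,
            self.bank, self.config, noise=self.noise,
        )

    def visit_activity(self, location) -> np.ndarray:
        """Place-mode (r=0) final rates; proportional to the place input."""
        return self.run(location, InputSchedule.place(self.config)).x

    def gain_activity(self, location, r: float) -> np.ndarray:
        """Final rates under an intermediate recurrence gain, no seed input."""
        return self.run(location, InputSchedule.gain(self.config, r)).x

    # -- memory operations ---------------------------------------------------
    def store_cache(self, location: int) -> EpisodeTrace:
        """Run caching dynamics at ``location`` and bind the final pattern."""
        state = self.run(int(location), InputSchedule.caching(self.config))
        x = state.x.copy()
        p = self.bank.vectors[int(location)].copy()
        trace = EpisodeTrace(
            location=int(location), x_stored=x, p_stored=p,
            s_used=self.config.lam,
        )
        # record-then-update: the trace holds the pattern as it was stored
        hebbian_update(self.weights, x, self.config)
        scale = self.config.eta / self.config.N_x
        self.readout.w_seed += scale * x
        self.readout.J_place += scale * np.outer(p, x)
        self.traces.append(trace)
        return trace

    def recall_event(self, location, s_strength: float = 0.0):
        """Recall-mode dynamics; returns (x_final, y_seed, y_place).

        ``location`` may be a sequence, in which case ``y_seed`` has one entry
        per queried state and ``y_place`` one column per state.
        """
        state = self.run(location, InputSchedule.recall(self.config, s_strength))
        x = state.x
        y_seed = self.readout.w_seed @ x
        y_place = self.readout.J_place @ x
        return x, y_seed, y_place

    # -- convenience ---------------------------------------------------------
    @property
    def cache_locations(self) -> List[int]:
        return [t.location for t in self.traces]

    def place_peak_states(self, y_place: np.ndarray) -> np.ndarray:
        """Map place-output peaks to track states via preferred locations."""
        y = np.atleast_2d(y_place.T).T  # ensure (N_p, B)
        idx = np.argmax(y, axis=0)
        return self.bank.preferred_locations[idx] * self.config.N_s
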