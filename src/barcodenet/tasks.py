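"""Caching-task protocols, decision rules, metrics, and ablations.

The behavioral protocol stores a sequence of caches on the circular track and
then probes recall from every state.  Two readout-based decisions quantify
memory:

* **Cache Presence** — is there a stored seed at the current location?
  Decided by thresholding the seed output at ``kappa`` (strictly greater).
* **Cache Location** — where is the nearest cache?  A recall is successful if
  the seed output clears ``kappa`` AND the place-output peak falls within a
  tolerance window of the cache nearest to the probe position.

Aggregation across replicate networks uses normal-approximation binomial
confidence intervals at the configured level (default 99%).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import ModelConfig, RandomStreams
from .memory import BarcodeMemory
from .network import circular_distance

__all__ = [
    "TaskSpec",
    "TaskResult",
    "ModelFactory",
    "default_factory",
    "make_ablation",
    "cache_presence_decision",
    "cache_location_success",
    "run_three_cache_task",
    "correct_reject_sweep",
    "single_cache_width",
    "binomial_ci",
]

ModelFactory = Callable[[ModelConfig, int], BarcodeMemory]


def default_factory(config: ModelConfig, seed: int) -> BarcodeMemory:
    """Fresh full model for one replicate."""
    return BarcodeMemory(config, seed=seed)


def make_ablation(kind: str, config: ModelConfig) -> ModelFactory:
    """Factories for the two component-ablated models.

    ``place_only`` removes the random recurrence that generates barcodes
    (weights initialized with mu=0, sigma=0), leaving storage driven by place
    correlations alone.  ``barcode_only`` removes spatial correlation from the
    inputs (place scale nu=1e-3), so each state's input is essentially a
    one-hot pattern and no proximity structure exists.
    """
    if kind == "place_only":
        cfg = config.replace(mu=0.0, sigma=0.0)
    elif kind == "barcode_only":
        cfg = config.replace(nu=1e-3)
    elif kind == "full":
        cfg = config
    else:
        raise ValueError(
            f"unknown ablation {kind!r}; valid: 'place_only', 'barcode_only', 'full'"
        )

    def factory(_config_ignored: ModelConfig, seed: int) -> BarcodeMemory:
        return BarcodeMemory(cfg, seed=seed)

    return factory


# --------------------------------------------------------------------------
# decisions
# --------------------------------------------------------------------------

def cache_presence_decision(y_seed: float, config: ModelConfig) -> bool:
    """Seed present iff the seed output strictly exceeds kappa."""
    return bool(y_seed > config.kappa)


def state_distance(a, b, N_s: int) -> np.ndarray:
    """Circular distance between track states, in states."""
    d = np.abs(np.asarray(a, float) - np.asarray(b, float)) % N_s
    return np.minimum(d, N_s - d)


def nearest_cache(position, caches: Sequence[int], N_s: int) -> np.ndarray:
    """State index of the cache closest to each position (ties -> first)."""
    pos = np.atleast_1d(position)
    caches = np.asarray(list(caches))
    d = state_distance(pos[:, None], caches[None, :], N_s)
    return caches[np.argmin(d, axis=1)]


def cache_location_success(
    y_seed: float,
    y_place: np.ndarray,
    position: int,
    caches: Sequence[int],
    config: ModelConfig,
    bank,
    window: float = 4.0,
) -> bool:
    """Conjunctive success rule for the Cache Location task.

    True iff the seed output exceeds kappa and the place-output peak (mapped
    to a track state through the argmax unit's preferred location) lies within
    ``window`` states of the cache nearest to the probed position.  If two
    caches are equidistant, either is accepted.
    """
    if len(caches) == 0:
        raise ValueError("cache_location_success requires at least one stored cache")
    if not cache_presence_decision(y_seed, config):
        return False
    peak_state = bank.preferred_locations[int(np.argmax(y_place))] * config.N_s
    pos_d = state_distance(position, np.asarray(list(caches)), config.N_s)
    best = np.flatnonzero(pos_d == pos_d.min())
    return bool(
        any(
            state_distance(peak_state, list(caches)[i], config.N_s) <= window
            for i in best
        )
    )


def binomial_ci(successes: np.ndarray, n: int, level: float = 0.99):
    """Normal-approximation binomial CI on a success probability."""
    p = np.asarray(successes, float) / max(n, 1)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(np.clip(p * (1 - p), 0, None) / max(n, 1))
    return p, np.clip(p - half, 0, 1), np.clip(p + half, 0, 1)


# --------------------------------------------------------------------------
# task protocol
# --------------------------------------------------------------------------

@dataclass
class TaskSpec:
    """Protocol for one simulated caching experiment.

    ``cache_fractions`` are track positions as fractions of circumference
    (the standard protocol caches at 20%, 35% and 70%); ``s_values`` the
    recall search strengths probed; ``n_seeds`` the replicate count.
    """

    cache_fractions: Tuple[float, ...] = (0.2, 0.35, 0.7)
    cache_order: Optional[Tuple[int, ...]] = None  # permutation of caches
    s_values: Tuple[float, ...] = (0.0, 0.4, 1.5)
    n_seeds: int = 35
    ci_level: float = 0.99
    stages: str = "final"     # evaluate after "final" cache or after "each"
    window: float = 4.0       # Cache Location tolerance, in states

    def locations(self, N_s: int) -> List[int]:
        locs = [int(round(f * N_s)) % N_s for f in self.cache_fractions]
        if len(set(locs)) != len(locs):
            raise ValueError(f"cache locations must be distinct, got {locs}")
        order = self.cache_order or tuple(range(len(locs)))
        if sorted(order) != list(range(len(locs))):
            raise ValueError(f"cache_order must permute {len(locs)} caches")
        return [locs[i] for i in order]


@dataclass
class TaskResult:
    """Aggregated outcome of a replicated caching task."""

    spec: TaskSpec
    config: ModelConfig
    # mean seed-output per (stage, s, state); stages as stored-cache counts
    y_seed_curves: Dict[Tuple[int, float], np.ndarray]
    # tidy per-state metrics after the final cache
    table: pd.DataFrame

    def success_curve(self, s: float) -> pd.DataFrame:
        """Recall success vs distance (states) to the nearest cache.

        Successes are pooled over replicates and over states sharing the same
        distance to their nearest cache.
        """
        t = self.table[np.isclose(self.table["s"], s)]
        out = []
        for d, sub in t.groupby("dist_nearest"):
            k, m = sub["success"].sum(), len(sub)
            pp, ll, hh = binomial_ci(np.array([k]), m, self.spec.ci_level)
            out.append((d, float(pp[0]), float(ll[0]), float(hh[0]), m))
        return pd.DataFrame(out, columns=["dist_nearest", "p", "lo", "hi", "n"])

    def presence_at(self, state: int, s: float) -> float:
        t = self.table[
            (self.table["state"] == state) & np.isclose(self.table["s"], s)
        ]
        return float(t["present"].mean())


def run_three_cache_task(
    spec: TaskSpec,
    config: ModelConfig,
    factory: ModelFactory = default_factory,
    master_seed: int = 0,
    query_states: Optional[Sequence[int]] = None,
) -> TaskResult:
    """Run the replicated caching task and aggregate the two task metrics.

    For each replicate a fresh model is built from a derived seed, the caches
    are stored in the spec's order, and recall is probed at ``query_states``
    (default: every state) for every search strength.  Per-state presence and
    location-success indicators are pooled over replicates.
    """
    streams = RandomStreams(master_seed)
    locs = spec.locations(config.N_s)
    queries = (
        np.arange(config.N_s) if query_states is None else np.asarray(query_states)
    )
    stages = (
        [len(locs)] if spec.stages == "final" else list(range(1, len(locs) + 1))
    )

    curves: Dict[Tuple[int, float], np.ndarray] = {
        (st, s): np.zeros(len(queries)) for st in stages for s in spec.s_values
    }
    rows = []
    for rep in range(spec.n_seeds):
        seed = streams.child_seed(rep)
        model = factory(config, seed)
        n_stored = 0
        for loc in locs:
            model.store_cache(loc)
            n_stored += 1
            if n_stored not in stages:
                continue
            for s in spec.s_values:
                _, y_seed, y_place = model.recall_event(queries, s_strength=s)
                curves[(n_stored, s)] += y_seed
                if n_stored == len(locs):
                    cached_now = model.cache_locations
                    near = nearest_cache(queries, cached_now, config.N_s)
                    d_near = state_distance(queries, near, config.N_s)
                    peak_states = model.place_peak_states(y_place)
                    peak_ok = (
                        state_distance(peak_states, near, config.N_s) <= spec.window
                    )
                    present = y_seed > config.kappa
                    for j, q in enumerate(queries):
                        rows.append(
                            (rep, int(q), float(s), float(y_seed[j]),
                             bool(present[j]), bool(present[j] and peak_ok[j]),
                             float(d_near[j]))
                        )
        del model
    for key in curves:
        curves[key] /= spec.n_seeds
    table = pd.DataFrame(
        rows,
        columns=["rep", "state", "s", "y_seed", "present", "success", "dist_nearest"],
    )
    return TaskResult(spec=spec, config=config, y_seed_curves=curves, table=table)


def correct_reject_sweep(
    config: ModelConfig,
    spacings: Sequence[int],
    s_values: Sequence[float] = (0.0, 0.4, 1.5),
    n_seeds: int = 35,
    factory: ModelFactory = default_factory,
    master_seed: int = 0,
    base_fraction: float = 0.2,
    third_fraction: float = 0.7,
    ci_level: float = 0.99,
) -> pd.DataFrame:
    """Cache Presence at the midpoint between two caches, vs their spacing.

    For each spacing ``2*h`` (states), caches are made at ``c1``, ``c1+2h``
    and a distant third site; the probed midpoint sits ``h`` states from both
    flanking caches.  With even spacing the exact midpoint falls between two
    states; the floor state is probed.  Returns a tidy frame with the
    correct-reject probability (seed output <= kappa at the empty midpoint)
    and CI per (spacing, s).
    """
    streams = RandomStreams(master_seed)
    c1 = int(round(base_fraction * config.N_s))
    c3 = int(round(third_fraction * config.N_s))
    rows = []
    for spacing in spacings:
        c2 = (c1 + int(spacing)) % config.N_s
        mid = (c1 + int(spacing) // 2) % config.N_s  # floor state for odd spacing
        rejects = {s: 0 for s in s_values}
        for rep in range(n_seeds):
            seed = streams.child_seed(10_000 + 97 * int(spacing) + rep)
            model = factory(config, seed)
            for loc in (c1, c2, c3):
                model.store_cache(loc)
            for s in s_values:
                _, y_seed, _ = model.recall_event(np.array([mid]), s_strength=s)
                if not cache_presence_decision(float(y_seed[0]), config):
                    rejects[s] += 1
            del model
        for s in s_values:
            p, lo, hi = binomial_ci(np.array([rejects[s]]), n_seeds, ci_level)
            rows.append(
                (int(spacing), float(spacing) / 2.0, float(s),
                 float(p[0]), float(lo[0]), float(hi[0]), n_seeds)
            )
    return pd.DataFrame(
        rows,
        columns=["spacing", "dist_to_flank", "s", "p_correct_reject", "lo", "hi", "n"],
    )


def single_cache_width(
    config: ModelConfig,
    n_seeds: int = 10,
    factory: ModelFactory = default_factory,
    master_seed: int = 0,
    cache_fraction: float = 0.5,
    s: float = 0.0,
) -> pd.DataFrame:
    """Width of the supra-threshold seed-output region around a lone cache.

    Returns per-replicate left/right extents (contiguous states with
    y_seed > kappa adjacent to the cache) in states.
    """
    streams = RandomStreams(master_seed)
    c = int(round(cache_fraction * config.N_s))
    rows = []
    for rep in range(n_seeds):
        seed = streams.child_seed(20_000 + rep)
        model = factory(config, seed)
        model.store_cache(c)
        _, y_seed, _ = model.recall_event(np.arange(config.N_s), s_strength=s)
        above = y_seed > config.kappa
        left = right = 0
        for d in range(1, config.N_s // 2):
            if above[(c + d) % config.N_s]:
                right += 1
            else:
                break
        for d in range(1, config.N_s // 2):
            if above[(c - d) % config.N_s]:
                left += 1
            else:
                break
        rows.append((rep, bool(above[c]), left, right))
        del model
    return pd.DataFrame(rows, columns=["rep", "present_at_cache", "left", "right"])
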