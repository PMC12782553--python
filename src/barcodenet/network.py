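"""Core recurrent network: place inputs, random weights, rate dynamics.

The model is a ReLU rate network on a circular track.  Voltages evolve under

    dv/dt = -(alpha/N_x) * sum(x) * v  +  r * J @ x  +  p  +  s * j_in
    x = relu(v)

integrated with explicit Euler steps of size ``dt`` from the zero state.  The
first term is shunting inhibition proportional to total population activity (a
divisive normalization that prevents runaway excitation); ``r`` gates the
recurrent contribution (r=0 feedforward "visit" mode, r=1 full recurrence for
caching and recall); ``p`` is the place input for the current track state and
``s`` a scalar seed input delivered through a fixed random pathway.

With recurrence on, the combination of subtractive inhibition (negative mean
weights) and quenched random weight fluctuations drives a winner-take-all
competition whose outcome is a sparse activity pattern essentially
uncorrelated between distant states — the "barcode" used as a memory index.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import ModelConfig

__all__ = [
    "PlaceInputBank",
    "RecurrentWeights",
    "SeedPathway",
    "NetworkState",
    "InputSchedule",
    "NoiseSpec",
    "DivergenceError",
    "build_place_inputs",
    "init_recurrent_weights",
    "init_seed_pathway",
    "step_dynamics",
    "run_mode",
]


class DivergenceError(FloatingPointError):
    """Raised when the Euler integration produces non-finite voltages."""


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class PlaceInputBank:
    """Per-state place input vectors.

    ``vectors[k, l]`` is the drive onto neuron ``l`` when the agent occupies
    track state ``k``; ``preferred_locations[l]`` is the track position (as a
    fraction of circumference in [0, 1)) where neuron ``l``'s input peaks.
    """

    vectors: np.ndarray              # (N_s, N_p)
    preferred_locations: np.ndarray  # (N_p,)

    def input_for(self, states) -> np.ndarray:
        """Column-stacked inputs for one or more states, shape (N_p, B)."""
        return self.vectors[np.atleast_1d(states)].T


@dataclass
class RecurrentWeights:
    """Recurrent connectivity: random base + optional predictive + Hebbian.

    The effective weight matrix is ``J = B + M_pred + H``.  ``B`` is frozen
    after initialization; only ``H`` accumulates learning.
    """

    B: np.ndarray                       # (N_x, N_x) random base
    M_pred: Optional[np.ndarray] = None  # (N_x, N_x) predictive map, or None
    H: Optional[np.ndarray] = None       # (N_x, N_x) Hebbian increments

    def __post_init__(self):
        if self.H is None:
            self.H = np.zeros_like(self.B)

    @property
    def effective(self) -> np.ndarray:
        J = self.B + self.H
        if self.M_pred is not None:
            J = J + self.M_pred
        return J


@dataclass
class SeedPathway:
    """Fixed input weights from the scalar seed unit onto recurrent neurons."""

    j_in: np.ndarray  # (N_x,), standard normal at init, never learned


@dataclass
class NetworkState:
    """Voltages and rates of the recurrent population (possibly batched)."""

    v: np.ndarray     # (N_x,) or (N_x, B)
    x: np.ndarray     # relu(v), same shape
    step: int = 0

    @classmethod
    def zeros(cls, N_x: int, batch: Optional[int] = None, dtype=np.float32):
        shape = (N_x,) if batch is None else (N_x, batch)
        v = np.zeros(shape, dtype=dtype)
        return cls(v=v, x=v.copy(), step=0)


@dataclass
class InputSchedule:
    """Per-step gains for one dynamics run.

    ``r`` is the recurrence gain, ``s`` the per-step seed-input strength and
    ``p_active`` whether place input is delivered.  The three behavioral modes
    are:

    * place (visit): r=0, s=0, place on for all steps;
    * caching: r=1, place on, seed at strength ``lam`` for the final ``t_s``
      steps only;
    * recall: r=1, place on, seed at the (freely chosen) search strength for
      every step.
    """

    mode: str
    r: float
    s: np.ndarray          # (n_steps,)
    p_active: bool = True

    @classmethod
    def place(cls, config: ModelConfig) -> "InputSchedule":
        return cls("place", 0.0, np.zeros(config.n_steps))

    @classmethod
    def caching(cls, config: ModelConfig) -> "InputSchedule":
        s = np.zeros(config.n_steps)
        s[config.n_steps - config.t_s:] = config.lam
        return cls("caching", 1.0, s)

    @classmethod
    def recall(cls, config: ModelConfig, s_strength: float) -> "InputSchedule":
        if s_strength < 0:
            raise ValueError(f"search strength must be >= 0, got {s_strength}")
        return cls("recall", 1.0, np.full(config.n_steps, float(s_strength)))

    @classmethod
    def gain(cls, config: ModelConfig, r: float) -> "InputSchedule":
        """Recurrence-gain sweep mode (predictive-map analyses): 0 <= r <= 1."""
        return cls("gain", float(r), np.zeros(config.n_steps))


@dataclass
class NoiseSpec:
    """Optional perturbations: per-step dynamics noise and static offsets.

    ``dynamic_sd`` adds N(0, dynamic_sd^2 * dt) noise to each voltage update
    (Euler–Maruyama scaling); ``static_sd`` draws one Gaussian offset vector
    per run and adds it to the place input and the initial voltage.  Defaults
    are zero: the printed model is deterministic given its seed.
    """

    dynamic_sd: float = 0.0
    static_sd: float = 0.0
    rng: Optional[np.random.Generator] = None

    def require_rng(self) -> np.random.Generator:
        if self.rng is None:
            raise ValueError("NoiseSpec with nonzero sd needs an rng")
        return self.rng


# --------------------------------------------------------------------------
# construction
# --------------------------------------------------------------------------

def circular_distance(a: np.ndarray, b: np.ndarray, circumference: float = 1.0) -> np.ndarray:
    """Minimum distance on a circle of the given circumference."""
    d = np.abs(np.asarray(a, float) - np.asarray(b, float)) % circumference
    return np.minimum(d, circumference - d)


def build_place_inputs(config: ModelConfig) -> PlaceInputBank:
    """Exponential place tuning: drive = exp(-d / nu).

    ``d`` is the minimum circular distance between the queried state and the
    neuron's preferred location, as a fraction of track circumference.
    Preferred locations tile the track evenly (N_p points on [0, 1)), so with
    the defaults 50 neurons share each of the 100 states.
    """
    if config.nu <= 0:
        raise ValueError(f"nu must be positive, got {config.nu}")
    pref = np.arange(config.N_p, dtype=np.float64) / config.N_p
    states = np.arange(config.N_s, dtype=np.float64) / config.N_s
    d = circular_distance(states[:, None], pref[None, :])
    vectors = np.exp(-d / config.nu).astype(config.np_dtype)
    return PlaceInputBank(vectors=vectors, preferred_locations=pref)


def init_recurrent_weights(
    config: ModelConfig, rng: np.random.Generator
) -> RecurrentWeights:
    """Random Gaussian base weights, mean mu/N_x, sd sigma^2/sqrt(N_x*N_ref).

    At the reference size (N_x = N_ref = 5000) the entry scale is
    sigma^2/N_x.  For scaled-down networks the sd is anchored to the
    reference size so that the per-unit recurrent fluctuation — which is what
    places the network in the input-driven, intermediate, or scrambled regime
    — is independent of N_x; a reduced simulation then reproduces the
    reference dynamics rather than drifting into a more chaotic regime.

    The Hebbian accumulator starts at exactly zero; the predictive component
    is absent unless installed later (hybrid variant).
    """
    mean = config.mu / config.N_x
    scale = config.sigma**2 / np.sqrt(float(config.N_x) * config.N_ref)
    B = rng.normal(mean, scale, (config.N_x, config.N_x)) if scale > 0 else np.full(
        (config.N_x, config.N_x), mean
    )
    return RecurrentWeights(B=B.astype(config.np_dtype))


def init_seed_pathway(config: ModelConfig, rng: np.random.Generator) -> SeedPathway:
    """Seed-input weights drawn from the standard normal; never learned."""
    return SeedPathway(j_in=rng.standard_normal(config.N_x).astype(config.np_dtype))


# --------------------------------------------------------------------------
# dynamics
# --------------------------------------------------------------------------

def step_dynamics(
    state: NetworkState,
    p_vec: np.ndarray,
    s_val: float,
    r: float,
    weights: RecurrentWeights,
    seed_path: SeedPathway,
    config: ModelConfig,
    J: Optional[np.ndarray] = None,
    noise_vec: Optional[np.ndarray] = None,
) -> NetworkState:
    """One explicit-Euler update of the voltage dynamics (in place).

    ``J`` may be passed to avoid recomputing ``weights.effective`` every step.
    Raises :class:`DivergenceError` on non-finite voltages.
    """
    v, x = state.v, state.x
    batched = v.ndim == 2
    if r != 0.0 and J is None:
        J = weights.effective

    # The explicit Euler map is stable only while dt times the local rate of
    # change stays moderate.  Runaway activity (pathological regimes such as
    # heavily interfering stored patterns) stiffens both the shunting leak
    # and the learned recurrent drive; the step is then subdivided so the
    # integration tracks the bounded continuous dynamics instead of
    # overflowing.  In all calibrated regimes a single full step is taken
    # and the update is identical to plain Euler.
    def derivative(v_cur, x_cur):
        leak = (config.alpha / config.N_x) * x_cur.sum(axis=0)
        dv = -leak * v_cur if not batched else -(leak[None, :] * v_cur)
        if p_vec is not None:
            dv = dv + p_vec
        if r != 0.0:
            dv = dv + r * (J @ x_cur)
        if s_val != 0.0:
            j = seed_path.j_in
            dv = dv + s_val * (j if not batched else j[:, None])
        if noise_vec is not None:
            dv = dv + noise_vec
        return dv

    remaining = config.dt
    for _ in range(512):
        dv = derivative(v, x)
        scale = float(np.max(np.abs(dv))) / (float(np.max(np.abs(v))) + 1.0)
        h = remaining if scale * remaining <= 0.5 else 0.5 / scale
        v = v + h * dv
        if not np.all(np.isfinite(v)):
            raise DivergenceError(
                f"non-finite voltage at step {state.step + 1} "
                f"(mode r={r}, s={s_val}); reduce dt or check weights"
            )
        x = np.maximum(v, 0.0)
        remaining -= h
        if remaining <= 1e-12:
            break
    else:
        raise DivergenceError(
            f"voltage dynamics too stiff at step {state.step + 1} "
            f"(mode r={r}, s={s_val})"
        )
    state.v = v
    state.x = x
    state.step += 1
    return state


def run_mode(
    location,
    schedule: InputSchedule,
    weights: RecurrentWeights,
    seed_path: SeedPathway,
    bank: PlaceInputBank,
    config: ModelConfig,
    noise: Optional[NoiseSpec] = None,
) -> NetworkState:
    """Integrate ``n_steps`` from the zero state under the given schedule.

    ``location`` may be a single state index or a sequence of indices; in the
    batched case the returned state has shape ``(N_x, len(location))`` and the
    runs are fully independent (the shunting term is computed per column).
    """
    locs = np.atleast_1d(location)
    if np.any((locs < 0) | (locs >= config.N_s)):
        raise ValueError(f"location out of range [0, {config.N_s}): {location}")
    batch = None if np.isscalar(location) or np.ndim(location) == 0 else len(locs)
    state = NetworkState.zeros(config.N_x, batch, dtype=config.np_dtype)

    p = bank.input_for(locs) if schedule.p_active else None
    if p is not None and batch is None:
        p = p[:, 0]

    static = None
    if noise is not None and noise.static_sd > 0:
        g = noise.require_rng()
        shape = state.v.shape
        static = noise.static_sd * g.standard_normal(shape).astype(config.np_dtype)
        state.v = state.v + static
        state.x = np.maximum(state.v, 0.0)
        if p is not None:
            p = p + static

    J = weights.effective if schedule.r != 0.0 else None
    sqrt_dt = np.sqrt(config.dt)
    for t in range(config.n_steps):
        nvec = None
        if noise is not None and noise.dynamic_sd > 0:
            g = noise.require_rng()
            # Euler–Maruyama: dv gets noise of sd dynamic_sd*sqrt(dt) after the
            # dt multiplication, i.e. contribute dynamic_sd/sqrt(dt) to dv
            nvec = (noise.dynamic_sd / sqrt_dt) * g.standard_normal(
                state.v.shape
            ).astype(config.np_dtype)
        step_dynamics(
            state, p, float(schedule.s[t]), schedule.r,
            weights, seed_path, config, J=J, noise_vec=nvec,
        )
    return state
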