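"""Model variants: predictive-map hybrid, feedforward barcodes, GP inputs.

* **Hybrid**: recurrent weights J = B + M where M is a successor-
  representation-like circulant matrix for a deterministic clockwise walk.
  Intermediate recurrence gains then produce predictive (future-shifted)
  place activity while full gain produces barcodes.
* **Feedforward**: barcodes generated by a random expansion layer with a
  sparsity threshold followed by a compressive readout — the alternative to
  recurrent generation.
* **GP inputs**: place inputs replaced by samples of a zero-mean Gaussian
  process on the circle with exponential covariance, testing that the memory
  mechanism does not depend on the specific tuning-curve shape.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import ModelConfig, RandomStreams
from .memory import BarcodeMemory
from .network import PlaceInputBank, RecurrentWeights, init_recurrent_weights

__all__ = [
    "build_predictive_matrix",
    "build_hybrid_weights",
    "hybrid_factory",
    "FeedforwardModel",
    "init_feedforward",
    "feedforward_barcode",
    "build_gp_inputs",
    "gp_factory",
    "make_model",
]


# --------------------------------------------------------------------------
# predictive map (successor representation)
# --------------------------------------------------------------------------

def build_predictive_matrix(config: ModelConfig) -> np.ndarray:
    """Circulant SR-like matrix for a deterministic clockwise walk.

    Neurons are ordered by preferred location; one transition advances one
    neuron index.  The discounted transition series, truncated at horizon
    ``D``, gives entry ``rho * gamma**d + delta`` at backward offset ``d``
    (i.e. M[i, i-d]), and ``delta`` everywhere else: unit i is driven by
    units whose preferred locations it is about to reach, which shifts the
    activity bump clockwise (toward the expected future position).
    """
    N = config.N_x
    # D and gamma are defined per neuron-step at the reference size; for a
    # reduced network, one neuron-step spans more track, so the horizon is
    # shortened and the per-step discount deepened to keep the predictive
    # window's track span and total drive unchanged
    scale = config.N_ref / N
    gamma_eff = config.gamma**scale
    D = min(int(round(config.D / scale)), N - 1)
    row_offsets = np.zeros(N)
    row_offsets[: D + 1] = config.rho * gamma_eff ** np.arange(D + 1)
    M = np.empty((N, N), dtype=config.np_dtype)
    # circulant in neuron-index space: M[i, (i - d) % N] = rho*gamma^d + delta
    idx = (np.arange(N)[:, None] - np.arange(N)[None, :]) % N
    M[:] = row_offsets[idx] + config.delta_off
    return M


def build_hybrid_weights(
    config: ModelConfig, rng: np.random.Generator
) -> RecurrentWeights:
    """Random base weights plus the predictive matrix; Hebbian H starts zero."""
    w = init_recurrent_weights(config, rng)
    w.M_pred = build_predictive_matrix(config)
    return w


def hybrid_factory(config: ModelConfig, seed: int) -> BarcodeMemory:
    streams = RandomStreams(seed)
    weights = build_hybrid_weights(config, streams["weights"])
    return BarcodeMemory(config, seed=seed, weights=weights)


# --------------------------------------------------------------------------
# feedforward barcode generation
# --------------------------------------------------------------------------

@dataclass
class FeedforwardModel:
    """Expansion/compression pathway for feedforward barcode generation."""

    W_h: np.ndarray   # (M_hidden, N_p), N(0, 1/N_p)
    W_o: np.ndarray   # (N_x, M_hidden), N(0, 1/M_hidden)
    theta: float      # hidden-layer active fraction


def init_feedforward(config: ModelConfig, rng: np.random.Generator) -> FeedforwardModel:
    W_h = rng.normal(0.0, 1.0 / np.sqrt(config.N_p), (config.M_hidden, config.N_p))
    W_o = rng.normal(0.0, 1.0 / np.sqrt(config.M_hidden), (config.N_x, config.M_hidden))
    return FeedforwardModel(
        W_h=W_h.astype(config.np_dtype),
        W_o=W_o.astype(config.np_dtype),
        theta=config.theta,
    )


def _threshold_to_sparsity(u: np.ndarray, frac: float) -> np.ndarray:
    """ReLU(u - C) with C chosen per column so a ``frac`` fraction is active."""
    if not (0.0 < frac <= 1.0):
        raise ValueError(f"active fraction must lie in (0, 1], got {frac}")
    q = np.quantile(u, 1.0 - frac, axis=0, keepdims=True)
    if frac >= 1.0:
        q = np.minimum(q, u.min(axis=0, keepdims=True))
    out = np.maximum(u - q, 0.0)
    if np.all(out == 0):
        raise ValueError("requested sparsity produced an all-zero layer")
    return out


def feedforward_barcode(
    bank: PlaceInputBank,
    ff: FeedforwardModel,
    target_sparsity: float,
    states=None,
) -> np.ndarray:
    """Barcodes for each state via expansion -> sparsify -> compress -> sparsify.

    The hidden threshold is chosen per input pattern so that exactly a
    ``theta`` fraction of hidden units is active; the output threshold is
    chosen so the output active fraction matches ``target_sparsity`` (the
    sparsity of the recurrent model's barcodes it is compared against).
    Returns an (n_states, N_x) matrix.
    """
    P = bank.vectors if states is None else bank.vectors[np.atleast_1d(states)]
    U = ff.W_h @ P.T                       # (M_hidden, n_states)
    Xh = _threshold_to_sparsity(U, ff.theta)
    V = ff.W_o @ Xh                        # (N_x, n_states)
    X = _threshold_to_sparsity(V, target_sparsity)
    return X.T


# --------------------------------------------------------------------------
# Gaussian-process place inputs
# --------------------------------------------------------------------------

def build_gp_inputs(
    config: ModelConfig,
    rng: np.random.Generator,
    length_scale: float = 0.4,
) -> PlaceInputBank:
    """Input bank sampled from a zero-mean GP with exponential covariance.

    The covariance between the inputs of two units is exp(-d / length_scale)
    with ``d`` the minimum circular distance between their preferred
    locations.  Because units tile the track evenly, a single stationary GP
    sample on the neuron circle realizes this covariance; the input pattern
    for state k is that sample rotated so the agent's position aligns with
    the sampled field — giving the same covariance across units at every
    state and smooth correlation across states.  Sampling uses the circulant
    spectral decomposition (FFT), which is exact on the circle; numerically
    negative eigenvalues are clipped at zero.
    """
    N = config.N_p
    pref = np.arange(N, dtype=np.float64) / N
    d = np.minimum(pref, 1.0 - pref)
    kernel_row = np.exp(-d / length_scale)
    eig = np.fft.rfft(kernel_row).real
    eig = np.clip(eig, 0.0, None)
    white = rng.standard_normal(N)
    spec = np.fft.rfft(white) * np.sqrt(eig / N)
    sample = np.fft.irfft(spec, n=N) * np.sqrt(N)
    shift_per_state = N // config.N_s
    vectors = np.stack(
        [np.roll(sample, -k * shift_per_state) for k in range(config.N_s)]
    )
    return PlaceInputBank(
        vectors=vectors.astype(config.np_dtype), preferred_locations=pref
    )


def gp_factory(config: ModelConfig, seed: int) -> BarcodeMemory:
    streams = RandomStreams(seed)
    bank = build_gp_inputs(config, streams["gp_inputs"])
    return BarcodeMemory(config, seed=seed, bank=bank)


# --------------------------------------------------------------------------
# variant dispatch
# --------------------------------------------------------------------------

_FACTORIES = {
    "default": lambda cfg, seed: BarcodeMemory(cfg, seed=seed),
    "hybrid": hybrid_factory,
    "gp_inputs": gp_factory,
}


def make_model(config: ModelConfig, seed: int, variant: str = "default") -> BarcodeMemory:
    """Build a model of the named variant ('default', 'hybrid', 'gp_inputs')."""
    try:
        factory = _FACTORIES[variant]
    except KeyError:
        raise ValueError(
            f"unknown variant {variant!r}; valid options: {sorted(_FACTORIES)}"
        ) from None
    return factory(config, seed)
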