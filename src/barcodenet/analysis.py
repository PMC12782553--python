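"""Spike simulation, correlation-vs-distance profiles, calibration, projections.

Population activity is compared across behavioral conditions the way the
corresponding electrophysiology is analyzed: Poisson spike counts are drawn
from the model's rates, population Pearson correlations are computed between
condition pairs, binned by the circular distance between the two probed
sites, pooled over simulated experiments, and normalized by the visit-visit
correlation at zero separation.

The unit of distance is the "site distance": the state separation at which
the normalized visit-visit correlation falls to 0.75 (about eight states at
the default place-input scale), matching the spacing of adjacent cache sites
in the arena the model emulates.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import ModelConfig, RandomStreams
from .memory import BarcodeMemory
from .tasks import ModelFactory, default_factory, state_distance

__all__ = [
    "CorrelationProfile",
    "ProjectionDecomposition",
    "CalibrationError",
    "simulate_spikes",
    "population_correlation",
    "correlation_profile",
    "visit_correlation_curve",
    "calibrate_site_distance",
    "code_projection",
]


class CalibrationError(RuntimeError):
    """The calibration target is never crossed by the measured profile."""


# --------------------------------------------------------------------------
# spikes
# --------------------------------------------------------------------------

def simulate_spikes(
    rates: np.ndarray,
    rng: np.random.Generator,
    scale: float = 0.2,
    offset: Optional[float] = None,
) -> np.ndarray:
    """Independent Poisson spike counts from a rate vector.

    Two parameterizations are supported: counts ~ Poisson(scale * r) for the
    correlation analyses (scale k = 0.2 by default), or — when ``offset`` is
    given — counts ~ Poisson(r + offset), the variant used for visualizing
    spikes (offset K = 0.2 gives silent units a small baseline count).
    """
    rates = np.asarray(rates)
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    lam = rates + offset if offset is not None else scale * rates
    return rng.poisson(lam)


def population_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation across the full population vector."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


# --------------------------------------------------------------------------
# correlation-vs-distance profiles
# --------------------------------------------------------------------------

@dataclass
class CorrelationProfile:
    """Mean pairwise correlation per condition pair and site distance."""

    table: pd.DataFrame        # condition, distance (site units), value, n
    normalization: float       # visit-visit raw correlation at distance 0
    site_distance_states: int  # states per site-distance unit

    def value(self, condition: str, distance: float) -> float:
        t = self.table
        sel = (t["condition"] == condition) & np.isclose(t["distance"], distance)
        return float(t.loc[sel, "value"].iloc[0])

    def sem(self, condition: str, distance: float) -> float:
        t = self.table
        sel = (t["condition"] == condition) & np.isclose(t["distance"], distance)
        return float(t.loc[sel, "sem"].iloc[0])


def visit_correlation_curve(config: ModelConfig, seed: int = 0) -> np.ndarray:
    """Rate-based visit-visit correlation vs separation (states), normalized.

    Visit activity (r=0) is proportional to the place input, so this curve is
    deterministic: entry ``d`` is the Pearson correlation between the final
    activity vectors of two states ``d`` apart, divided by the value at zero
    separation (which is 1 for rates).
    """
    model = BarcodeMemory(config, seed=seed)
    X = model.visit_activity(np.arange(config.N_s))  # (N_x, N_s)
    C = np.corrcoef(X.T)
    max_sep = config.N_s // 2
    curve = np.empty(max_sep + 1)
    for d in range(max_sep + 1):
        vals = [C[k, (k + d) % config.N_s] for k in range(config.N_s)]
        curve[d] = float(np.mean(vals))
    return curve / curve[0]


def calibrate_site_distance(
    profile: np.ndarray, target: float = 0.75
) -> int:
    """State separation at which a normalized profile first reaches ``target``.

    The profile is indexed by separation in states and must decrease through
    the target; linear interpolation between the bracketing separations is
    rounded to the nearest integer state.
    """
    prof = np.asarray(profile, float)
    if prof.min() > target or prof.max() < target:
        raise CalibrationError(
            f"target {target} outside profile range [{prof.min():.3f}, {prof.max():.3f}]"
        )
    below = np.flatnonzero(prof <= target)
    if len(below) == 0:
        raise CalibrationError(f"profile never crosses {target}")
    j = int(below[0])
    if j == 0:
        return 0
    p_hi, p_lo = prof[j - 1], prof[j]
    frac = 0.0 if p_hi == p_lo else (p_hi - target) / (p_hi - p_lo)
    return int(round(j - 1 + frac))


def correlation_profile(
    config: ModelConfig,
    n_experiments: int = 20,
    n_sites: int = 5,
    factory: ModelFactory = default_factory,
    master_seed: int = 0,
    recall_s: float = 0.0,
    k_scale: Optional[float] = None,
    site_distance_states: int = 8,
    use_spikes: bool = True,
    min_site_separation: Optional[int] = None,
) -> CorrelationProfile:
    """Visit-visit and cache-retrieval spike correlations vs site distance.

    Each simulated experiment draws ``n_sites`` random cache sites, stores a
    cache at each, then simulates retrieval (recall mode) at each site along
    with two independent visits.  Poisson spike counts (k = ``k_scale``) are
    drawn from every activity vector and all pairwise population correlations
    are binned by the circular distance between the two sites, in units of
    ``site_distance_states``.  Values are pooled over experiments and
    normalized by the visit-visit value at distance zero.
    """
    if n_sites < 2:
        raise ValueError("need at least two sites to form pairs")
    k = config.k_spike if k_scale is None else k_scale
    streams = RandomStreams(master_seed)
    spike_rng = streams["spikes"]
    sep = (
        min_site_separation
        if min_site_separation is not None
        else site_distance_states
    )

    pair_vals: Dict[Tuple[str, float], List[float]] = {}
    task_rng = streams["task"]
    for exp in range(n_experiments):
        seed = streams.child_seed(exp)
        model = factory(config, seed)
        # sample distinct sites with a minimum separation, as cache sites
        # in the arena are never closer than one site distance
        sites: List[int] = []
        tries = 0
        while len(sites) < n_sites and tries < 2000:
            cand = int(task_rng.integers(config.N_s))
            if all(state_distance(cand, s, config.N_s) >= sep for s in sites):
                sites.append(cand)
            tries += 1
        if len(sites) < n_sites:
            raise RuntimeError("could not place cache sites with the requested separation")

        cache_pats = {}
        for s_i in sites:
            cache_pats[s_i] = model.store_cache(s_i).x_stored
        retr_pats = {}
        x_all, _, _ = model.recall_event(np.array(sites), s_strength=recall_s)
        for j, s_i in enumerate(sites):
            retr_pats[s_i] = x_all[:, j]
        visit_rates = model.visit_activity(np.array(sites))
        visits1 = {s_i: visit_rates[:, j] for j, s_i in enumerate(sites)}

        def spk(r):
            if not use_spikes:
                return r
            return simulate_spikes(r, spike_rng, scale=k)

        v_spk_a = {s_i: spk(visits1[s_i]) for s_i in sites}
        v_spk_b = {s_i: spk(visits1[s_i]) for s_i in sites}
        c_spk = {s_i: spk(cache_pats[s_i]) for s_i in sites}
        r_spk = {s_i: spk(retr_pats[s_i]) for s_i in sites}

        for i, si in enumerate(sites):
            for j, sj in enumerate(sites):
                d_states = state_distance(si, sj, config.N_s)
                # bin to the nearest integer site distance (0 only for the
                # exact same site, guaranteed by the minimum separation)
                d = float(round(d_states / site_distance_states))
                if i < j or i == j:
                    val = population_correlation(v_spk_a[si], v_spk_b[sj])
                    pair_vals.setdefault(("visit-visit", d), []).append(val)
                val = population_correlation(c_spk[si], r_spk[sj])
                pair_vals.setdefault(("cache-retrieval", d), []).append(val)
        del model

    norm = float(np.nanmean(pair_vals[("visit-visit", 0.0)]))
    rows = []
    for (cond, d), vals in sorted(pair_vals.items()):
        arr = np.asarray(vals, float)
        arr = arr[np.isfinite(arr)]
        rows.append(
            (cond, d, float(np.mean(arr) / norm),
             float(np.std(arr) / np.sqrt(max(len(arr), 1)) / abs(norm)),
             len(arr))
        )
    table = pd.DataFrame(rows, columns=["condition", "distance", "value", "sem", "n"])
    return CorrelationProfile(
        table=table, normalization=norm, site_distance_states=site_distance_states
    )


# --------------------------------------------------------------------------
# recurrence-gain projection decomposition
# --------------------------------------------------------------------------

@dataclass
class ProjectionDecomposition:
    """Mean projection magnitudes of activity onto three reference codes.

    Each curve (place, predictive, barcode) is max-normalized over the swept
    recurrence gains.  References per location: the place code is the r=0
    activity; the predictive code is the place pattern of the next-clockwise
    site orthogonalized against the place code; the barcode is the r=1
    activity orthogonalized against the place code.
    """

    r_values: np.ndarray
    place: np.ndarray
    predictive: np.ndarray
    barcode: np.ndarray

    @property
    def predictive_peak_r(self) -> float:
        return float(self.r_values[int(np.argmax(self.predictive))])

    @property
    def barcode_peak_r(self) -> float:
        return float(self.r_values[int(np.argmax(self.barcode))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r": self.r_values,
                "place": self.place,
                "predictive": self.predictive,
                "barcode": self.barcode,
            }
        )


def _orthogonalize(vec: np.ndarray, against: np.ndarray) -> np.ndarray:
    against = against / (np.linalg.norm(against) + 1e-12)
    return vec - (vec @ against) * against


def code_projection(
    model: BarcodeMemory,
    r_sweep: Sequence[float],
    predictive_offset_states: int = 1,
    locations: Optional[Sequence[int]] = None,
) -> ProjectionDecomposition:
    """Project gain-swept activity onto place, predictive and barcode codes.

    For every location the three unit-normalized reference vectors are built
    from r=0 and r=1 activity (no seed input, no stored caches expected);
    activity at each swept gain is projected onto each reference and the
    absolute projections are averaged over locations.  Each resulting curve
    is normalized by its own maximum.

    ``predictive_offset_states`` sets how far clockwise the "next site" lies
    (in track states) for the predictive reference.
    """
    r_sweep = np.asarray(list(r_sweep), float)
    if np.any((r_sweep < 0) | (r_sweep > 1)):
        raise ValueError("recurrence gains must lie in [0, 1]")
    cfg = model.config
    locs = np.arange(cfg.N_s) if locations is None else np.asarray(locations)
    nxt = (locs + predictive_offset_states) % cfg.N_s

    X0 = model.gain_activity(locs, 0.0)          # (N_x, L) place code
    X0_next = model.gain_activity(nxt, 0.0)      # next-clockwise place patterns
    X1 = model.gain_activity(locs, 1.0)          # barcode regime

    L = len(locs)
    refs = {"place": np.empty((cfg.N_x, L)), "predictive": np.empty((cfg.N_x, L)),
            "barcode": np.empty((cfg.N_x, L))}
    for j in range(L):
        place = X0[:, j]
        pred = _orthogonalize(X0_next[:, j], place)
        barc = _orthogonalize(X1[:, j], place)
        for name, v in (("place", place), ("predictive", pred), ("barcode", barc)):
            n = np.linalg.norm(v)
            refs[name][:, j] = v / n if n > 0 else 0.0

    curves = {name: np.zeros(len(r_sweep)) for name in refs}
    for i, r in enumerate(r_sweep):
        Xr = X0 if r == 0.0 else (X1 if r == 1.0 else model.gain_activity(locs, r))
        for name in refs:
            proj = np.abs(np.sum(refs[name] * Xr, axis=0))  # per-location |dot|
            curves[name][i] = float(np.mean(proj))
    for name in curves:
        m = curves[name].max()
        if m > 0:
            curves[name] = curves[name] / m
    return ProjectionDecomposition(
        r_values=r_sweep,
        place=curves["place"],
        predictive=curves["predictive"],
        barcode=curves["barcode"],
    )
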