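# Methods

This note documents the model as implemented: its equations, the parameter
choices that matter, where the implementation had to resolve ambiguities or
re-calibrate, and what the simulations do and do not establish.

## Model

**Architecture.**  `N_p` place-input units connect one-to-one onto `N_x`
recurrent ReLU rate units (`N_p = N_x`); a scalar seed unit projects through
fixed weights `j_in ~ N(0, 1)`.  The track is a circle of `N_s = 100`
discrete states; input unit `l` has drive `exp(-d(k, l) / nu)` at state `k`,
with `d` the minimum circular distance as a fraction of circumference and
preferred locations tiling the track evenly.  With `nu = 0.2` the
visit-activity correlation between states 8 apart is 0.809, and 0.75 — the
correlation measured between adjacent cache sites in the arena this model
emulates — is first reached near 9 states; one "site distance" is therefore
taken as 8 states throughout.

**Dynamics.**  Voltages follow
`dv/dt = -(alpha/N_x) sum(x) v + r J x + p + s j_in`, integrated with
explicit Euler steps `dt = 0.1` for `T = 100` steps from the zero state (a
config switch interprets `T` in time units instead, i.e. 1000 steps; at the
default parameters the dynamics reach their fixed point well inside either
horizon).  Any non-finite voltage raises an error rather than being
clipped.  Three schedules implement the behavioral modes: visits (`r = 0`),
caching (`r = 1`, seed at strength `lam` for the final `t_s = 5` steps), and
recall (`r = 1`, seed at the chosen search strength throughout).

**Weight initialization.**  Base weights are i.i.d. Gaussian with mean
`mu / N_x` (`mu = -40`) and standard deviation `sigma^2 / N_x` at the
reference size `N_x = 5000` (`sigma = 7`).  Two conventions are possible
for the printed form of this distribution; the implementation uses the one
under which the model functions.  Under the alternative (sd
`sigma / sqrt(N_x)`), the `sigma = 7` network is deeply chaotic: activity
retains no smooth place component at any separation, and — because chaotic
trajectories cannot be revisited — a stored pattern can never be re-cued at
recall.  Under the adopted convention the recurrent dynamics converge to a
location-specific fixed point: the quenched weight fluctuations are
amplified by the winner-take-all competition into a sparse pattern that is
reproducible (the same network at the same state always produces it) yet
essentially uncorrelated between states more than a few apart.  That
combination — reproducible but decorrelated — is precisely what a memory
index requires here.

**Size anchoring.**  Per-unit recurrent fluctuation scales as
`sigma^2 rate / sqrt(N_x)` under this convention, so naively re-applying
the formulas at a reduced `N_x` lands the network in a more scrambled
regime.  The implementation therefore anchors the weight sd to a reference
size: `sd = sigma^2 / sqrt(N_x * N_ref)` with `N_ref = 5000`.  At full size
this equals the convention above; at reduced sizes it holds the dynamical
regime fixed, so the simulations in the tests (1000–2000 units) behave like
the full-size model.  The predictive matrix is anchored the same way (see
below).  All reported simulations state their `N_x`.

**Plasticity and readouts.**  A cache event applies
`dJ = (eta/N_x)(x x^T + beta x 1^T)` once, with the activity at the final
integration step (`eta = 40`, `beta = -0.35`; the bias multiplies the
postsynaptic factor, so rows of `dJ` vanish wherever `x_i = 0`).  The same
event increments the seed readout by `(eta/N_x) x` and the place readout by
`(eta/N_x) p x^T`.  Carrying the learning-rate factor on the readouts makes
the seed output O(1) and independent of network size, which is what makes a
fixed decision threshold (`kappa = 0.5`) meaningful across scales; with raw
increments the output would grow linearly with `N_x`.  The episode trace is
recorded before the update is applied.

**Recall as gated pattern completion.**  The Hebbian drive along a stored
pattern is `(eta/N_x) x_c (x_c . x + beta sum(x))`: completion takes hold
only where the cue overlap exceeds `|beta|` of total activity.  Whether any
cue can pass this gate is controlled by the activity "concentration"
`|x|^2 / sum(x)`, which scales as `1/sqrt(alpha)`.  At the printed
normalization strength (`alpha = 20`) the concentration equilibrates at
~0.36 — numerically at the gate — so no partial cue can ever ignite a
stored pattern and recall is impossible.  The default is therefore
`alpha = 6`, where same-site place cues ignite with margin, midpoint and
remote cues stay suppressed, and the ablated models behave as intended (see
below).  Analyses that involve no plasticity (the weight-scale regime
profiles and the recurrence-gain projection decomposition) are run at
`alpha = 20`, where they are exact to the original dynamics; the projection
peaks reported below are from that setting.

**Seed strength at storage.**  The caching seed blast perturbs the stored
pattern away from the network's own fixed point; too strong a blast leaves
nothing a place cue can re-ignite, while too weak a blast leaves no tag for
seed-driven (broad) search.  The default `lam = 1.0` balances the two:
same-site recall at `s = 0` reinstates the stored pattern (cosine ~0.9) and
the search radius grows with `s` over the probed range {0, 0.4, 1.5}.

## Tasks and metrics

The three-cache protocol stores caches at 20%, 35% and 70% of the track
(order configurable; metrics are statistically unchanged under reordering)
and probes recall at every state for each search strength.  Cache Presence
is decided by `y_s > kappa` (strictly); Cache Location succeeds iff the
presence decision is positive **and** the place-output argmax, mapped to a
state through the winning unit's preferred location, lies within 4 states
(half a site distance; the tolerance is not externally constrained and is
configurable) of the cache nearest the probe.  Aggregation across the 35
replicate networks uses normal-approximation binomial confidence intervals
at 99%.  The midpoint sweep stores caches `2h` states apart plus a distant
third cache and probes the floor-state midpoint.

Ablations: "place only" sets `mu = sigma = 0` (no barcode generation);
"barcode only" sets `nu = 1e-3` (spatially uncorrelated inputs).  In the
implemented regime the place-only model stores heavily overlapping smooth
patterns that merge into an agglomerated attractor: recall ignites over wide
stretches of the track, so the empty midpoint between two nearby caches is
rejected at roughly chance while the full model rejects it reliably.  The
barcode-only model detects presence as well as the full model but can
localize only at the cached state itself.

## Spike-correlation analysis

Population activity is compared across conditions via Poisson spike counts
(`counts ~ Poisson(k r)`, `k = 0.2`; a visualization variant uses
`Poisson(r + K)`, `K = 0.2`).  Each simulated experiment caches at five
random sites (minimum separation one site distance), simulates retrievals
and two independent visits per site, and computes population Pearson
correlations between all condition pairs, binned by integer site distance,
pooled over 20 experiments, and normalized by the same-site visit-visit
value.  Same-site cache-retrieval correlation exceeds the visit-visit value
several-fold — the stored index is reactivated at retrieval.  A caveat: in
the implemented regime, full-recurrence patterns carry almost no smooth
place component, so cache-retrieval correlations at one or two site
distances sit near zero rather than decaying along the visit-visit curve;
sharpening memory precision and retaining smooth cross-site correlation
pull against each other here (a milder winner-take-all regime restores the
smooth tails but abolishes single-site midpoint rejection — verified by
sweeping `mu`).

## Predictive-map hybrid

The hybrid adds `M = rho * sum_{d=0..D} gamma^d (T^T)^d + delta` to the base
weights, with `T` the deterministic clockwise one-step transition in
neuron-index space; for a ring this is circulant with entry
`rho gamma^d + delta` at backward offset `d` and `delta` elsewhere
(`rho = 0.075`, `gamma = 0.99`, `delta = -0.015`, `D = 300` neuron-steps at
the reference size).  The transpose orientation is the one under which
intermediate-gain activity shifts toward future positions (cross-correlation
lag ~ +6 states at `r = 0.3`).  At reduced size the horizon shortens and the
per-step discount deepens (`D N_x / N_ref`, `gamma^{N_ref / N_x}`), keeping
the window's track span and its total drive in proportion to the `delta`
offset.

The projection decomposition runs the unlearned hybrid at gains
`r = 0, 0.1, ..., 1`; per location the references are the `r = 0` activity
(place), the next-clockwise location's `r = 0` activity orthogonalized
against place (predictive; the offset is one state by default,
configurable), and the `r = 1` activity orthogonalized against place
(barcode).  Mean absolute projections over locations, max-normalized per
curve, give: place maximal at `r = 0`, predictive peaking at `r = 0.4`,
barcode peaking at `r = 1.0` (2000 units, `alpha = 20`).

Known limitation: with a single stored cache, the hybrid's recall field is
displaced 2–4 states beyond the cache along the movement direction (the
stored pattern's units sit ahead of the cache, so the place input that best
feeds them arrives after passing it), rather than extending onto the
approach path.  The implementation keeps the forward-predictive orientation
(it is the one consistent with the shift analysis and the printed series)
and reports the recall-field asymmetry as it comes out.

## Synthetic-data scope

All inputs are generated internally; there is no external data.  What the
generator emulates: discretized 1-D circular place coding with smooth
exponential (or GP-sampled) tuning, event-based caching/retrieval/visit
protocols, and Poisson spiking variability.  What it does not: 2-D
environments, behaviorally driven trajectories, multiple caches per site,
forgetting, E/I-separated circuitry, or temporal dynamics of real spike
trains.  Passing tests therefore establish the internal consistency of the
mechanism and its calibrations, not a fit to recorded data.

## Numerical choices

Float32 by default (float64 via config for exactness-sensitive checks);
one master seed fans out to named independent streams (weights, seed
pathway, noise, spikes, GP inputs, feedforward, task) so toggling one
randomness source never shifts another; optional Gaussian perturbations
(per-step dynamics noise with Euler–Maruyama scaling, and a static offset
added to the input and initial state) default to zero; division-free
degenerate cases (zero-variance vectors in correlations, empty distance
bins) return NaN or are dropped rather than fabricated.  Reported problem
sizes: unit and behavior tests at 200–1000 units, task and projection
evaluations at 1000–2000 units, exact oracles at the printed 5000.
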