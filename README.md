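# barcodenet

A recurrent-network model of episodic memory in the hippocampus of
food-caching birds.  Chickadees remember hundreds of individual seed caches;
their hippocampus emits sparse, high-dimensional activity patterns
("barcodes") that are unique to each caching event, reappear when that cache
is retrieved, and coexist — in the same neurons — with ordinary place
tuning.  `barcodenet` implements a mechanistic account of how such patterns
can be generated, bound to memory content, and recalled, together with the
task protocols and analyses used to evaluate it.

The package is for computational neuroscientists who want to simulate,
probe, or extend the model: every component (dynamics, plasticity, readouts,
task metrics, ablations, the predictive-map hybrid) is an ordinary Python
function or class, and a CLI orchestrates the standard experiments.

## The model

A ReLU rate network of `N_x` units sits on a 1-D circular track of `N_s =
100` discrete states.  Each unit receives a place input
`p_l = exp(-d / nu)` (with `d` the circular distance to the unit's preferred
location, `nu = 0.2`), and the voltages evolve by explicit Euler steps of

    dv/dt = -(alpha / N_x) * sum(x) * v  +  r * J x  +  p  +  s * j_in
    x = relu(v)

The first term is shunting (divisive) inhibition proportional to total
population activity; `r` gates the recurrent weights `J` (`r = 0` during
ordinary visits, `r = 1` during caching and recall); `s` is a scalar "seed"
input through fixed random weights `j_in ~ N(0, 1)`.  `J` is initialized
randomly with negative mean (`mu / N_x`, `mu = -40`): with recurrence on,
subtractive inhibition plus quenched random fluctuations drive a
winner-take-all competition whose sparse outcome is decorrelated between
sites only a few states apart — the barcode.

Storing a cache applies one biased Hebbian update with the final caching
activity `x`,

    dJ = (eta / N_x) * (x x^T + beta * x 1^T),    eta = 40, beta = -0.35

making the pattern an attractor, and increments two plastic readouts: a seed
output `y_s = w^T x` (is a stored memory reactivated here?) and a place
output `y_p = J_yx x` (where is it?).  The negative bias `beta` acts as an
ignition gate at recall: cues must overlap a stored pattern strongly enough,
relative to total activity, for pattern completion to take hold, which is
what lets the network report "no cache" between two caches one site distance
(8 states) apart.  The recall search radius is widened continuously by the
seed input strength `s` — pattern separation and pattern completion under a
single dial.

A hybrid variant adds a successor-representation-like circulant matrix `M`
(`rho = 0.075`, `gamma = 0.99`, offset `delta = -0.015`, horizon `D = 300`)
to the random weights; sweeping the recurrence gain then moves the network
from a place code (r = 0) through predictive, future-shifted activity
(peak near r = 0.4) to barcodes (r = 1).  A feedforward
expansion/sparsification pathway and a Gaussian-process place-input variant
are included as alternatives.

## Worked example

```python
import numpy as np
from barcodenet import BarcodeMemory, ModelConfig

cfg = ModelConfig(N_p=1000, N_x=1000, N_y=1000)   # reduced network
model = BarcodeMemory(cfg, seed=2)
for c in (20, 35, 70):                            # cache at 20%, 35%, 70%
    model.store_cache(c)

for s in (0.0, 1.5):                              # narrow and broad search
    _, y_seed, y_place = model.recall_event(
        np.array([20, 27, 35, 52, 62, 70]), s_strength=s)
    print(f"s={s}: seed output {np.round(y_seed, 2)}")
    print(f"       place peaks {np.round(model.place_peak_states(y_place)).astype(int)}")
```

prints

```
s=0.0: seed output [0.98 0.02 1.78 0.   0.   1.59]
       place peaks [20 20 35  0 70 70]
s=1.5: seed output [0.85 0.83 3.06 0.54 0.52 0.55]
       place peaks [20 20 35 35 35 70]
```

At `s = 0` the seed output exceeds the decision threshold `kappa = 0.5` only
at the three cached states (probes 20, 35, 70), and the place output peaks
at the recalled cache; the empty midpoint (27) and remote states (52, 62)
are correctly silent.  At `s = 1.5` the search radius broadens: previously
silent states now retrieve a nearby cache memory, at the cost of
presence/absence precision — the trade-off the model is built to expose.

## CLI

```
barcodenet --seed 1 --outdir results simulate --experiment calibration
barcodenet task                 # three-cache task metrics (CSV + JSON)
barcodenet profile              # visit/cache-retrieval spike correlations
barcodenet projection           # recurrence-gain projection decomposition
barcodenet compare              # full vs place-only vs barcode-only
barcodenet figures              # re-render figures from result tables
```

Configuration is a flat `key = value` text file (`--config`); unknown keys
are rejected.  Results are tidy CSV tables plus JSON summaries; activity
snapshots are compressed arrays with JSON sidecars.

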