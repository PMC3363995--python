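# neurodi

Directed-information effective connectivity for trial-based neural time
series.

## The problem

Functional-connectivity measures (correlation, coherence) are symmetric:
they say two brain signals covary, not which one drives the other.
*Effective* connectivity asks for the direction and strength of influence.
Model-based answers — Granger causality (GC) fitted with multivariate
autoregressions, dynamic causal modelling — assume a signal model, usually
linear, and can both miss nonlinear coupling and hallucinate causality when
a single source reaches several sensors (volume conduction).

`neurodi` implements a model-free alternative built on **directed
information (DI)**,

```
DI(X^N -> Y^N) = Σ_{n=1..N} I(X^n ; Y_n | Y^{n-1}),
```

the part of the dependence between processes X and Y that X's past and
present contribute to Y's next sample.  DI is asymmetric, detects both
linear and nonlinear coupling, and for jointly Gaussian processes its rate
equals Geweke's Granger-causality index — which this package exploits as a
cross-check between its nonparametric and linear machinery.

Estimating DI directly requires joint densities whose dimension grows with
the record length.  The workhorse here is the **modified time-lagged DI
(MDI)**, a stationary-Markov windowed form,

```
MDI(X^N -> Y^N) = Σ_{n=p+1..N} I(X_{n-p..n-1} ; Y_n | Y_{n-p..n-1}),
```

whose terms stay (2p+1)-dimensional.  The model order `p` is selected
model-free with Cao's embedding-dimension criterion; mutual informations
are estimated by Darbellay–Vajda adaptive partitioning of the joint rank
space across trials; significance comes from trial-shuffle permutation
nulls; and normalization by the total dependence (both directed flows plus
the instantaneous exchange) keeps common sources and instantaneous sensor
mixing from masquerading as causality.  Benjamini–Hochberg FDR control
handles the many pairs of a full channel-by-channel analysis.

The intended users are electrophysiologists and methods researchers who
have trial-aligned recordings (EEG/MEG/LFP epochs) and want directed
interaction maps that do not presuppose a linear signal model.

## Worked example

Simulate the coupled linear benchmark (X drives Y through lags 1–5 with
coupling 0.8), pick the order, and test both directions:

```python
import numpy as np
from neurodi import simulators as sim
from neurodi.directed_info import DIConfig
from neurodi.inference import mdi_rho_test
from neurodi.order_selection import select_order

rng = np.random.default_rng(42)
spec = sim.LinearARSpec.random(rng, gamma=0.8)
x, y = sim.simulate_linear_ar(spec, n_trials=1024, n_time=60, seed=42)

p = select_order(x, y)                      # -> 5, the generative order
cfg = DIConfig(p=p)
fwd, rev = mdi_rho_test(x.window(0, 12), y.window(0, 12), cfg,
                        n_shuffles=100, seed=0)
```

Output:

```
selected order p = 5
rho_xy = 0.845  threshold = 0.463  p = 0.0099  significant = True
rho_yx = 0.128  threshold = 0.358  p = 0.3267  significant = False
```

`rho_xy` is the share of the total X–Y dependence carried by the lagged
X→Y flow.  It exceeds the 95th percentile of its own 100-trial-shuffle
null (p ≈ 0.01), while the reverse direction does not: the test recovers
the unidirectional ground truth.

A thin CLI wraps the same machinery:

```
neurodi simulate --model linear_ar --seed 1 --out sim/
neurodi connectivity --in sim/ensemble.csv --window-len 53 --q 0.05 --seed 1 --out result/
```

## Benchmarks

`scripts/acceptance.py` regenerates the five ground-truth benchmark
systems (multi-order linear and sigmoid-coupled AR pairs, instantaneous
linear mixing, a common AR source on two noisy sensors, and delayed-drive
coupled Lorenz oscillators), reruns order selection, the DI significance
tests, and the GC comparator on them, and writes the summary quantities
(recovered orders, false-positive rate, detection boundaries over the
mixing and coupling grids) to JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All inputs are simulated from the given seed at the scale documented in
`neurodi/benchmarks.py`; nothing is read from outside the repository.
`docs/methods.md` describes the estimators, the frozen benchmark
configuration, and known limitations.
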