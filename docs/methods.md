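# Methods

## Signals and sampling model

All estimators consume `TrialEnsemble`s: an `n_trials x n_time` matrix per
channel, trials treated as i.i.d. realizations of one underlying
stochastic process.  Joint densities at fixed time indices are estimated
across trials; an optional *stationary mode* additionally pools sliding
window positions across time (see below).  Everything is reported in bits.

## Information estimators

Three families sit behind one `EstimatorConfig`:

* **gaussian** — covariance plug-in: `H = (d/2) log2(2πe) + (1/2) log2 det Σ`,
  MI and conditional MI from log-determinant ratios.  Deterministic given
  the sample covariance; captures only second-order dependence.  Exact
  closed forms on *model* covariances (`gaussian_di_from_cov` and friends)
  serve as oracles in the test suite.
* **adaptive_partition** — Darbellay–Vajda recursive partitioning,
  generalized to vector arguments.  Data are rank-transformed per
  coordinate (copula scale, so the estimator is invariant to monotone
  marginal transforms); each cell is split 4-ways at conditional medians
  of the best cut-coordinate pair (largest 2x2 independence chi-square,
  with a 4x4 quartile test as a second chance), and refinement stops when
  independence is no longer rejected or children would fall below
  `ap_min_cell = 5` points.  Terminal cells contribute
  `(n_C/N) log2(n_C N / (n_C^X n_C^Y))`.
  The refinement level `ap_significance` defaults to **0.3**: lower levels
  stop refinement so early that the estimator's truncation bias breaks the
  known bivariate-Gaussian value (−½ log2(1−r²) = 0.2075 bits at r = 0.5:
  level 0.05 reads 0.168 on average at n = 8192, level 0.3 reads 0.199
  with independence bias +0.004).  This calibration uses only the Gaussian
  closed form.
* **histogram** — fixed equiprobable per-coordinate binning with plug-in
  MI; a cross-check for low-dimensional problems only.

Conditional MI uses the two-term decomposition
`I(X;Y|Z) = I(X;(Y,Z)) − I(X;Z)` with the lower-dimensional argument kept
standalone (partitioning a scalar against a joint block resolves far
better than vector against vector).  Nonparametric estimates may be
negative; they are returned raw and clipped only inside normalization.

## Directed information and MDI

`directed_information` evaluates the growing-window form
`Σ_n [I(X^n;Y^n) − I(X^n;Y^{n−1})]`.  `mdi` evaluates the windowed
stationary-Markov bound with order `p` and unit interaction lag.  Two
estimation modes:

* **per-index** (default): each term estimated across trials at its own
  time index — the faithful mode when stationarity is in doubt;
* **pooled stationary mode** (`pool_time=True`, default in the
  significance tests): all `N − p` window positions pooled into one
  sample of `n_trials · (N − p)` rows, one conditional MI scaled by
  `N − p`.  The trial-shuffle null remains exact under pooling because a
  permutation of X's trials preserves each process's internal overlap
  structure while breaking the X–Y pairing.

In the pooled adaptive mode the conditional MI is estimated by
**stratified conditioning**: pooled rows are partitioned into
equal-occupancy strata by recursive median cuts on the Y-window
coordinates (most recent lag first, 4–32 strata targeting ~900 rows
each), and `I(X-window; Y_n | Y-window)` is the occupancy-weighted sum of
within-stratum adaptive MI on within-stratum ranks.  Rationale: when the
target is strongly autocorrelated — common in the benchmark systems,
whose coefficients are drawn up to the stability boundary — a difference
of two joint-MI estimates spends the partition's entire resolution on the
Y self-memory and carries no sensitivity to the X increment (a case with
9 bits of true excess over its shuffle null read 0.04 bits by
differencing and correctly by stratification).  Strata depend on Y alone,
so shuffled statistics reuse them.

Known departures from the source formulas, both verified against Gaussian
closed forms:

* the two-sample time-lagged DI with its printed prefactor
  `(N−p1)/(2(N−p1−1))` equals full DI only when both marginals are
  memoryless (iid source, target without own-lag terms); with own-memory
  the closed-form gap is several tenths of a bit in either direction.
  The formula is implemented verbatim and its exactness is asserted only
  in the exactly-valid case.
* "MDI ≥ DI" compares sums over different index ranges (MDI starts at
  `p+1`); the valid exact statement, and the one the tests assert, is
  `MDI ≥ DI(N) − DI(p)`.

## Order selection

Cao's criterion on pooled delay vectors (Chebyshev metric, self-matches
excluded, deterministic strided subsampling capped at 4000 vectors).  At
finite sample sizes E1 creeps toward 1 at every dimension — white noise
shows the same creep — so the plateau is detected structurally: E1
increases of at least `e1_tol = 0.10` count as unfolding steps and the
selected dimension is one past the last step.  This rule reproduces the
generative order of the AR(5) benchmark (modally over regenerations), 3
for the driven Lorenz component, and 2 for a sampled sinusoid.  The E2
curve flags noise-like inputs (`|E2 − 1| ≤ 0.1` everywhere) whose
E1-based order is unreliable; the flag never alters the returned value.
The pairwise order is `max` of the two channels' dimensions.

## Significance testing

* **Trial shuffle**: permute the source channel's trial axis, recompute
  the statistic, threshold at the empirical 95th percentile; p-values use
  the add-one rule `(1 + #{null ≥ obs})/(1 + n_shuffles)`.
* **Time shuffle** (single realizations, the GC comparator): permute time
  samples.  Note this null destroys autocorrelation and is therefore
  anti-conservative for regression statistics on strongly autocorrelated
  data; it is retained as the stated benchmark procedure.
* **Normalized MDI share** (`mdi_rho_test`): the detection statistic for
  the benchmark studies.  Each directional MDI is measured as its excess
  over the trial-shuffle median (cancelling the estimator's dimensional
  bias), the instantaneous exchange is the extra excess contributed by
  the source's current sample, and
  `rho = excess_fwd / (excess_fwd + excess_rev + instantaneous + floor)`
  with the floor set to the null's (1−α) excess quantile, so a direction
  is only credited with a share of dependence beyond what shuffling
  produces.  A common source or instantaneous mixing inflates the
  denominator and drives both observed shares toward zero — the
  specificity mechanism that keeps volume conduction from reading as
  causality.  This is the one statistic that simultaneously yields
  significance at every coupling strength on the linear benchmark and a
  zero false-positive rate on the common-source benchmark.
* **FDR**: Benjamini–Hochberg step-up on pooled p-value lists, separately
  per measure in the connectivity pipeline.

## Simulators: what they emulate and what they do not

Five seeded generators with known ground truth: multi-order linear AR
pairs (unidirectional coupling over lags 1..5, all coefficients N(0,1)
with unstable draws rejected), the same pairs coupled through a steep
sigmoid (`b1 = 0, b2 = 50` — essentially a threshold on the driver's
sign, invisible in no linear model but weakly linearly correlated),
instantaneous linear sensor mixing, a common AR(5) source observed with
independent noise (volume-conduction surrogate, SNR +19 to −19 dB over
the noise-weight grid), and two Lorenz oscillators with a 2-sample
delayed drive integrated by forward Euler at dt = 0.01 (100 steps, 90
discarded; diverging trials regenerated).  AR generators discard a
100-sample burn-in; draws near the stability boundary remain slowly
mixing, so short records are only approximately stationary — tests that
need the exact stationary covariance use a long burn-in.

What green tests on these systems do *not* establish: performance on
nonstationary data, on non-Gaussian innovations, on networks of more than
two coupled processes (conditional DI is out of scope), or at trial
counts far below ~500.

## Frozen benchmark configuration

All benchmark studies (`neurodi.benchmarks`, used by the acceptance
script) run with p = 5, an analysis window of 12 samples (7 pooled
positions, making the pooled sample count comparable to the 4096
realizations of the original studies), 1024 trials, 100 shuffles,
α = 0.05.  The horizon and the estimator defaults were fixed against the
linear benchmark's stated baseline behaviour (significance at every
coupling strength) and the closed-form Gaussian values — never against
the boundary quantities the studies report — and are not varied per
study.

## Known limitations

* The adaptive estimator's rank transform makes it invariant to the
  amplitude attenuation that instantaneous mixing applies; consequently
  the raw MDI test keeps detecting mixed coupling essentially up to
  identical sensors, and the normalized-share test loses detection
  earlier than an amplitude-resolution-limited estimator would.  Mixing
  boundaries are therefore estimator-profile-dependent quantities.
* The time-shuffle GC null is anti-conservative on autocorrelated data
  (see above); GC detection boundaries inherit this.
* A common source with memory creates *real* directed statistical
  information flow from a clean sensor to a noisy one (the clean sensor's
  past predicts the noisy sensor's next sample beyond its own corrupted
  past).  At low SNR the instantaneous share no longer dominates, and the
  normalized test correctly begins to detect this flow; "common source
  implies no detection" holds only while the instantaneous exchange
  dominates the dependence.
* The Geweke/DI-rate equivalence is asymptotic; at short horizons the
  startup transient biases the plain `DI/N` rate, so comparisons use the
  increment rate between two horizons.
* `p1` is fixed at 1 in MDI (no information flow is lost; only the window
  dimension grows); the explicit-lag path exists only in the two-sample
  time-lagged form.
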