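# Methods

This note documents the models implemented in `tactilenp`, the
assumptions behind them, the synthetic data that stands in for recorded
neurons, and the numerical choices a user should know about before
trusting — or extending — the results.

## The encoding model

A cortical (S1) neuron is described by a linear-nonlinear-Poisson (LNP)
cascade over two input channels, the rapidly adapting (RA) and Pacinian
(PC) afferent population firing rates:

    p(s_t) = r( k_RA · s_RA,t + k_PC · s_PC,t )

`s_RA,t` and `s_PC,t` are the z-scored population rates in the 100 ms
preceding bin `t` (1-ms bins), `k_RA`, `k_PC` are 100-tap temporal
filters, and `r` is a piecewise-linear rectifier: `r(x) = b1` for
`x < 0`, otherwise `b1 + b2·x` clipped at 1.  Spikes are independent
Bernoulli draws per 1-ms bin.  The lag convention is fixed repo-wide:
filter index `j` multiplies the input `j+1` ms before the response bin.

Filters are estimated by reverse correlation with a ridge correction
for input autocorrelation,

    k = (SᵀS + aI)⁻¹ Sᵀ s_C ,

where `S` is the lagged design matrix (200 columns: 100 RA lags then
100 PC lags), `s_C` the binary spike vector, trials concatenated with
the first 100 ms of each excluded (incomplete history).  Z-scoring
parameters are computed once on the fitting set and frozen.  `a` is
chosen by 5-fold cross-validated prediction on held-out stimuli from a
log-spaced grid; results are robust over a wide range of `a`, so the
validation experiment cross-validates a small subset of neurons and
shares the median `a`.

The nonlinearity `(b1, b2)` is fit after the filters: the drive is
split into 50 quantile bins and `(b1, b2)` are found by constrained
least squares of `b1 + b2·E[[x]⁺]` against the per-bin empirical spike
probability (per-bin expectation of the rectified drive, not the
rectified bin mean — the distinction matters only for the bin
straddling zero, where the naive version is biased).

### Estimation bias of the linear step, and the input-class decision

Whether a neuron receives RA input, PC input, or both is decided per
class by testing the estimated filters against the hypothesis that the
*other* class alone drives the neuron.  Two properties of the problem
dictate the design; both were diagnosed with noise-free controls.

**Cross-class spill-over.**  Linear estimation of a rectified model is
systematically biased: the regression finds the best *linear*
approximation of `r(k·s)`, and its residual is correlated with
anything that co-varies with the drive — in particular with the
*other* afferent class, because both population rates share the
stimulus envelope.  A neuron driven by one class alone therefore shows
a small but systematic weight in the class it does not receive (about
10% of the present-class magnitude under our conditions; a control
with a linear readout shows the effect vanish).  With 16 minutes of
data the estimation-noise floor drops below this bias, so any null
that ignores it misclassifies single-input neurons as dual-input.

**Correlated estimation noise.**  Reverse-correlation noise is
strongly correlated across lags (the population rates are
autocorrelated, the 4-fiber PC rate especially), so the plain sum of
absolute filter values drowns a narrow 10–20-ms filter in 100 lags of
correlated noise: its detection power is near chance at exactly the
signal strengths of interest (a PC filter a third the magnitude of its
RA partner).

The test therefore works as follows.  The single-input hypothesis is
built from the joint fit: zero the tested class's half of the
estimated filters and refit the rectifier on the remaining drive.  (A
single-class *refit* would absorb part of the tested class's real
signal for genuinely dual-input neurons and overstate the hypothesis.)
Surrogate spike-count vectors are drawn from the hypothesis's
predicted probabilities (Poisson per 1-ms bin with the
repeat-summed mean — a few percent more variance than the exact
binomial, erring conservative) and the filters re-estimated for each —
a parametric bootstrap whose draws carry both the estimation noise and
the spill-over.  The statistic is the Mahalanobis norm of the class's
100 coefficients under the surrogate covariance
(shrinkage-regularized, 10% of the average eigenvalue on the
diagonal); whitening the correlated noise directions raises the
dual-input detection margin several-fold over the raw magnitude.  The
surrogates are split into two folds, each fold's covariance scoring
the other fold's draws and the observed filters, so every null
statistic is out-of-sample (in-sample Mahalanobis norms are biased low
and make the test anti-conservative).  A class is deemed to contribute
when the pooled bootstrap p-value is at most α (default 0.02 per
class, placing dual false positives on single-input neurons at the
low-percent level).  Stimulus-independent spiking yields a
near-constant hypothesis probability trace, so the same construction
calibrates the "none" decision.

Surrogate re-estimation is cheap because the ridge estimate is linear
in the spike counts: with the precomputed bank `G = S(SᵀS+aI)⁻¹`,
each surrogate costs one sparse gather-product over its spikes.

Because the rectifier also scales the recovered filters (the best
linear fit of `r(x)` is `E[r′]·k` for near-Gaussian inputs — a Bussgang
argument), true-vs-estimated filter comparisons divide each neuron's
estimate by its least-squares gain before pooling; shape metrics
(width, excitation index, magnitude *ratio*) are unaffected by the
gain.

## The peripheral model

Each afferent is a noise-free leaky integrate-and-fire unit,

    dv/dt = (−v + w · f(t − delay)) / τ_m ,

spiking at threshold, resetting to 0, with a 1-ms absolute refractory
period.  `f` holds six rectified stimulus features ([x]⁺, [−x]⁺, [ẋ]⁺,
[−ẋ]⁺, [ẍ]⁺, [−ẍ]⁺) of the Gaussian-pre-smoothed displacement trace.
The integrator uses the exact exponential update for piecewise-constant
drive and locates threshold crossings in closed form within a step
(dt = 0.05 ms), so inter-spike intervals match the analytic LIF
solution to < 1e-3 relative error; this is why entrainment plateaus
(integer spikes per stimulus cycle over a range of amplitudes) emerge
from refractoriness and reset alone.

Default class parameterizations are synthetic stand-ins chosen to
reproduce the qualitative physiology that the downstream analyses rely
on, not fits to any fiber:

* **RA**: positive-going velocity, smoothing σ = 2 ms.  Velocity grows
  with frequency while the smoothing cuts it back, so sensitivity peaks
  near 80 Hz (flutter) and is gone above ~300 Hz.  The smoothing also
  smears RA spike timing.
* **PC**: positive-going acceleration, smoothing σ = 0.8 ms.
  Sensitivity peaks near 280 Hz and rolls off above ~300 Hz; locking is
  millisecond-precise.

Only positive-going channels carry weight so the drive dips below
threshold every cycle; with symmetric weights the drive is positive
almost everywhere and units fire at the refractory ceiling with no
amplitude coding.

Populations (default 14 RA / 4 PC) jitter weights (log-normal 20%) and
thresholds (log-normal 60%, covering about a decade) so the
population-averaged rate grades smoothly with amplitude even though
each unit's rate-intensity function is a staircase of entrainment
plateaus.  Response delays disperse over ~6 ms across RA units but only
~1 ms across PC units: the pooled RA signal is temporally smeared while
the pooled PC signal stays precise — the timing asymmetry between the
two channels that the cortical model's behavior, and the
information-optimal filter shapes, inherit.

Afferent fitting minimizes the summed squared van Rossum distance
(causal exponential kernel; normalized so a single spike against the
empty train has squared distance 1/2) by compass search over the
feature weights, following a schedule of stimulus-set/τ stages — noise
first, then alternating sets with decreasing τ.

## Stimuli

All stimuli are displacement traces in µm at 20 kHz (≥ 2× the 800-Hz
ceiling with margin for differentiated features).  Band-limited noise is
synthesized in the frequency domain — random phases on the in-band bins
— so band edges are exact and a seed reproduces the trace bit-for-bit
("frozen noise").  Texture stand-ins are power-law band noise
(amplitude spectrum ∝ f^−1.5 by default, 50–800 Hz, 500 ms) because the
original texture-elicited vibrometry recordings are not available;
their RMS is drawn log-uniformly.  The "distorted" control is the
second finite difference (central differences; one-sided second-order
at the endpoints, length-preserving) renormalized to the original RMS,
which keeps the frequency support and reweights power by f².

## The validation experiment

Because no recordings are distributed, every stage is validated by
parameter recovery.  The central experiment simulates 243 ground-truth
LNP neurons — a full 3⁵ factorial over input class (both / RA-only /
PC-only), filter width, magnitude, excitation index and temporal
offset — with target firing rates log-spaced over 5–100 spikes/s.
Ground-truth filters are sums of adjacent, compactly supported sin²
lobes, so the requested width, magnitude and excitation index hold
*exactly* under the metrics used to analyze them, and the 80–100-ms
tail used as the width metric's noise reference is exactly silent.

Study conditions (the defaults of `ValidationConfig`): 192 one-second
frozen-noise stimuli (50–800 Hz) at 5 repeats — 16 minutes of noise
data per neuron — with per-stimulus RMS log-uniform over 10–60 µm.
The amplitude spread is deliberately moderate: reverse correlation
assumes weakly correlated population inputs, and very wide amplitude
ranges induce strong shared-envelope correlations between the RA and
PC rates.  The per-neuron gain `b2` is solved by bisection so the mean
spiking probability hits the target rate exactly (baseline `b1`
carries 20% of the rate).  Classification uses 200 circular-shift
surrogates per neuron (enough to place the 98th-percentile threshold
reliably) with the leakage-corrected criterion above.

What passing this experiment shows: the estimation and classification
chain recovers filter shapes and input classes under realistic
temporal statistics, cross-class envelope correlations, rectification
and Bernoulli noise.  What it does not show: robustness to features of
real recordings that the generator does not emulate — electrode drift
and non-stationarity, spike-history dependence (bursting), cortical
coupling, or mismatch between the true encoder and the LNP family.

## Information-maximizing filters

For texture-analog inputs the package asks which filters maximize the
mutual information between the binary spike variable S and the binned
stimulus amplitude V:

    I(S,V) = Σ_s Σ_v p(s,v) log2 [ p(s,v) / p(s)p(v) ]

`p(v)`: absolute deflection amplitude point-sampled per 1-ms bin,
pooled over the texture's traces, in 50 equal-width bins.  `p(s=1|v)`:
the mean LNP probability over time bins whose amplitude, read 15 ms
before the response (cortical latency), falls in bin v — expected
probabilities rather than sampled spikes (same expectation, lower
variance).  Logs are base 2.  The mean spiking probability is
constrained to a target rate (default 0.05 per 1-ms bin ≈ 50 spikes/s,
a mid-range cortical rate); the nonlinearity is fixed.  Optimized
filters are invariant to the rate target and to the nonlinearity
parameters up to overall scale, which the scale-invariance tests
verify.

The gradient is analytic (the dependence of the marginal p(s) on
p(s|v) contributes exactly zero, a convenient identity), with the
sub-gradient at the rectifier kinks taken from the right branch.
Optimization is SLSQP with the equality rate constraint from 10 random
smooth starts by default (deterministic per seed; the best feasible
candidate — including the initialization — is kept, so the reported MI
never falls below the starting point).  Per-class global input
scalings are first calibrated by bisection so mean simulated RA and PC
rates match texture-evoked targets (defaults 80 and 120 spikes/s), and
textures that leave either class below 20 spikes/s are excluded.

Against this synthetic periphery, information-optimal filters weight
RA over PC, make the RA filter net-excitatory and the PC filter
balanced-to-suppressive; re-optimizing on distorted (f²-reweighted)
inputs shifts weight toward PC and pushes the PC filter toward net
excitation.  One qualitative property of the recorded-data analysis
does not reproduce: optimized PC filters do not widen on the distorted
set.  In this generator the PC population tracks per-millisecond
amplitude well even for high-frequency-dominated inputs, so a narrow
PC readout is genuinely optimal; real PC populations appear to carry
less instantaneous amplitude information, forcing longer integration.
The corresponding test documents this as an open divergence rather
than papering over it.

## Numerical choices and degenerate inputs

* Filter width metric: threshold = 3·SD of the filter over lags
  80–100 ms, strict `>`; an all-constant filter (zero tail SD) counts
  every nonzero bin.  On *estimated* (noisy) filters the tail SD
  reflects estimation noise, which makes widths of shallow, broad
  filters biased low; the validation report quantifies this bias.
* Temporal-resolution bands (3/5/13/66 ms) are zero-phase 4th-order
  Butterworth lowpass filters with cutoff 1000/(2·Δ) Hz — the minimal
  reading of "filtered to a resolution"; exact band edges are not
  standardized.
* Predictable variance uses the repeat-based signal-power
  decomposition: signal = (n·Var_t(mean) − mean_t(var across repeats))
  / (n−1), reported as a fraction of signal + trial noise.
* van Rossum distances are computed in closed form from pairwise
  exponentials; fitting costs are summed squared distances.
* Ridge systems are solved by Cholesky factorization, cached per
  regularization weight; a singular `SᵀS` at `a = 0` falls back to the
  pseudoinverse with a warning.
* Surrogate re-estimation (bootstrap and circular-shift alike) runs
  through the cached estimator bank `G = S(SᵀS+aI)⁻¹` as sparse
  matrix products over spike positions (float32), which is what makes
  150 bootstrap draws per class × 243 neurons tractable on one core.
* Problem sizes in the test suite: the validation experiment runs the
  full 16-minute profile; afferent-fit and nonlinearity recoveries use
  a few minutes of stimulation and ~3·10⁵ bins respectively; the
  information-maximization checks use 3 textures × 24 half-second
  traces with 5 restarts.  These sizes were chosen as the smallest
  that leave clear margins on the quantities being tested.

## Known limitations

* The IF afferents are deterministic; real afferent spike-time jitter
  and across-trial variability are absent (population heterogeneity
  stands in for them).
* The afferent parameterization is qualitative: threshold *curves*
  have the right shape and ordering, but absolute thresholds are not
  calibrated to microneurography data.
* SA1 afferents are not modeled; the texture-inclusion rule implements
  only the RA/PC minimum-rate criterion.
* Real-data headline numbers (fractions of predictable variance,
  population filter statistics, texture counts) depend on the
  unavailable recordings and are out of scope; all quantitative claims
  here are about synthetic ground truth.
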