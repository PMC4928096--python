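# Methods

`pphrv` implements an inhomogeneous point-process model of heartbeat
dynamics and the estimator chain built on top of it: instantaneous
time/frequency indices, bispectral indices, complexity measures, and a
stimulus-locked classification pipeline. This note records the model, the
estimators, the numerical choices, and what the synthetic fixtures do and do
not establish.

## The point-process model

R-wave events are modelled as a point process in which the waiting time to
the next beat, given the history, is inverse Gaussian (IG) with shape
`xi0(t) > 0` and mean

    mu_RR(t) = RR_{N(t)} + g0(t) + sum_i g1(i,t) l_i(t)
               + sum_{i<=j} g2(i,j,t) l_i(t) l_j(t)   [+ cubic terms],

where `l_i(t)` are the outputs of discrete orthonormal Laguerre filters
applied to the first-differenced R-R series and `RR_{N(t)}` is the last
observed interval. Modelling interval *differences* improves local
stationarity; anchoring the reconstruction at the last interval keeps
`mu_RR` in seconds. The IG law arises as the first-passage time of a drifted
random walk, which is the physiological motivation for using it as the
inter-beat density. Because the density is defined in continuous time, all
estimators below are available at any time resolution without interpolating
the series.

An important structural consequence of the anchored parametrization: with
constant parameters the model is an *integrated* process (a random walk in
the intervals), so "constant-parameter simulation" in the tests and the
acceptance script means i.i.d. IG draws around a constant mean — the renewal
null of the same distributional family. The full forward NARL generator is
also provided and is validated on short horizons.

### Laguerre basis

`phi_i(n)` with decay parameter `alpha` (default 0.2) and history length
chosen as the smallest `n` with `alpha^{n/2} < 1e-8` (capped at 200 lags, 23
at the default alpha). Orthonormality is enforced at construction to 1e-6.
Defaults: 3 functions in the linear kernel, 2 in the quadratic, 2 in the
cubic (complexity path only). Estimates are undefined until `truncation + 1`
intervals have been observed (burn-in); no zero-padding is used because it
biases early kernels.

### Local maximum likelihood

Parameters are tracked on a `delta`-spaced grid (5 ms canonically; coarser
grids are used for the bundled simulations and are equally valid) by
maximizing the exponentially weighted local log-likelihood over the trailing
window `W` (default 90 s, truncated at the recording start):

    sum_{u_j in (t-W, t]} e^{-varpi (t-u_j)} log f(RR_j | history)
      + log S(t - u_{N(t)})

with the right-censoring survival term for the open interval (toggleable)
and `varpi = 0.02 / s` (e-folding 50 s, inside W). Newton–Raphson with
analytic gradient and Hessian for the observed-interval sum, damped step
halving that enforces a non-decreasing log-likelihood, a safeguarded
gradient step when the Hessian is not negative definite, warm starts from
the previous grid time, and `xi0` optimized on the log scale (bounded to
(~6e-6, 7e10) so near-interpolated small windows cannot drive the
likelihood to infinity). The censoring term's gradient is analytic; its
Hessian contribution (one term among ~100) is omitted, which damping makes
harmless. Non-converged grid points carry the last converged estimate and
are flagged. The grid starts once the burn-in *and* roughly three beats per
parameter are available, so early windows cannot be near-interpolated.

Instantaneous moments from the fitted IG at each grid time:
`sigma_RR = sqrt(mu_RR^3/xi0)`; heart-rate mean and SD from the closed-form
moments of the reciprocal of an IG variate
(`E[1/X] = 1/mu + 1/xi0`, `Var[1/X] = 1/(mu xi0) + 2/xi0^2`), reported in
beats/min.

### Goodness of fit

The time-rescaling theorem maps each interval through the integrated
conditional hazard; under a correct model the transformed variates are unit
exponential, hence uniform after `1 - exp(-z)`. The integral is computed
exactly on each piecewise-constant parameter segment as a difference of IG
log-survival values. The KS distance is taken against the quantiles
`(k - 1/2)/n` with the 95% band `1.36/sqrt(n)`; independence is checked via
the autocorrelation of the normal-quantile-transformed variates at lags
1..60 with bands `+-1.96/sqrt(n)`.

## Spectral and bispectral estimators

The autoregressive Laguerre kernels are converted to input-output Volterra
transfer functions (`H1 = 1/(1 - Gamma1)`,
`H2 = H1(f1+f2) Gamma2 H1(f1) H1(f2)`, with the one-beat lag shift in the
transforms). Kernels live on the beat axis; Hz frequencies use
`nu = f * mu_RR(t)` per grid time.

The linear spectrum is pinned by a Parseval convention:
`S(f,t) = 2 mu_RR sigma^2 |H1|^2` with `sigma^2 = mu^3/xi0`, so the
integral over `[0, Nyquist]` equals `sigma_RR^2` exactly for the null
(white) model; the test suite asserts this. Band powers are trapezoidal
integrals over VLF 0.01–0.05, LF 0.05–0.15, HF 0.15–0.5 Hz with band edges
included (shared edges are measure-zero). The flat-spectrum LF/HF ratio is
therefore exactly 0.10/0.35.

The bispectrum of the quadratic system driven by the white IG innovation is
assembled from the three canonical pairings of two first-order and one
second-order transfer evaluation (the sixth-cumulant `H2^3` term is
excluded); `LL`, `LH`, `HH` are magnitude integrals over LFxLF, LFxHF,
HFxHF. For a linear model (`g2 = 0`) the bispectrum vanishes identically.
The surface is evaluated on the LF-union-HF square (resolution 0.005–0.01 Hz
by configuration) and, for cost control, on a strided subset of grid times,
step-expanded back to the full grid.

## Complexity estimators

**Lyapunov exponents.** Per beat, a sparse cubic NAR map on the
Laguerre-filtered differences is selected by Fast Orthogonal Search over the
trailing window: candidates are all Laguerre monomials up to order 3 plus a
constant, greedily added by residual-variance reduction through
orthogonalized regressors. The stop rule compares the best marginal
reduction, relative to the current residual variance, against
`max(1e-4, (2 log C + 6)/N)` for `C` candidates — the extreme-value scale of
chance reductions — so white noise selects nothing while genuine structure
passes easily. The companion-form Jacobian of the fitted map is evaluated at
the observed state and accumulated through a running QR chain;
`lambda_i(t)` is the trailing-window mean of `log R_(j)ii` (nats/beat
primary; per-second values divide by the local mean interval; the first two
exponents are reported in sorted order). Windows whose fit keeps no dynamic
term would give an exactly singular map, so the last informative fit is
carried; a genuinely singular chain flags the grid time missing.

**Point-process entropy.** Phase-space points are the per-beat predictive IG
laws; the distance between two points is the Kolmogorov–Smirnov distance
between their cdfs. Because the density log-ratio of two IG laws is a
quadratic in the elapsed time after clearing denominators, the sup-norm is
attained at one of at most two positive roots — the vectorized path
evaluates these exactly, while the scalar `ks_distance` keeps a coarse-scan
plus golden-section construction (tolerance 1e-8) for generality; the two
agree to ~1e-12 and the test suite pins the optimized aggregates to a naive
double-loop implementation at 1e-10.

The match radius carries the conventional `0.2 * SD` rule into the distance
space actually used: `r(t)` is the KS distance between two predictive IG
laws whose means differ by `0.2 * sigma_RR(t)` (about 0.08 for near-Gaussian
shapes). Taking `0.2 * sigma_RR(t)` literally as a KS threshold would
compare a dimensionless quantity against seconds and makes every template
mismatch. `A_I` uses the `Phi^m - Phi^{m+1}` log-average construction with
self-matches (always defined); `S_I` uses `-log(A/B)` excluding
self-matches. Both orders are evaluated over the same `N - m` templates, so
the order-(m+1) match count never exceeds the order-m count pointwise:
`A_I >= 0` by construction and a perfectly regular sequence gives exactly
`S_I = 0`. Zero matches at order `m+1` flag the grid time missing rather
than infinite. Embedding `m = 2`,
beat-anchored templates, trailing window `W`. `S_I` is sparse by nature when
matching is rare; the estimate panel carries the last defined value forward,
which makes some of its windowed summaries (e.g. the MAD over one second)
exactly zero — a known, documented property of count-based estimators at
these window lengths.

## Feature extraction and classification

Per stimulus, each of the 13 estimators (`mu_RR`, `sigma_RR`, `sigma_HR`,
LF, HF, LF/HF, LL, LH, HH, `A_I`, `S_I`, `lambda1`, `lambda2`) is restricted
to the last second of the stimulus, divided pointwise by the estimator's
median over the first covered 10 s of the initial rest (estimates exist only
after the model burn-in, so the window starts at the first covered instant),
and summarized by maximum, median and MAD: 39 dimensions. A rest baseline
that is exactly zero (possible for degenerate entropy stretches) falls back
to the mean magnitude of the rest window, then to 1, instead of dividing by
zero.

Screening: a stimulus is dropped when any dimension's z-score (mean/sample
SD over rows) exceeds 4 in magnitude, skipping zero-variance dimensions.
Paired differences between conditions use the two-sided Wilcoxon signed-rank
test (exact null for n <= 25, normal approximation above, zeros dropped,
empty effective samples guarded as p = 1).

Classification is leave-one-out with a nu-SVM (nu = 0.5, radial basis
kernel, `gamma = 1/n_features`); per fold, median/MAD normalization is
fitted on the training split only. Scaled features are clipped at +-3 MAD
units: with `gamma = 1/n` the worst single dimension then contributes at
most `(2*3)^2/n ~ 1` nat to the kernel exponent, so an epsilon-floored
degenerate dimension cannot saturate the kernel into the majority-vote
regime (in which leave-one-out becomes systematically anti-predictive).
Force and velocity run as independent binary problems.

SVM-RFE ranks features per training fold by the change in the kernel-space
weight criterion `sum alpha_i alpha_j y_i y_j K(x_i, x_j)` when a feature is
removed from the kernel (an O(1) elementwise update for the RBF kernel),
with a correlation-bias-reduction step: features whose pairwise correlation
exceeds 0.95 within the fold are grouped, given their mean criterion, and
eliminated together; ties break by original feature index. The
accuracy-versus-top-k curve re-runs the leave-one-out classifier on the
top-k features by overall median rank.

## Synthetic data

The protocol generator emulates the study conditions: per subject, two
2-minute rests bracketing the four stimulus types (2 force x 2 velocity
levels, randomized order), 35-s pre/post windows, and per-velocity stimulus
durations of 25 s (slow) and 4.3 s (fast), inside the 4.3–25 s range.
Defaults: 32 subjects, baseline mean interval 0.8 s with between-subject SD
0.05 s, IG shape 1500 with log-normal subject multiplier, and deterministic
LF (0.095 Hz, 15 ms) and respiratory-band (0.25 Hz, 25 ms) mean modulation.
Intervals are conditionally independent IG draws around the modulated mean
(see the integrated-process note above). Condition effects act only inside
stimulus windows as mean shifts and multiplicative scalings of the
respiratory amplitude and IG shape; the fast-velocity effect
(-120 ms mean, HF x 0.20, shape x 0.35) was calibrated once so that the
velocity task lands in a separable-but-not-trivial 75–95% leave-one-out
band at the bundled problem size, and the force effect is deliberately
weaker. These effect sizes are fixture choices, not physiological claims.

What the fixtures do *not* emulate: real QRS morphology and detection
error, respiration as a measured covariate, ectopy, slow drifts,
inter-subject autonomic heterogeneity beyond the two random effects, and
any genuine nonlinearity of cardiac control beyond what the fitted model
class induces. Passing tests therefore establish internal consistency and
correctness of the estimators against their definitions and closed-form
oracles — not clinical validity on recorded data.

## Problem sizes and runtime choices

The bundled test suite and the acceptance script run on scaled problem
sizes chosen as reasonable desk-scale defaults: 6–16 simulated subjects on
coarse grids (0.1–0.25 s instead of 5 ms), 100 ten-minute constant-parameter
simulations for the coverage check, a 2000-iterate logistic chain for the
Lyapunov oracle, and a ~200-beat segment for the entropy double-loop
oracle. All estimator code is grid-agnostic; the 5 ms canonical resolution
is a configuration value, not an assumption.

## Known limitations

- The anchored conditional mean makes the constant-parameter model
  integrated; long free-running NARL simulations drift and the renewal null
  is used instead (see above).
- `S_I` is undefined where no template matches at order m+1; downstream
  consumers see carried values.
- Artifact correction uses a predictive-IG tail criterion (default 1e-4 per
  side on a 90-s local fit) with merge/insert actions; this is a documented
  stand-in for real-time correction algorithms whose exact published policy
  is unavailable, and its actions are flagged per beat.
- Kernel transforms are implemented to order 2 (spectra/bispectra); cubic
  terms feed only the complexity path.
- The LF/HF ratio uses a floor on the HF power; bicoherence normalization is
  an extension point, not implemented.
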