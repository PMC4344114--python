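# Methods

## Encoding model

The package models a one-dimensional, non-periodic stimulus variable `s`
(arbitrary units A) encoded by `N` rate-coding neurons. Each neuron's spike
count over an integration window `tau` (seconds) is Poisson,
`R_i ~ Pois[tau * f_i(s)]`, and counts are conditionally independent across
neurons given the stimulus. Two tuning-curve families are supported:

- **unimodal** (Gaussian bump): `f(s) = f_bg + f_mod exp(-(s-sigma)^2 / 2 omega^2)`;
  `sigma` is the peak.
- **monotonic** (logistic sigmoid): `f(s) = f_bg + f_mod / (1 + exp(-(s-sigma)/omega))`;
  `sigma` is the flank midpoint, where the rate is `f_bg + f_mod/2` and the
  gradient is maximal (`f_mod / 4 omega`).

Parameters, with the defaults used by most bundled conditions: background
rate `f_bg` (10 spikes/s; must be positive for any Chernoff computation,
since natural parameters are `log lambda`), modulation depth `f_mod`
(40 spikes/s), width `omega` (0.1 for unimodal, 0.044 for monotonic — these
give approximately matched peak gradients), and `tau` (condition-dependent,
5 ms–1 s; shorter `tau` means higher trial-to-trial variability). Rates are
never clamped; tuning functions are defined on all reals, so task ensembles
may extend beyond any nominal stimulus interval without clipping.

Populations place `N` copies of a template curve with characteristic
stimuli regularly spaced across an interval. By default the spacing
includes both endpoints, so odd `N` yields a neuron exactly at the interval
center — the "neuron of interest" in marginal analyses; a cell-centered
placement is available as an option.

Stimulus ensembles are discrete distributions over stimulus values.
Continuous uniform stimulus variables are represented by uniform grids
(default 401 points), and all "continuous" analyses are carried out on such
grids. Zero-probability stimuli are allowed in custom ensembles; information
curves there are reported as NaN (undefined), not zero.

The **flank width** of a tuning curve is defined as rate range over maximum
slope, `f_mod / max|f'|` (`omega e^{1/2}` for unimodal, `4 omega` for
monotonic), and forced-choice spacings are normalized by it:
`delta_s_norm = delta_s * max|f'| / f_mod`. A spacing of one flank width has
`delta_s_norm = 1`. This orientation makes the normalized spacing
dimensionless and linear in `delta_s`.

## Information measures

**Fisher information.** `J(s) = tau f'(s)^2 / f(s)` per neuron, summed over
conditionally independent neurons. Derivatives are analytic. Although some
ensembles are discrete, `J` treats `s` as continuous (it requires a
derivative); curves are simply evaluated on the grid.

**RSI / SSI.** All Shannon quantities are in bits, with `0 log 0 := 0`. The
response-specific information of a response vector is
`I(r) = H(S) - H(S|R=r)` with the posterior computed exactly by Bayes' rule
over the (discretized) ensemble; it can be negative for responses that
point to unexpected stimuli. The SSI is `I(s) = E_{r|s}[I(r)]`, evaluated
two ways:

- *Exact enumeration*: each neuron's count range is truncated at the
  smallest `c` with `CDF(c; lambda_max) >= 1 - epsilon` (`epsilon = 1e-10`
  by default), where `lambda_max` is the neuron's largest mean over the
  ensemble, so the enumerated lattice carries at least `1 - N epsilon` of
  the mass under every stimulus. The lattice size is capped at 1e7 states;
  beyond that an error directs the caller to the Monte-Carlo path.
- *Monte Carlo*: for each stimulus, `M` response vectors are drawn from
  `P(r|s)` (default `M = 1000`), the exact posterior is evaluated for each,
  and the RSI is averaged; the reported standard error is the sample
  standard deviation over `sqrt(M)`. This avoids the exhaustive integral
  over the response space and scales to hundreds of neurons. `M` is chosen
  per analysis so standard errors are small relative to curve features, and
  is always recorded in output metadata.

The expectation of the SSI over the ensemble is the mutual information
`I(S;R) >= 0` (even where the SSI itself is negative). When `I(S;R)`
exceeds 99% of `H(S)` a warning is emitted: a saturated code distorts the
shape of the SSI, and modeled precisions should be chosen to stay below
saturation.

**Marginal SSI (mSSI).** The contribution of neuron `i` in context:
population SSI minus the SSI of the population without neuron `i`. The two
RSI terms are evaluated on the *same* sampled response vectors (the reduced
term drops coordinate `i`, a valid marginal of the joint distribution), so
the difference is a paired estimate with greatly reduced variance; its
standard error is that of the paired difference. Single-neuron SSI and mSSI
act as upper and lower bounds on a neuron's informational contribution in a
redundant code.

**Chernoff distance.** In nats (a bits conversion is provided). For
independent Poisson populations the alpha-exponent factorizes as
`phi(alpha) = sum_i [alpha l1_i + (1-alpha) l2_i - l1_i^alpha l2_i^(1-alpha)]`.
Three routes are implemented and cross-validated:

- *Univariate closed form*: with the logarithmic mean
  `L = (l2 - l1)/log(l2/l1)`, the optimal exponent solves
  `l1^a l2^(1-a) = L` and `D_C = a l1 + (1-a) l2 - L`; the `l1 = l2` limit
  is `D_C = 0`, `a = 1/2`.
- *Bregman bisection*: in natural parameters `theta_i = log lambda_i` with
  log-partition `F(theta) = sum exp(theta_i)`, there is a point
  `theta_alpha = alpha theta1 + (1-alpha) theta2` at which the two Bregman
  divergences are equal, and the common value is `D_C`. The implemented
  divergence `B(theta, theta') = F(theta') - F(theta) - <theta'-theta, grad F(theta)>`
  expands around its *first* argument, and the bisection equalizes
  `B(theta_alpha, theta1)` and `B(theta_alpha, theta2)`; this orientation is
  pinned by mandatory equality tests against direct maximization (agreement
  to 1e-8 on randomized suites with `N` up to 20). The gap function is
  monotone in alpha; bisection stops at gap `< 1e-10` or interval
  `< 1e-12`, capped at 200 iterations.
- *Direct maximization*: dense alpha grid (1001 points) plus bounded
  refinement of the factorized exponent; and, for small means, evaluation
  of the defining sum on a truncated count lattice (which factorizes over
  coordinates). These are the oracles for the other two routes.

**Task curves.** A 2AFC task with spacing `delta_s` is modeled by two-point
ensembles. A stimulus can be the lower or upper member, so its task SSI has
K components `I_k(s)` (SSI of `s` as the k-th member of a K-point
equiprobable ensemble); the task curve is their simple average. This
average is local to `s` and is not a mutual information; the alternative
centered average (ensemble `{s - delta_s/2, s + delta_s/2}`, which *is* the
ensemble's mutual information) is provided for comparison and agrees
closely at small spacings. The task Chernoff curve is
`[D_C(s, s+delta_s) + D_C(s, s-delta_s)]/2`; K is fixed at 2 for Chernoff,
which is inherently pairwise. Marginal task curves (mSSI per component with
common random numbers; mDC as full-population minus reduced-population task
Chernoff curve — the definition mirrors the mSSI) quantify the neuron of
interest's contribution. Note that for conditionally independent neurons
the mDC is bounded by `0 <= mDC(s) <= single-neuron task curve`, with
equality at the upper bound for an identical twin: unlike the mSSI, the
Chernoff exponent is additive over neurons at fixed alpha, so redundancy
cannot drive the mDC to zero.

## Regime classification and transition detection

In forced-choice tasks the best-encoded stimulus switches from the
maximal-gradient flank (fine discrimination, Fisher-like) to the
tuning-curve peak (unimodal) or the flank ends (monotonic) as the
normalized spacing grows past about 1. The classifier formalizes this by
the location of the information curve's global argmax relative to the
neuron of interest:

- unimodal: *coarse* when the argmax lies within 0.25 flank widths of the
  peak `sigma`; *fine* otherwise.
- monotonic: *coarse* when the argmax lies at least 0.5 flank widths from
  `sigma` (at or beyond a flank end); *fine* otherwise.

The coarse regime is recognized *positively* (argmax jumping to the peak or
flank ends) rather than by distance from the Fisher maxima, because the
fine-regime flank peaks themselves drift gradually outward with the task
spacing; a distance-from-Fisher rule would misread that drift as a regime
change roughly one scan step early. Thresholds (0.25, the noise factor, and
the zero tolerance) are configurable. Curves whose maximum is not
distinguishable from zero (non-positive, below an absolute tolerance of
1e-12, or below twice the median Monte-Carlo standard error) are classified
*undefined*.

A transition scan evaluates the marginal task curve on a log-spaced grid of
normalized spacings (default stimulus grid: 101 points spanning 2.5 flank
widths either side of the neuron's characteristic stimulus), classifies
each curve, and places the fine-to-coarse boundary by a
minimum-misclassification changepoint over the label sequence (identical to
the unique switch for clean sequences, robust to an isolated Monte-Carlo
label flip). The reported transition is the arithmetic midpoint of the
bracketing pair of scanned spacings; sub-grid interpolation is deliberately
avoided because Monte-Carlo noise makes it spurious. With the bundled
81-neuron, 20 ms conditions and an 11-point scan of [0.16, 1.6], the
deterministic marginal-Chernoff scans bracket the transition at
(0.80, 1.01) for both tuning families; the stochastic marginal-SSI scans
bracket it within one grid step of 1, with the exact bracket at knife-edge
grid points depending on the Monte-Carlo seed.

## Bayesian observer

The observer knows the stimulus distribution and the encoding model; by
default its prior equals the true stimulus distribution (any prior can be
supplied). The average posterior `P(z|s) = E_{r|s}[P(z|r)]` is computed
exactly on the truncated lattice when feasible and by Monte Carlo otherwise
(exact columns sum to 1 up to the `<= N epsilon` truncated mass; MC columns
sum to 1 exactly). Sorting each column in descending order leaves column
sums and entropies unchanged and exposes the per-stimulus uncertainty
profile. `I2(s) = H(S) - H(Z|S=s)` takes the entropy of the averaged
posterior, whereas the SSI averages the entropies of individual posteriors;
the two are genuinely different quantities and the tests verify a
measurable difference at moderate noise.

## Randomness and reproducibility

Every stochastic analysis takes a single integer seed. Per-stimulus
substreams are derived deterministically from (seed, grid index) via
`SeedSequence` spawn keys, so results do not depend on evaluation order and
repeated runs are byte-identical. Scans derive one 31-bit child seed per
scan step the same way.

## Synthetic study conditions

The fixture registry reproduces the stereotypical conditions analysed with
the package (single neurons on rich ensembles, population scans,
non-uniform priors, forced-choice scans). Where a condition does not pin a
value, the fixture records a documented default: integration-time scans use
five log-spaced values {5, 20, 80, 300, 1000} ms; small-population 2AFC
conditions default to N=4 with tau=5 ms; the broadly peaked stimulus
distribution is a synthetic truncated-Gaussian-shaped weight profile of
width 0.3 on [-1, 1], wide relative to the tuning curves (FWHM about a
third of the interval) yet concentrated enough that stimuli at the central
neuron's tuning tails are genuinely uncommon — the condition under which a
transiently negative marginal SSI arises. Analyses on these stand-ins are
qualitative.

These generators emulate idealized rate codes only: homogeneous tuning
amplitudes, uncorrelated Poisson variability, stationary rates, and a
one-dimensional linear stimulus. Passing tests therefore demonstrate the
correctness of the measures on the model class, not properties of real
neural data, which exhibit correlated variability, heterogeneous tuning
and non-Poisson dispersion.

## Problem sizes

The bundled analyses run at desk scale: grids of 101–401 stimuli, Monte
Carlo with 400–2000 samples per stimulus in the test suite and 1000 in the
regime scans, populations up to N=81. These sizes keep standard errors
small relative to the curve features being classified while completing a
full scan in tens of seconds on one CPU; all of them are parameters, and
larger runs only cost time.

## Known limitations

- No correlated trial-to-trial variability, non-Poisson noise, spike-timing
  codes, or circular stimulus spaces.
- Exact SSI and exact posteriors are limited by the truncated-lattice cap
  (about 1e7 states); larger problems must use the Monte-Carlo estimators.
- The Chernoff machinery requires strictly positive rates (`f_bg > 0`) and
  is pairwise only (no K > 2 generalization).
- Monte-Carlo SSI estimates are unbiased per stimulus but noisy; argmax
  locations extracted from noisy curves near a regime boundary inherit that
  noise (hence bracket-midpoint transition reporting).
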