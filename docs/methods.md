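# Methods

## The model

`msvolt` fits a multivariate stochastic volatility (MSV) model to
multichannel neural time series.  For J channels observed at times
t = 0..T−1 within an epoch,

    y_{j,t} = exp(x_{j,t}/2) ε^y_{j,t},        ε^y_t ~ N(0, I_J)
    x_t − μ = β (x_{t−1} − μ) + ε^x_t,         ε^x_t ~ N(0, Σ)

with Σ = diag(σ²₁..σ²_J).  The observed series has zero conditional mean
(preprocessing removes linear structure first); all temporal and spatial
structure lives in the latent log-volatility x.  The persistence matrix β is
*full*: β[j,k] is the lag-one effect of channel k's log-volatility on channel
j's, so off-diagonal entries encode directed cross-channel influence, the
quantity of scientific interest for region-level connectivity.  Channels are
conditionally independent given their latent paths; heavy tails (kurtosis
above 3) and volatility clustering in y are emergent, not assumed.

Epochs (events) are modelled as independent realizations that share (μ, β,
Σ) — a session-stationarity assumption appropriate when all epochs come from
the same task period.  Each event's initial latent state is drawn from the
stationary law N(μ, V₀) with V₀ solving the discrete Lyapunov equation
V₀ = βV₀βᵀ + Σ, which makes events exchangeable.

Stationarity is enforced as spectral radius of β strictly below 1.  The
entrywise bound |β[j,k]| < 1 (the prior's support) does *not* imply this for
J > 1, so both conditions are checked; the prior is used truncated to the
stationary region, unnormalized (the truncation constant cancels in MCMC
ratios).

## Priors

Deliberately flat: μ ~ MVN(0, 1000·I); each (β[j,k]+1)/2 ~ Beta(20, 1.5)
independently (favouring strong positive persistence — the Beta(20,1.5)
mode maps to β ≈ 0.949 — while keeping entries inside (−1,1)); and
σ²_j ~ Gamma(shape 1/2, rate 1/20), equivalently ±σ_j ~ N(0, 10).  With the
data sizes these analyses use (10⁴–10⁶ samples per channel) the likelihood
dominates all three.

## Estimation

The observation equation is linearized by squaring and taking logs:
z = log(y² + c) = x + log ε², with offset c = 10⁻⁸ × per-channel sample
variance guarding exact zeros (scale-aware, negligible bias).  The log χ²₁
error is approximated by the standard 10-component Gaussian mixture (Omori,
Chib, Shephard & Nakajima 2007 constants, checked in the tests against the
exact law: CDF distance < 0.01, matching mean ψ(1/2)+log 2 and variance
π²/2).  No final reweighting to the exact likelihood is applied; posterior
summaries are therefore exact for the auxiliary mixture model and accurate
to the mixture error for the original model.

A Metropolis-within-Gibbs sweep cycles:

1. **Mixture indicators** from their exact discrete conditionals.
2. **Latent paths** by forward-filtering backward-sampling (FFBS) — an
   exact joint draw per event from the conditionally linear-Gaussian model,
   with the stationary N(μ, V₀) initial state.  The kernels are numba-
   compiled scalar loops over events × time with dense J×J algebra.
3. **μ** from its conjugate Gaussian conditional (transitions + initial
   states + prior).
4. **β row-wise** by MH.  The default proposal is the exact Gaussian shape
   of the row's transition likelihood, N(G⁻¹c_j, σ_j²G⁻¹) where G and c_j
   are lagged Gram statistics; the likelihood then cancels in the acceptance
   ratio, leaving only the prior and the initial-state density (which
   couples rows through V₀ and is recomputed per proposal via a Lyapunov
   solve).  Proposals outside the stationary region are rejected.
5. **σ² per channel** by MH with the analogous inverse-gamma likelihood-
   shaped proposal IG(n_tr/2 − 1, SSE_j/2).

Sweeps alternate these independence proposals with classical random-walk
proposals (Gaussian on β rows; log-scale on σ²).  The independence moves
give near-ideal mixing when the likelihood is informative; the random-walk
moves provide a local escape channel from a sticky self-consistent region at
σ² ≈ 0 (over-smooth latents imply tiny innovations imply tiny σ²) that pure
independence sweeps exit slowly on small datasets.  Random-walk scales start
at likelihood-informed values (≈2.4× the conditional standard deviations)
and adapt toward 30% acceptance during burn-in only, so the post-burn-in
kernel is fixed.  A pure random-walk sampler (`proposal="rw"`) is retained;
its acceptance rates on the synthetic benchmark sit in the conventional
(0.1, 0.7) band.

Initialization is method-of-moments on z: Cov(z) = Cov(x) + (π²/2)I and the
lag-one cross-covariance of z equals βV₀, giving starting values for β and
σ²; eigenvalues of the implied Cov(x) are floored at 0.25 and σ² at 0.05
because at small sample sizes the moment estimate of Cov(x) can collapse,
which would start the chain inside the σ² ≈ 0 region.

Setting `diagonal=True` pins all off-diagonal β at zero, which reduces the
model to J independent univariate SV models (verified against separate
single-channel fits in the tests).

### Sampler validation

Three layers, all in the test suite:

- **Oracle equivalence.** The Kalman filter log-likelihood equals the
  log-density of the explicitly assembled JT-dimensional joint Gaussian on
  random small instances (J ≤ 3, T ≤ 6) to 1e−8, and FFBS draw moments match
  the brute-force conditional of that joint Gaussian.
- **Exact conditionals.** μ, β, σ² updates are checked against closed-form
  or numerically integrated one-dimensional conditionals.
- **Prior invariance (Geweke-style).** A successive-conditional simulator
  alternates one full sampler sweep with a fresh redraw of (x, indicators,
  z) given the current parameters, generating z in the linearized space
  with the same mixture the sampler targets — so the check is exact for the
  sampler as implemented.  Recorded β and σ² marginals match their priors
  (KS test on a thinned chain).  The σ² chain makes occasional long
  excursions near zero (the Gamma(1/2) prior concentrates mass there and
  the region is slowly mixing), so finite chains at some seeds fail a KS
  test on dwell-time clumping alone; a 150 000-cycle chain passes with
  KS p ≈ 0.8–0.99 and quantile-exact occupancies.  μ mixes slowly relative
  to its very flat N(0, 1000) prior (its conditional is much tighter than
  the prior), so the prior-invariance test targets β and σ².

## DIC model comparison

D̄ = E[−2 log P(y | θ, x)] averages the conditional deviance over posterior
draws, with latent paths treated as parameters; p_D = D̄ − D(θ̄, x̄) at the
posterior means; DIC = D̄ + p_D.  Because the conditional likelihood depends
on θ only through x, the per-draw deviances recorded during sampling are
exactly the required quantities; D̄ uses the stored (thinned) latent draws
and x̄ the running mean over all kept iterations.  Comparisons between the
full MSV and the diagonal (univariate SV) fit are normalized by
events × electrodes.  An exp(ΔDIC/2) evidence ratio helper is provided but
labelled heuristic.

## Spectral companions

- Rolling variance (window 20, ddof 1) and a log-normal goodness-of-fit
  (Gaussian MLE on logs + KS test) reproduce the empirical motivation:
  volatility of detrended traces is right-skewed and near log-normal.
- Morlet wavelet power (wave number 5) on a 3–180 Hz grid via
  `mne.time_frequency.tfr_array_morlet`, kept time-resolved for the
  volatility–power correlation and log-transformed + epoch-averaged (over
  edge-valid samples) for classification features; per-session z-scoring
  across events.
- The volatility–power relation correlates the posterior-mean log-volatility
  path with the log power time course within each event and averages over
  events; on synthetic MSV data this correlation is strongly positive at
  high frequencies, mirroring the broadband character of volatility.
- Frequency curves are smoothed by Gaussian-process regression with a
  Matern(5/2) kernel (amplitude and white-noise level estimated by marginal
  likelihood, jitter 1e−6).  The zero-function test is a Wald-type quadratic
  form of the posterior mean against zero on an evaluation grid (default 11
  log-spaced frequencies, configurable), with dof equal to the grid size —
  a reconstruction of the usual χ²-on-a-grid reading, and calibrated to
  near-nominal size in the tests.

## Behavioural analyses

**Classification.** Features are per-electrode epoch means of posterior-mean
log-volatility (or electrode × frequency z-scored log power), z-scored
within session.  An L2-penalized logistic regression is evaluated by
leave-one-session-out nested cross-validation: the inner leave-one-session-
out CV over the remaining sessions picks the penalty from a log-spaced
10⁻⁴..10⁴ grid by mean AUC; at least three sessions are required.  AUC is
the pairwise concordance probability with ties counted ½.

**Directional connectivity.** The fitted β is aggregated to regions:
C_{I→J} = mean over target electrodes j ∈ J (rows) and source electrodes
i ∈ I (columns) of β[j, i] — the lag-one influence of region I on region J.
The subsequent-memory contrast is Δ_{I→J} = C^R − C^{NR} from separate fits
to recalled and non-recalled epochs, averaged within subject.  Group
inference: two-sided one-sample t-tests per ordered region pair across
subjects, cells with fewer than 10 contributing subjects excluded before
Benjamini–Hochberg FDR adjustment at α = 0.05.

## The synthetic-data generator

`synthetic` draws data exactly from the MSV model with known parameters
(counter-based seeding: one master seed spawns a substream per event, so
earlier events are unchanged when the event count grows).  The benchmark
parameter set uses diagonal persistence 0.85, off-diagonal couplings ±0.08,
μ spanning −0.5..0.5 and σ² = 0.1 — values in the range typical of highly
persistent volatility series.  Condition pairs plant a directed region-level
contrast (default magnitude matching the −0.04..−0.06 range relevant for
MTL subsequent-memory effects) into β of the recalled condition only.  Raw
fixtures pass MSV innovations through an AR filter, add a 60 Hz line
sinusoid and a common across-channel offset, exercising notch filtering,
common-average referencing and VAR detrending end to end.

What the generator does *not* emulate: 1/f spectral background, true
oscillations, artifacts, bad channels, inter-subject anatomical variation,
volume conduction, or any relation between volatility and behaviour beyond
the planted β contrast.  Passing tests therefore certify the estimation and
inference machinery, not the adequacy of the MSV model for any particular
real recording.

## Preprocessing

Zero-phase (forward–backward `sosfiltfilt`) 4th-order Butterworth band-stop
at 57.5–62.5 Hz; common-average reference across the montage (CAR and the
notch commute, both being linear and channel-symmetric — tested); epochs are
half-open windows of round(1.6·fs) samples, 0-based; VAR detrending is a
pooled least-squares fit across a session's epochs, with the order chosen by
AIC over p ∈ {0..p_max} (default p_max 10), all candidate orders scored on a
common response window, ties toward parsimony.  AIC's known overselection
(probability ≈ P(χ²₁ > 2) per spurious lag) means order recovery is a
majority-of-replicates property, and the tests assert it as such.

## Problem sizes and numerical choices

Validation workloads are sized for a single CPU: parameter recovery uses
J=3, 300 events of 800 samples with 400 MCMC iterations (μ within ±0.1, β
within ±0.05, σ² within ±30% of truth); DIC comparisons use 80 events of
250 samples; the planted-contrast study uses 40 subjects × 2 conditions ×
(30 events of 240 samples) with 250 iterations per fit; the prior-invariance
chain runs 45 000 cycles at J=1, one event of 4 samples.  Epoch length
matters for directional inference: at ~120 samples per epoch the planted
directed effect partially reflects into the mirror (reverse-direction) cell,
while at 240 samples the reflection vanishes — short epochs blur lag-one
directionality, a caveat that applies to real data as well.

Degenerate inputs are handled explicitly: Σ = 0 collapses FFBS to the
deterministic path (a PSD-aware Cholesky zeroes null directions; a relative
ridge of 1e−12 keeps the backward smoother defined); constant series are
flagged rather than z-scored or log-fitted; innovation covariances in the
filter are always positive-definite because the mixture variances are.

## Limitations

- Σ is diagonal; contemporaneous volatility correlation is not modelled.
- The mixture linearization is an approximation (no reweighting step).
- DIC with latents as parameters is one of several DIC variants; its p_D
  can be large and comparisons should stay within this convention.
- Posterior means of β need not be stationary even when every draw is; the
  summary re-checks and warns.
- Single-lag (VAR(1)) latent dynamics; longer-range volatility dependence
  is only captured through persistence.
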