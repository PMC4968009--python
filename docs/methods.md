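# Methods

This note documents the statistical machinery implemented in `movelsp`:
the periodogram and its fast evaluation, the movement models used as
simulators and null hypotheses, the Monte-Carlo periodicity test, the
schedule diagnostics, and the numerical and design choices made where
more than one defensible option existed.

## 1. The periodogram of a gappy track

### Definition

A telemetry record is a series of K-dimensional planar locations
X(t_j) (K ∈ {1,2,3}, meters) at strictly increasing epoch times. The
record is laid on an even grid {t_j = t_1 + (j−1)Δt, j = 1…N} with the
grid interval Δt equal to the median sampling interval (lower median:
with an even number of distinct gaps the finer candidate is used, so a
mostly-hourly record with dropouts maps to an hourly grid). A binary
schedule function w(t_j) marks cells holding a record; each record snaps
to its nearest cell, and of two records colliding on one cell the
earlier is kept (deterministic, order-independent). The `res_time`
option refines the grid to Δt/res_time, shrinking the worst-case
snapping error to Δt/(2·res_time).

At frequency f the Lomb-Scargle periodogram (LSP) is the least-squares
fit of the observed values to a sinusoid pair,

    X(t_j) ≈ A(f) e^{2πif t_j} + A(f)* e^{−2πif t_j},

per dimension, with the power defined as half the energy the fit
explains: LSP(f) = ½(Σ_j w_j X_j² − min_A L(f)), where L is the
w-weighted squared error. The K dimensions are fit independently and
the combined periodogram is their arithmetic mean. Before fitting, each
dimension is centered by its schedule-weighted mean Σ w X / Σ w; the
sinusoid model has no intercept, and an unremoved DC offset would
otherwise leak into every frequency through the schedule transform.

### Fast evaluation

Writing W = DFT{w} and P = DFT{w·X_centered} (convention
DFT{Y}(f) = Σ_j Y_j e^{−2πif t_j}), solving the two normal equations of
the fit analytically gives

    LSP(f) = [ W(0)·|P(f)|² − Re( conj(W(2f)) · P(f)² ) ]
             / [ W(0)² − |W(2f)|² ].

The conjugation on W(2f) matters: it is what makes the expression
invariant to shifting the time origin, as a least-squares power must be.
Both transforms are evaluated by one real-input FFT zero-padded to
length M = 2·res_freq·N, so that every grid frequency k·Δf/res_freq
(Δf = 1/(NΔt)) sits on bin 2k and its double on bin 4k; bins above M/2
come from conjugate symmetry. Complexity is O(N log N) and the whole
pipeline is FFT-bound.

The frequency grid runs from Δf/res_freq up to the Nyquist frequency
F = 1/(2Δt), excluding f = 0 (degenerate there, and the mean is removed
anyway). `res_freq` oversamples the spectrum; beyond the base resolution
the data contain no new information and the periodogram merely smooths.

### Degenerate frequencies

Where the denominator W(0)² − |W(2f)|² falls below 10⁻¹²·W(0)² the
closed form is 0/0 or numerically unstable. The canonical case is the
exact Nyquist bin of an even-length complete series: there
W(2F) = W(0), the sine quadrature vanishes, and the least-squares power
equals exactly half the DFT bin. At such bins the implementation solves
the fit's 2×2 normal equations directly (minimum-norm where singular);
their coefficients are simple functions of W(0), W(2f) and P(f), so the
fallback is O(1) per affected bin. Consequently the identity "LSP =
DFT periodogram when no data are missing" holds to floating-point
precision at every frequency except that single boundary bin, where the
factor ½ is intentional and asserted in the tests.

### Exact-time oracle

`lsp_oracle.lsq_lsp` evaluates the same least-squares problem by dense
normal equations at the *true* (unsnapped) record times, O(N) per
frequency. It certifies two things: that the FFT algebra is exact on the
grid (agreement ~10⁻¹³ relative), and that grid snapping converges —
for fix times perturbed by quarter-interval multiples, the sup-norm
error of the snapped periodogram shrinks monotonically over
res_time ∈ {1, 2, 4} and reaches numerical precision at 4, where the
perturbed times lie exactly on the fine grid. For continuously jittered
times the residual error is O((2πfε)²) with ε the residual snapping
offset; res_time = 2 already suffices for most schedules.

### Spectral leakage and prewhitening

A rectangular-window periodogram cannot display spectral decay steeper
than f⁻²: the Fejér kernel's sidelobes fall off as f⁻², and for a
non-stationary process (whose variance, and hence leakage floor, grows
with the study duration) the floor does not recede with longer records.
The velocity-autocorrelated families genuinely fall as f⁻⁴ below period
2πτ_vel, so their raw periodograms flatten to slope 2 at high frequency.
`prewhitened_lsp` applies the classical remedy for complete series:
difference the series (the differenced process is near-stationary with
small variance) and divide the resulting periodogram by the exact
transfer function of differencing, |1 − e^{−2πifΔt}|² = 4 sin²(πfΔt).
The acceptance measurements of the steep-slope regimes use this
estimator; stationary processes (OU) need no correction.

### Peaks, width, harmonics

Peak width on the period scale is a resolution artefact, ΔT ≈ T²/(NΔt),
so long periods always show wide peaks; width carries little biological
information. The periodogram error term oscillates with period 1/D on
the frequency scale (D = study duration), so `local_maxima` keeps only
local maxima and merges any two closer than 1/D, keeping the higher.
The fundamental is the period of the global maximum. A non-fundamental
peak is labeled a harmonic when the fundamental period is an integer
multiple of its period (ratio within 0.05 of an integer, absolute — a
relative criterion would accept almost anything at high multiples) and
its power is below the fundamental's; any peak failing this marks the
signal multi-periodic, as does a short-period peak that dominates a
long-period one. Non-sinusoidal or non-elliptical repeated patterns
always generate harmonic series, so sub-multiple peaks should not be
over-interpreted.

### Multi-individual pooling

`combine_individuals` normalizes each individual's periodogram by its
mean power (individuals differ in movement variance), interpolates onto
the coarsest common frequency grid truncated to the shared band, and
averages with weights proportional to each individual's number of
recorded fixes. This is one reasonable pooling scheme, documented here
as the package's interpretation; shared periodic behavior reinforces
while individual noise averages down.

## 2. Movement models

Four aperiodic continuous-time Gaussian models serve as simulators,
background noise, and null hypotheses. All are Markov in a state of at
most (position, velocity), so simulation is *exact*: each step draws
from the closed-form transition distribution over the actual interval,
with no discretization error, at arbitrary (irregular) times.
Dimensions are independent with shared parameters.

| family | state | parameters | position ACF / character |
|---|---|---|---|
| BM  | x | σ (m²/s, diffusion rate) | Var grows σt; spectrum f⁻² |
| OU  | x | σ (m²), τ_pos | σ e^{−t/τ}; flat beyond period 2πτ_pos, f⁻² below |
| IOU | (x,v) | σ (m²/s), τ_vel | BM-like at long lags, ballistic below τ_vel; f⁻² → f⁻⁴ |
| OUF | (x,v) | σ (m²), τ_pos > τ_vel | σ(τ_p e^{−t/τ_p} − τ_v e^{−t/τ_v})/(τ_p−τ_v); 0 → 2 → 4 regimes |

Conventions. OU transition: x' = e^{−Δ/τ}x + N(0, σ(1−e^{−2Δ/τ})).
IOU is the integral of an OU velocity with stationary variance
η² = σ/(2τ_vel), chosen so that IOU matches BM with rate σ at lags well
beyond τ_vel; the joint (displacement, velocity) transition uses the
standard integrated-OU moments (e.g. Var(∫v | v₀) =
η²τ²(2θ − 3 + 4e^{−θ} − e^{−2θ}), θ = Δ/τ). OUF is the stationary
solution of the second-order SDE with characteristic rates 1/τ_pos and
1/τ_vel; its transition matrix is the matrix exponential (closed form
for distinct rates, the (1+rΔ)e^{−rΔ} limit for nearly equal ones) and
the innovation covariance follows from stationarity, Q = S − ΦSΦᵀ with
S = diag(σ, σ/(τ_pos τ_vel)). Initial conditions: BM and IOU positions
start at the origin (non-stationary); IOU and OUF velocities start at
their stationary distribution; OU and OUF positions at theirs. The
regime transitions of all spectra sit at period 2πτ, where the two
asymptotes of each Lorentzian factor intersect (`theoretical_lsp`
returns the two-sided continuous spectral densities; a gridded
periodogram's expectation is approximately that divided by Δt).

Periodic means. A deterministic periodic component can be added:
a per-dimension cosine, an ellipse across the first two dimensions, or a
constant-speed square circuit (`square_loop`) — a deliberately
non-elliptical pattern that activates harmonic series. Amplitude is in
meters, period in seconds, phase in radians.

Missingness. Record thinning comes in three forms: i.i.d. Bernoulli
retention (`p_keep`); deterministic duty cycling (`on_len` kept,
`off_len` dropped, by record index); and an autocorrelated
copy-or-redraw Markov chain — with probability `p_stay` a record copies
the previous one's retention state, otherwise it redraws
Bernoulli(p_keep), giving stationary retention p_keep with lag-one
retention autocorrelation p_stay. Optionally the redraw probability is
modulated over a cycle, p_keep + cycle_depth·cos(2πt/cycle_period),
emulating time-of-day-dependent fix failure (canopy, collar
malfunction). A purely Markov gap process is aperiodic and cannot
create a schedule peak; the cyclic modulation is what transfers a daily
line into the schedule spectrum, and it is the package's own
construction for reproducing that phenomenon.

## 3. Null-model likelihoods, fitting, selection

`gaussian_loglik` evaluates the exact Gaussian log-likelihood of a track
under any of the four families at arbitrary observation times, by a
forward state-space recursion. Because position is observed without
error, the filtered covariance collapses each step to a scalar latent
velocity variance; the gain sequence is computed by a cheap scalar
recursion (cut short once it reaches steady state on even grids, after
which the innovation recursion runs as a first-order linear filter at C
speed). Equivalence with dense-covariance multivariate-normal densities
is asserted for every family at N ≤ 100.

Conventions, chosen once and used throughout:

- Stationary families (OU, OUF) use the full likelihood including the
  stationary density of the first fix; the location mean is profiled
  out per dimension (innovations are linear in the mean, so its
  conditional MLE is closed-form via a parallel filter pass on the
  all-ones series).
- Non-stationary families (BM, IOU) condition on the first fix, which
  absorbs location; they have no mean parameter.
- AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with n the number of records and k
  counting the profiled means for OU/OUF (so BM:1, IOU:2, OU:2+K,
  OUF:3+K). Mixing a conditioned likelihood (BM, IOU) with a full one
  (OU, OUF) in one AICc comparison is a mild inconsistency shared by
  standard practice for these models; it is immaterial for the
  contrasts exercised here (all-family fits at n ≥ hundreds) but is
  noted as a limitation.

`fit_model` maximizes on log-scale parameters (variances and timescales
are positive and span decades) with Nelder-Mead from three fixed starts
(timescales at 0.1×, 1×, 10× the median interval; variance at the
sample variance, or the mean squared increment rate for the diffusive
families). BM has a closed-form MLE. The OUF autocovariance is symmetric
in (τ_pos, τ_vel), so the optimizer runs unconstrained and the result is
canonicalized to τ_pos > τ_vel. A fitted OU timescale below a third of
the median interval implies lag-one correlation under 0.05 — the
white-noise boundary, where the likelihood is flat in log τ — and is
reported with a warning. `select_model` fits all four families and
returns the lowest AICc, ties toward fewer parameters.

## 4. The periodicity test

The null hypothesis "no periodic pattern of space use" is the fitted
aperiodic model. `null_model_test` simulates n_sims tracks from it at
the *exact observed timestamps*, passes each through the identical
gridding and periodogram pipeline, reads off the power at the grid
frequency nearest 1/period (ties toward lower frequency), and reports
the P-value as the proportion of simulated values exceeding the
observed one — the raw proportion, granularity 1/n_sims, displayed as
"< 1/n_sims" when zero (no +1 correction; the display makes the
resolution explicit). Because the simulations inherit every irregularity
of the sampling schedule, artefactual power inflates null and observed
periodograms alike, which is what keeps the test near its nominal level
where white-noise tests fail in both directions: colored noise and
schedule artefacts each drive their rejection rate far above α.

Under the plug-in null (parameters re-fitted per dataset) the test's
type-I error at α = 0.05 is verified to sit inside the exact binomial
band in 200 replicates of an OU truth. Rejection probability rises
monotonically with injected periodic amplitude. For activity rather
than location periodicity, `activity_periodicity_test` applies the same
machinery to the 1-D movement-speed series (step length / interval,
stamped at interval midpoints) with an OU null fitted to the speeds;
speed is non-negative and hence non-Gaussian, so the OU null is an
approximation adequate for rhythm detection, not for speed modeling.

## 5. Schedule diagnostics

`rescale_zero_max` maps a periodogram to log₁₀ power shifted to a
maximum of exactly zero (zeros floored at the smallest positive value),
making data and schedule periodograms directly overlayable.
`artefact_flag` raises a suspicion when the schedule periodogram has a
local maximum within ±Δf of the target frequency whose prominence on
the log scale reaches 0.5 decades (both the window and the threshold are
parameters; the underlying procedure in the field is visual, and the
threshold quantifies "a clear coincident peak"). The flag indicates
*risk* of a false positive only: a genuine periodicity can sit on top of
an artefactual one, so the report always carries that caveat.

The end-to-end reconstruction in the acceptance suite mirrors the
classic collar-malfunction case: an aperiodic OUF track (σ = 10⁷ m²,
τ_pos = 7 d, τ_vel = 1 h, 3528 hourly fixes — a home-range-resident
grazer's scale) is resampled to the gap pattern of a daily-modulated
autocorrelated schedule (p_keep 0.5, p_stay 0.5, 24 h cycle, depth 0.5,
≈50% retained). The artefactual 24 h peak appears (≥1 decade above the
local continuum, where the complete track shows none), the flag fires,
and the null-model test — simulating on the inherited schedule — finds
it non-significant in the expected fraction of replicates.

## 6. What the synthetic data do and do not show

All tests run on synthetic tracks from the exact Gaussian simulators, so
they certify the estimators under the models' own assumptions:
stationary (or conditioned) Gaussian noise, correct family, no
measurement error, schedule independent of movement. Real telemetry
adds telemetry error (not modeled here; it whitens the high-frequency
end of the spectrum), behavioral non-stationarity (periodograms average
over it; regime shifts are out of scope), non-Gaussian step
distributions, and movement-dependent missingness (e.g. habitat-driven
fix failure violates the schedule-inheritance logic of the null test).
Passing tests therefore demonstrate correctness of the computations and
calibration under the stated conditions, not robustness to every field
condition.

Problem sizes used by the test and acceptance harnesses — 2¹⁴ hourly
fixes for the spectral-slope measurements (with 8–32 replicate
periodograms averaged to estimate expected spectra), N ≤ 2048 for
oracle certification, 400-fix tracks × 200 replicates for type-I
calibration, the 3528-fix schedule-artefact reconstruction — are the
package's choices balancing Monte-Carlo precision against a test suite
that runs in minutes.

## 7. Numerical details

- Denominator floor 10⁻¹²·W(0)²; below it, direct 2×2 normal-equation
  solve (minimum-norm via lstsq when singular).
- Combined power may dip to −ε from round-off; non-negativity is
  guaranteed only up to ~10⁻⁹ of the peak.
- Oracle normal equations: per-frequency 2×2 solve, vectorized over
  frequency chunks of 256; singular systems (det ≤ 10⁻¹²·trace²) fall
  back to minimum-norm, and an all-zero system yields zero power with a
  warning.
- Likelihood guards: non-finite or non-positive innovation variances
  return −∞ (the optimizer treats it as 10³⁰⁰).
- Geographic input is projected per individual onto a local tangent
  plane (equirectangular, centered at the median location;
  R = 6 371 008.8 m). Pairwise distance error is <0.5% within ~200 km
  extents; ocean-basin-scale tracks need a proper projection upstream.
- Timestamps are epoch seconds (UTC) internally; CLI durations accept
  s/m/h/d and `lunar` = 29.53059 d.
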