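# Methods

## Signal model and pre-processing

A walking bout is a tri-axial acceleration record x₁(t), x₂(t), x₃(t)
sampled at `fs` (default 80 Hz). All analysis is done on the vector
magnitude vm(t) = √(x₁² + x₂² + x₃²), which is invariant to device
orientation. The bout is cut into non-overlapping windows of `window_s`
seconds (default 10 s, τ = 800 samples); a trailing remainder shorter than
one window is discarded, since the windowed statistics below require
exactly τ samples.

Per window:

- **VMC** — the mean absolute deviation (1/τ)Σ|vm(u) − v̄m|, with the mean
  taken within the window. It summarizes movement energy and is invariant
  to constant offsets (gravity).
- **Spectrum** — |Σᵤ vm(u) h(u) e^(−i2πf·u/fs)| with Hanning weights
  h(u) = 0.5[1 − cos{2πu/(τ−1)}], evaluated on the physical frequency grid
  0, 0.1, …, 39.9 Hz. The transform is phrased in physical frequency
  (f·u/fs in the exponent) so the grid is honored exactly for any τ and fs;
  for the default 10 s/80 Hz configuration the grid coincides with the
  natural DFT bins and an FFT is used, with a direct complex-summation path
  for off-bin grids. Because the taper's period is τ−1 rather than τ, even
  a natural-bin evaluation leaks about 0.05% of a tone's magnitude into
  non-adjacent bins; its main lobe spans ±1 bin. Only magnitudes are used,
  so the window's absolute time origin is irrelevant.
- **Cadence** — the frequency of the largest spectral magnitude within
  1.2–4.0 Hz. Ties break to the lowest frequency, which favors the
  fundamental over harmonics. A window whose in-range spectrum is entirely
  non-finite raises a no-peak condition and is dropped from the subject's
  average (with a logged count); a subject with no usable window is an
  explicit failure.

Each window's spectrum is re-indexed on the order axis s = f/cadence and
linearly interpolated onto the common grid of 546 equally spaced points on
[0.3, 5.75] (spacing 0.01, the unique uniform grid matching both endpoints
and the count). For cadences above 39.9/5.75 ≈ 6.9 Hz — outside the search
range, so only reachable with non-default configuration — target orders
beyond the realigned support hold the last observed value, with a warning.
Window spectra are averaged pointwise, and the average is divided by its
value at the grid point nearest order 1.0, so every subject's spectrum
equals 1 at the fundamental and harmonic magnitudes read as ratios to it.
An alternative scaling by the local maximum near order 1 (`scale_method:
local_max`) is available; the two agree whenever the average spectrum peaks
on the nearest-to-1 grid point, which is the generic case after alignment.

## Regression model

On the order grid s₁…sₚ (p = 546, spacing Δs) the functional term is
discretized by a Riemann sum, ∫W(s)β(s)ds ≈ Δs Σⱼ w(sⱼ)β(sⱼ). The Δs
factor is absorbed into the spectrum matrix W at design assembly, so the
fitted β̂ is on the scale of the continuous coefficient function; the same
quadrature is used when the synthetic generator constructs responses, which
makes noiseless parameter recovery exact. Scalar predictors are the
intercept, a male indicator, mean cadence, and mean VMC; a constant scalar
column (e.g. a single-sex cohort) is dropped with a warning rather than
producing a singular design. Covariates are not standardized (a fit-time
choice users can apply upstream if desired).

The criterion ‖y − Xγ − Wβ‖² + λ‖Lβ‖² is minimized in closed form,

    (γ̂, β̂) = (XₒᵀXₒ + λ·blockdiag(0, LᵀL))⁻¹ Xₒᵀ y,   Xₒ = [X W],

penalizing only β. L = a(I − P_Q) + P_Q with P_Q = QQ⁺ the orthogonal
projection onto the harmonic basis: Gaussian densities centered at orders
0.5, 1.0, …, 5.5 with common sd 0.08 (order units). The sd default is set
by a near-orthogonality criterion — the largest off-diagonal normalized
inner product of Q's columns must stay below 0.05 (at sd 0.08 it is
~6·10⁻⁵) — so the 11 bells behave like separate harmonic detectors.
Columns are scaled to unit norm before the pseudo-inverse (P_Q is invariant
to column scaling; this only conditions the computation), and singular
values below 10⁻¹⁰ of the largest are treated as zero. LᵀL has eigenvalue
1 on span(Q) and a² on its complement, so a > 1 (default 2) shrinks
off-harmonic structure harder while β ∈ span(Q) incurs a plain ridge
penalty regardless of a.

## λ selection by REML

Substituting b = Lβ (L is invertible for a > 0, with closed-form inverse
(1/a)(I − P_Q) + P_Q) turns the criterion into the mixed model
y = Xγ + Zb + ε, Z = WL⁻¹, b ~ N(0, σ²_β I), ε ~ N(0, σ²_ε I), and
λ = σ²_ε/σ²_β. The restricted likelihood is profiled over log λ on
[10⁻⁶, 10⁶] after an eigendecomposition of ZZᵀ, which makes each evaluation
O(N²). Two numerical points matter:

- The profile can be **multimodal** (a heavy-shrinkage optimum coexists
  with a signal optimum), so selection first scans 49 log-spaced points and
  then refines the best bracket with a bounded one-dimensional optimizer.
  The profiled criterion was verified against a brute-force contrast-space
  (error-contrast) REML evaluation; the two agree up to the expected
  λ-independent constant.
- The residual quadratic form is computed as a weighted sum of squares of
  the GLS residual. The algebraically equivalent difference form
  yᵀH⁻¹y − vᵀM⁻¹v loses all significant digits at small λ and can go
  negative, manufacturing spurious minima.

The natural scale of λ is set by the eigenvalues of ZZᵀ, which are small
here (the Δs quadrature weight is inside W); the wide search interval
covers it with margin. When the data carry no functional signal the REML
estimate of σ²_β is boundary-valued for roughly half of realizations — the
classic mixture behavior of variance-component estimates under the null —
so λ hits the upper cap (reported with a warning) in some datasets and
settles at a large-but-finite spurious optimum in others; in either case
the fitted β̂ carries a small fraction of any real effect's energy.

## Confidence bands

Pointwise level-0.95 bands are β̂(sⱼ) ± z₀.₉₇₅·SE(sⱼ) with SE from the
mixed-model (Bayesian/ridge) covariance σ̂²_ε(XₒᵀXₒ + λLₒᵀLₒ)⁻¹ — the
standard choice for penalized-spline-type estimators; a frequentist
sandwich variant is available via `method="sandwich"`. The selected λ is
plugged in and its sampling variability ignored. No multiplicity
adjustment is made across grid points; `significant_multiples` simply
reports the basis centers (evaluated at the nearest grid point) where the
pointwise band excludes zero. These are the usual limitations of plug-in
Bayesian bands: their calibration is an *average* property. In the
package's Monte-Carlo experiment (200 cohorts of 46 subjects, true β a
span(Q) bump at order 2.5, residual sd 0.5) the coverage averaged over the
11 basis centers lands near 0.91 at nominal 0.95 — within the accepted
[0.90, 0.99] window — but it is very unevenly distributed: centers where
the truth is zero are covered essentially always, while the bump center
itself is under-covered because with p ≫ N the estimator recovers only the
component of β in the (penalty-weighted) row space of W, a bias the plug-in
covariance does not see.

## Synthetic cohorts

Each subject's bout is a harmonic comb on the vertical axis: a constant
gravity offset (1 g) plus sinusoids at integer multiples of the cadence
with random phases, default amplitudes (0.40, 0.20, 0.10, 0.06, 0.04) g,
and — by default in cohorts — half-integer multiples with amplitudes
(0.10, 0.06, 0.04, 0.02, 0.01) g, mimicking the stride (two-step)
periodicity of real gait. Amplitudes sum below the offset, so the
noiseless vm is |offset + comb| = offset + comb, exactly periodic at the
cadence. Independent Gaussian noise (default sd 0.05 g) is added to all
three axes. Cadences are drawn per subject from Uniform(1.6, 2.5) Hz and
amplitudes are jittered by Uniform(0.7, 1.3) factors, which is what
creates between-subject variation in harmonic ratios for the regression to
detect. Bouts default to 60 s (six windows) — long enough for stable
averages, short enough that a hundred-cohort simulation study runs in
seconds; window-to-window variation within a subject comes only from the
noise, not from amplitude drift.

Responses use γ = (65, −2, −5, 10) (an age-like scale) and, in the
pipeline's default truth, β a Gaussian bump of height 50 at order 2.5 —
a half-integer multiple, which is why the generator's half-harmonics
default on: without energy at half-integer orders the functional term
would be degenerate at the bump. Residual sd defaults to 0.5, putting the
functional contribution (sd ≈ 0.12 across subjects) in the
weak-but-present regime. One global seed expands into per-subject
substreams plus a cohort-level stream, so cohorts are bit-reproducible and
stable under changes of n_subjects prefix.

What the generator does **not** emulate: biomechanical asymmetry (left/
right step differences beyond a stationary half-harmonic), amplitude drift
and fatigue within a bout, non-walking segments, device orientation
changes, or heteroscedastic device noise. Passing tests therefore
demonstrate the correctness of the pipeline's transforms and estimator
contracts, not robustness to free-living data.

## Problem sizes and numerical defaults

The simulation studies shipped with the package use: 100-subject cohorts
for the recovery noise ladder (residual sd 0.5 / 0.1 / 0.02), 200
46-subject cohorts for band calibration, and 50 random 800-sample windows
for the transform oracle. Tolerances: transform vs. brute-force summation
10⁻⁹ relative; estimator vs. generic numerical minimizer 10⁻⁶; penalty
eigenvalues 10⁻⁶; projection idempotency 10⁻⁸. The λ search interval is
[10⁻⁶, 10⁶] with the REML profile scanned at 49 points before refinement.
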