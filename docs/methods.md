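# Methods

## The problem

Hippocampal local field potentials (LFPs) carry oscillations — theta
(4–12 Hz), slow gamma (25–55 Hz), fast gamma (65–100 Hz), sharp-wave
ripples (SWR, 140–200 Hz) — whose power and event statistics are usually
quantified with Fourier or wavelet methods.  Those methods decompose the
signal into sinusoids and say nothing about its *dynamical geometry*: is
the local network sitting at a fixed point, cycling a periodic orbit,
winding a torus, or wandering a higher-dimensional (possibly fractal)
attractor?  This package estimates that geometry directly from a short
epoch of a single channel, and pairs it with the conventional
Morlet-wavelet band statistics so the two descriptions can be compared on
the same data.

## The estimation chain

Given an epoch `x[0..L-1]` sampled at `fs` (default 2500 samples at
1000 Hz, so samples and milliseconds are interchangeable):

1. **Delay embedding.**  Rows `(x[i], x[i+τ], …, x[i+(m−1)τ])` with `m = 8`
   delay coordinates and lag `τ = 1` sample form a point cloud in R⁸ whose
   topology matches the underlying attractor for generic observables.  For
   the composite two-stream condition (4–100 Hz and SWR filtered copies of
   the same epoch) the streams are embedded separately and concatenated
   column-wise — both are measurements of the same dynamic, so the joint
   cloud lives in R¹⁶ over the same time index.

2. **Self-tuning diffusion operator.**  Each point gets a local bandwidth
   `σᵢ` = distance to its `k`-th nearest neighbor (`k = 32`).  Affinities
   `w_ij = exp(−‖xᵢ−xⱼ‖² / σᵢσⱼ)` are kept out to `2√(σᵢσⱼ)` (where the
   kernel reaches e⁻⁴; the symmetrized kNN edges are always kept), then
   density-normalized with exponent α = 1 — the Laplace–Beltrami limit, so
   the spectrum reflects geometry rather than sampling density, which the
   counting law requires — and row-normalized into a Markov operator.
   Eigenpairs come from the symmetric conjugate form with a fixed starting
   vector, so runs are deterministic.

3. **Heat-semigroup inversion.**  Markov eigenvalues `μ` map to Laplacian
   eigenvalues `λ = −log(μ)/ε` with `ε = median(σᵢ²)/4`.  The −log form is
   exact for the heat semigroup and better conditioned than `(1−μ)/ε` for
   `μ` near 1.  The `/4` is not cosmetic: `exp(−d²/σ²)` equals the heat
   kernel `exp(−d²/4t)` at `t = σ²/4`, and getting this time scale right is
   what puts the fitted volume in correct units.

4. **Weyl counting fit.**  Weyl's law `N(λ) ≈ ω_d·V·λ^{d/2}/(2π)^d` is a
   power law, so `log N` vs `log λ` is fit by least squares over the
   contiguous window (≥ 20 eigenvalues, starting past the first nontrivial
   one) that maximizes R²; ties prefer the longer window, then the earlier
   start.  Slope gives `d = 2·slope`; the intercept gives the raw volume.
   Low modes are boundary/curvature-contaminated and high modes are
   kernel-resolution-limited, which is why the window is searched rather
   than fixed.

5. **Volume calibration.**  The raw Weyl volume is in embedding-space
   units.  Dividing by the *median* per-step displacement of the embedded
   trajectory, raised to the power `d`, converts it to timesteps, so a
   period-P orbit reads `Vol ≈ P` — volume is the higher-dimensional
   analog of a quasi-period.  The median (not the mean) matches the median
   used for `ε`; with a variable-speed orbit the self-tuning bandwidth
   tracks the local point spacing, and WKB homogenization of the resulting
   variable-coefficient operator shows the fitted circumference comes out
   in *median*-spacing units.  Using the mean here leaves a systematic
   bias of order the spread of the speed distribution (≈ +10 % for an
   eccentric delay-embedded sine).

### Numerical guards

- **Exactly periodic trajectories.**  A noiseless sine with period P ≤
  L/k revisits embedded points to machine precision, so the k-th-neighbor
  distance collapses to ~0.  The bandwidth is floored at the first
  *distinct* neighbor distance, and the neighbor search widens (up to a
  cap of 512) until the 2σ support is covered.  No points are merged or
  dropped.
- **Resolution rule.**  If even the slowest nontrivial mode decays at the
  kernel's own time scale (`μ₁ < 0.98`, i.e. the first "wavelength" is
  within a factor of a few of the bandwidth), the cloud has no extended
  structure the kernel can resolve and the epoch is classified as a point
  attractor: dimension 0, volume 0, converged.  This is what makes a
  tightly jittered fixed point read as 0: its delay cloud is an isotropic
  noise ball whose every mode lives at the kernel scale.  The flip side is
  documented below under limitations.
- **Semigroup trust region.**  Modes with `−log μ > 0.5` carry visible
  discretization bias in the inversion (the discrete dispersion relation
  bends away from quadratic), so the fit prefers the shallow part of the
  spectrum; when fewer than a window's worth of shallow modes exist, the
  shallowest 20 are used so noisy epochs still produce a flagged estimate
  rather than nothing.
- **Quality control.**  `volume > 250` (strictly) timesteps is flagged
  `discarded` — a tenth of the 2500-sample window is the longest
  quasi-period the window can certify.  Estimation failures at any stage
  (too-short signals, disconnected graphs, degenerate spectra) become
  flagged rows with an error string, never exceptions across a batch.

### Convergence contract

`converged` means: the eigensolver met its tolerance, the affinity graph
is connected, and the counting fit achieved R² ≥ 0.8 (or the resolution
rule fired, which is a definite classification, not a failure).

## Filters

Ten named conditions: no filter; theta 4–12; slow gamma 25–55; fast gamma
65–100; SWR 140–200; 20 Hz HP; 100 Hz LP; 100 Hz HP; 100–135 Hz; and the
composite 4–100 Hz + SWR pair.  (Theta is 4–12 Hz here; 6–12 Hz also
circulates in the literature.)  All are 4th-order Butterworth sections run
forward-backward — zero phase, effective 8th order, ≥ 40 dB one octave
outside each band.  Zero phase matters because phase distortion would warp
the delay-embedded geometry that everything downstream measures.  Stated
edges are −3 dB corners.  Epochs are reflect-padded by one
impulse-response length before filtering; the first/last impulse-response
length of a short epoch still carries some edge ringing, which is why
attenuation is specified in steady state.

## Wavelet comparator

Complex Morlet wavelets at 1 Hz steps from 1 to 101 Hz (97–101 Hz exceed
some conventions; the grid is configurable), 7 cycles, Gaussian time-sd
`n_cycles/(2πf)`.  Power is the squared magnitude of the convolution.
Each frequency row is z-scored over the *trial* (not the epoch), which
flattens the 1/f spectrum and absorbs across-trial recording differences.
Band summaries use the band's integer-Hz rows: average z-power over the
epoch window, and events = maximal contiguous runs of the band-mean z
series with |z| > 1.95 (the two-sided 5 % point of a standard normal;
per-sample counting is available as `event_mode="samples"`).  Mean (not
max) over band rows mirrors the "average power" convention; |z| is used
even though power z-scores are right-skewed, so negative excursions can
in principle count.  The SWR band is excluded from wavelet summaries
because the grid tops out near 100 Hz.

## Statistics

Dimension/Volume and band summaries are compared across age × drug ×
location (or alternation, dropping outer-arm epochs) by three-way ANOVA
with Type-II sums of squares: the discard rule unbalances cells, and
Type II reduces exactly to the classical decomposition when balanced (a
unit test checks this against directly computed sums of squares).
Inestimable effects are reported as such, never invented.  Collapsed
across factors, the ten filter conditions are compared by one-way ANOVA
(df between = 9) with Tukey HSD post hocs; adjusted p's use the
studentized range with Tukey–Kramer standard errors, interpolated from
the reference table away from decisions and computed exactly near the
0.05 boundary and below 10⁻³ (so the ≤ 0.05 / < 0.01 / < 0.0001 star
tiers are resolved).  Filter-property regressions put each filter at its
band's central tendency or range, substituting the Nyquist frequency
(fs/2 = 500 Hz) for missing upper bounds and 0 for missing lower bounds;
the composite condition spans the union of its components (4–200 Hz).

## Synthetic study conditions

The generators define the conditions every claim is tested under:

- `gen_fixed_point`: constant level 1.0 + Gaussian jitter (sd 10⁻³) —
  ground-truth dimension 0.
- `gen_limit_cycle`: unit sine, default 10 Hz at 1000 Hz (period 100
  samples), random initial phase per seed — dimension 1, period = fs/freq.
- `gen_torus`: two unit sines at 7 and 7√2 Hz (irrational ratio by
  construction; commensurate requests are flagged) — dimension 2.
  10000 samples are used for the torus: a surface needs more cloud than
  a curve before its second dimension is resolvable.
- `gen_lorenz`: RK4 at dt = 0.01 in the classic chaotic regime
  (σ=10, ρ=28, β=8/3), ≥ 1000-step transient discard, x-coordinate only
  (the single-electrode premise) — fractal dimension ≈ 2.06 in the
  literature, held here only to a loose (1, 3) band.
- `gen_lfp_composite`: 1/f background plus raised-cosine-enveloped tone
  bursts at band centers with a recorded schedule.  Burst height `z_amp`
  is calibrated to the *post-z-scoring* band-mean power scale by a short
  fixed-point iteration, because z-scoring power over the trial is
  self-normalizing: a burst inflates its own column's sd, and a dense
  schedule cannot reach arbitrarily high z no matter the amplitude.  The
  calibration makes `z_amp = 4` mean "an unambiguous event at the 1.95
  threshold" whenever the schedule is sparse relative to the trial.

What these fixtures do *not* emulate: spike contamination, non-stationary
state switches within an epoch, electrode drift, line noise, or any
biophysical network mechanism.  Passing tests certify the estimator's
geometry and calibration on clean dynamics, not its behavior on every
pathology of real recordings.

## Problem sizes

The validation suite runs each canonical geometry over 20 seeds (2500
samples for fixed point and limit cycle, 10000 for the torus), the
parameter-robustness grid over k ∈ {24, 32, 40} × m ∈ {6, 8, 10}, the
volume calibration at periods {50, 100, 200} × 3 seeds, the event
threshold at 10⁶ Monte-Carlo samples, and the statistical calibrations at
2000 null replicates each.

## Known limitations

- The resolution rule makes dimension non-monotone at extreme noise: on a
  noisy limit cycle the estimate rises with noise sd (≈ 1.0 → 1.6 over
  sd 0–0.2 at unit amplitude) and then collapses to the point-attractor
  classification once noise drowns all resolvable structure (sd ≈ 0.3+).
  Monotonicity is therefore only asserted on the moderate-noise regime.
- A 2500-sample epoch cannot certify high-dimensional structure; reliable
  characterization of d ≥ 4 needs hundreds of quasi-periods.  Estimates
  with volume > 250 are flagged for exactly this reason.
- The torus estimate at 10⁴ points reads ≈ 1.8 rather than 2.0 —
  curvature and finite kernel resolution bias the slope low; the rounded
  dimension is the deliverable at these sizes.
- An alternative reading of Volume — explicitly averaging detected cycle
  lengths rather than taking the Weyl intercept — exists in the
  literature's discussion of the method.  The Weyl route with timestep
  calibration is implemented here because it generalizes beyond d = 1;
  the two agree on periodic fixtures by the calibration property.
- Tukey p-values between 0.12 and 0.9 come from table interpolation and
  can deviate from the exact studentized-range tail by ~0.02; all
  significance decisions and reported tiers use exact evaluations.
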