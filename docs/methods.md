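# Methods

## Acquisition model

The package models a time-gated SPAD acquisition: a pulsed laser (sub-120 ps
pulses, 20 MHz) illuminates the sample while the camera opens a wide
detection gate (10.8 ns) whose delay from the laser sync is swept in steps
of `dt = 17.857 ps` across `n_steps = 1400` positions, a 25 ns window. Each
gate position accumulates 256 one-bit frames (4 μs exposure each), so raw
counts live in [0, 256] — 8-bit images. A time scan is the resulting
rows × cols × steps stack; a temporal profile (TP) is one pixel's or ROI's
trace along the gate axis. One gate step corresponds to ~2.7 mm of air
round trip, which sets the scale of the timing precision needed: sub-mm
depth resolution requires sub-gate-step TOF estimates, i.e. fitting, not
peak-picking.

## Forward model and its discretization

A TP is modelled as `IRF * H_medium` for reflectance and
`IRF * H_medium * exp(−t/τ)` for fluorescence, with `H_medium` a Gaussian
of amplitude `A`, mean `Δ_tissue` (relative TOF) and sd `σ` (dispersion).
The delay through air is absorbed into the IRF, which is measured (or
simulated) off a Lambertian surface and convolved forward; the package never
deconvolves the IRF from data.

Discretization: the Gaussian — and, with the lifetime term, the
Gaussian–exponential product, which is an exponentially modified Gaussian
(EMG) — is sampled **analytically** on the gate grid (EMG evaluated in the
`erfcx` form, piecewise-switched to the pure-decay asymptote for far-tail
arguments to avoid overflow) over a symmetric grid padded to 3× the axis
length, scaled by `A·dt`, and convolved with the IRF by FFT before cropping
back to the axis. Sampling the analytic kernel rather than convolving two
discretely sampled kernels matters: a discrete exponential kernel carries a
left-endpoint Riemann error of order `dt/2τ` (~1 %), while the sampled EMG
agrees with the continuous model to machine precision for `σ ≳ 2·dt`
(Poisson-summation argument: the EMG's Fourier transform at `2π/dt` is
`exp(−σ²(2π/dt)²/2)`-small). A warning is raised when `σ < dt/2`, where the
grid genuinely under-resolves the kernel.

The causal exponential has support `t ≥ 0` with its edge at the kernel
origin, and is unit-area, so the fluorescence convolution conserves total
expected photons up to axis cropping.

## Photon statistics

Each gate accumulates `N` binary frames; a binary frame fires with
probability `1 − exp(−λ/N)` for expected flux `λ` per gate, so detected
counts are `Binomial(N, 1 − exp(−λ/N))`: Poisson at low flux, pile-up
saturated (clamped at `N`) at high flux — the sensor's linear-range ceiling.
Dark counts add `rate × exposure × N` expected counts per gate (default
100 cps). Randomness is counter-based: pixel `(seed, pixel_key)` keys an
independent Philox stream, so identical seeds give bit-identical stacks and
partial re-simulation is reproducible. An aggregated superpixel (8×8 binned)
is simulated exactly as a single detector with `64·N` frames, since a sum of
i.i.d. binomials with equal `p` is binomial.

## Synthetic scenes

`PhantomScene` places fluorescent inclusions (per-pixel depth, NaN =
background) in a homogeneous scattering medium indexed by Intralipid
concentration `IL`. Ground-truth maps, chosen once for physical
plausibility and recorded with every simulated scan:

| quantity | default | rationale |
|---|---|---|
| `μs′(IL)` | `1.0 · IL` mm⁻¹ | Intralipid ≈ 1 mm⁻¹ per % near 650 nm |
| `μ_a` | 0.005 mm⁻¹ | weakly absorbing aqueous phantom |
| `k_fluo(IL)` | `12·IL + 15` ps/mm | ballistic round trip alone is ~9 ps/mm; scattering lengthens the effective path, more so at higher `IL` |
| `c_fluo` | 20 ps | geometry offset of the setup |
| `σ(z)` | `120 + 25·μs′·z` ps | dispersion grows with depth and scattering; the growth law is made explicit here because real acquisitions show it but no parameterization exists |
| reflectance kernel | `Δ = 5·μs′` ps, `σ = 80 + 15·μs′` ps | surface return broadens and shifts mildly with scattering |
| surface amplitude | `A·exp(−2·μ_eff·z)` | diffuse round-trip attenuation |
| τ | 0.7 ns | externally measured dye lifetime |
| IRF | Gaussian, 120 ps FWHM, peak a few σ into the axis | the instrument only bounds the pulse width; Gaussian is this package's modelling choice |
| IRF acquisition amplitude | scene amplitude / 5 | the operator attenuates the IRF measurement to stay in the linear range |

What the simulator does **not** emulate: radiative-transfer/Monte-Carlo
photon transport (the σ- and TOF-growth laws are phenomenological linear
maps, not derived), spatial blur of deep inclusions, laser jitter spectra,
rolling-shutter row timing, hot pixels, and autofluorescence. Passing tests
therefore demonstrate that the *computational chain* is correct and
statistically efficient under the stated noise model — not that the
phenomenological constants match any particular instrument or tissue.

## Profile processing

Normalization maps a TP onto ~[0, 1] using the mean of the `n_top` most
intense samples (ties broken toward earlier indices) as maximum and the mean
of the last `n_tail` samples as baseline (defaults 200/200 on full-length
scans; tests use 20/50 on 512-step axes). Smoothing is a centred moving
average (default 35 samples = 625 ps) with symmetric shrinking windows at
the edges so pulse tails are not biased; smoothing is cosmetic and fitting
runs on unsmoothed profiles. Cross-acquisition alignment fits a line to the
reflectance rising edge between normalized levels 0.2 and 0.8 (span
configurable; the fitted band is a design choice) and shifts the
fluorescence TP by the difference of zero crossings, sub-sample shifts by
linear interpolation. The scattering surrogate `Δ_refl` is the linearly
interpolated time at which the normalized reflectance pulse crosses 2 % of
maximum; rising or falling edge and both the alignment and comparison levels
are parameters, since the falling edge carries the scattering signature.

## Fitting

Bounded trust-region nonlinear least squares (`scipy.optimize.least_squares`)
over `(A, Δ_tissue, σ)` with `τ` fixed; tolerances 1e-8 (cost/step/gradient),
bounds `A > 0`, `σ ∈ [dt/2, span/4]`, `Δ` within a quarter-span of the axis.
Initialization is data-driven: `Δ0` from the lag of the peak
cross-correlation with the IRF (minus `τ/2` for fluorescence), `σ0` from the
excess FWHM over the IRF, `A0` from the area ratio. Fits run on normalized
profiles by default (raw behind a flag). Non-convergence returns
`converged=False` with diagnostics; a converged fit with `R² < 0.5` is
treated as unreliable (and masked in maps) — signal-free profiles routinely
"converge" to meaningless optima.

## Calibration and inversion

All calibration relations are ordinary least-squares lines. `c_fluo`, in
principle a pure geometry constant, is estimated as the mean intercept of
the per-IL depth regressions. The chain's pivot variable is the Intralipid
concentration; for media that are not Intralipid it acts as a latent
scattering index that only ever appears between two linear maps, so its
absolute scale cancels. Depth inversion guards the inferred slope: a
non-positive `k_fluo` (scattering feature outside the calibrated range)
yields an invalid estimate with a reason, never an exception; depths outside
the calibrated span (default 1–5 mm, matching the practice of excluding a
poorly controlled first millimetre) are flagged as extrapolation. Intensity
correction inverts `I = L·exp(−2 μ_eff z)`; the alternative
`exp(−μ_eff²·z)` reading of the attenuation exponent is selectable
(`convention="squared"`), the round-trip form being the physically standard
choice.

## Maps

Binning sums non-overlapping blocks (8×8 by default; 256×472 → 32×59),
preserving photon statistics; trailing partial blocks are dropped. Each
superpixel is fitted against its own IRF superpixel, absorbing pixel timing
skew and illumination non-uniformity. Map cleaning: intensity masking
(absolute threshold, or SNR-style against a designated background region,
default 2 background-sd above the background mean) and mask-aware Gaussian
smoothing (normalized convolution, default σ = 1 superpixel) that never
drags masked holes into valid regions. Topology re-references the TOF map so
its minimum valid value is zero — the shortest inclusion-surface distance
defines the surface — before inversion, yielding relative depth.

## Problem sizes and determinism

Tests and the acceptance script run on 512-step axes (9.1 ns), single
superpixels or small scene grids (≤ 24×32), and 5-replicate averaging per
measurement, mirroring the five-TP acquisition protocol. These sizes keep
the full suite under a minute while leaving every statistical margin (e.g.
median TOF error ~1.6 ps against the 17.857 ps gate step) wide. All
stochastic stages derive their streams from a single integer seed.

## Known limitations

* The linear TOF–depth and dispersion laws are simulator ground truth, not
  physics; against real tissue the chain must be recalibrated and the
  homogeneity assumption (optical properties constant along z) can fail.
* `Δ_refl` and `μs′` characterize the bulk surface medium only; layered
  media violate the single-scattering-index assumption.
* Fitting assumes a mono-exponential lifetime and a known `τ`; a wrong `τ`
  biases `Δ_tissue` (positively, if `τ` is underestimated).
* No spatial deconvolution: lateral blur of deep inclusions is untouched.
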