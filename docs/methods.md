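# Methods

This note documents the models, numerical choices and study designs behind
`fdfwi`, in the spirit of a solver manual: what is computed, under which
assumptions, and what the shipped tests do and do not demonstrate.

## Physical model

Acoustic propagation is modeled per frequency by the heterogeneous 2-D
Helmholtz equation

```
(∇² + k(x)²) u(x) = −q δ(x − x_s),      k(x) = ω / c(x) + i α(x, f),
```

with `c(x)` the sound-speed map (m/s) and `α` the attenuation in Np/m.
Attenuation is parameterized by its power-law slope `a(x)` in dB/(cm·MHz)
and assumed linear in frequency — the convention in ring-array ultrasound
tomography — so `α = a · f_MHz · 100 · ln(10)/20` Np/m. No dispersion
correction of the real part accompanies the loss term (shear, nonlinearity
and 3-D out-of-plane spreading are all outside the model). Fields follow the
`exp(−iωt)` convention: outgoing waves carry phase `exp(+ikr)` and the
free-space point-source field is `(i/4) H₀⁽¹⁾(kr)`.

### Discretization

Second-order 5-point Laplacian on a regular grid with pixel-center
registration. The PML (all four sides, default 20 pixels) uses complex
coordinate stretching `s = 1 + iσ/ω` with a quadratic σ profile; the operator
is assembled in the symmetrized form `∂x(s_y/s_x ∂x) + ∂y(s_x/s_y ∂y) +
s_x s_y k²`, which keeps the matrix complex symmetric. Consequences: discrete
source/receiver reciprocity holds to solver precision, and adjoint solves
reuse the same LU factors without transposition. The default PML amplitude
(`max_absorption = 15`) gives a measured boundary reflection of ~5·10⁻⁵
against a double-size reference domain.

The 5-point stencil's numerical phase velocity error is
`(kh)²(cos⁴θ + sin⁴θ)/24` at propagation angle θ. We multiply `k²` by
`1 − 0.75 (k_r h)²/12` (with `k_r = ω/c`), canceling the angular mean and
leaving a residual bounded by `(kh)²/96`. Measured free-space accuracy: 3.1%
relative L2 against the analytic Green's function over a 5–7 wavelength
annulus at 20 points per wavelength (ppw), 1.4% at 30 ppw, converging at
second order (error ratio ≈ 4 per halving of spacing). The correction enters
the adjoint-state derivative `∂k²_eff/∂c` analytically, so gradients remain
exact for the discrete objective.

One sparse LU factorization (SuperLU) is computed per (model, frequency) and
reused for all transmits and all adjoint solves; each additional source costs
a back-substitution. Point sources are injected at the nearest pixel with
amplitude `−q/h²`; observed-data synthesis instead spreads the delta over the
four bracketing pixels (see inverse-crime safeguards).

## Frequency differencing

For each channel, the difference-frequency signal is the normalized
cross-frequency autocorrelation over the recorded band,

```
p̄(Δf) = Σ_k p(f_k + Δf) p*(f_k) / Σ_k |p(f_k)|²,
```

a uniform Riemann sum in which the common frequency step cancels, so no
quadrature weights are applied. Both sums run over the same sample set; with
this choice the linear-phase identity `p(f) = e^{i2πfτ} ⇒ p̄(Δf) =
e^{i2πΔfτ}` holds exactly (to rounding), which is the method's foundation
and is asserted at 1e−12 in the tests. Two band-edge conventions are
implemented, since the continuum formula is ambiguous about reading
`p(f + Δf)` beyond the band: `truncate` (default) restricts `f_k` to
`[f_low, f_high − Δf]`; `extend` uses the full band whenever recorded samples
above `f_high` exist. Δf values must be integer multiples of the band's
sampling step — interpolation would corrupt the phase relation and is
refused rather than silently applied. Normalization is per (transmit,
receiver) channel; no additional power weighting across the band is applied.

Difference frequencies above `f_low/2` stretch the `Δf ≪ f_low` regime and
warn; published protocols reach Δf ≈ `f_low`, so this is deliberately not an
error.

## Inversion

The per-frequency misfit is `E = ½ Σ_i ‖a_i R u_i − p_obs,i‖²` over
transmits, with bilinear receiver sampling `R`, and `a_i` a per-transmit
complex source amplitude re-fit by least squares (`a_i = ⟨sim, obs⟩/‖sim‖²`)
before every gradient — variable projection, so the reduced-objective
gradient equals the fixed-source adjoint gradient. Receivers within ±5
element indices of the transmitter (circularly) are masked: the coincident
channel is singular for point sources and near-neighbors are dominated by it.

Gradients are discretize-then-optimize adjoint state. With the complex
symmetric system `A`, the adjoint solve is `A w_i = a_i Rᵀ conj(r_i)` and
`∂E/∂m_j = −Re(Σ_i u_ij w_ij · ∂D_j/∂m_j)`, where `D` is the diagonal mass
term including PML stretch and the dispersion-correction factor. Verified
against central finite differences to better than 1e−5 relative (both
parameters) on randomized models; the test gate is 1e−3.

Updates are nonlinear Polak–Ribière⁺ conjugate gradient, restarted on
non-descent, with illumination preconditioning `g / (Σ_i |u_i|² + ε)`
(configurable off), updates restricted to the ring interior, and a parabolic
line search seeded by the analytic directional derivative with a backtracking
cap of 5; only misfit-decreasing steps are accepted, so the objective is
nonincreasing within each block. Sound speed is clipped to [1300, 1800] m/s
by default; attenuation to [0, 10] dB/(cm·MHz). The first line-search trial
caps the pointwise update at 10 m/s (0.05 dB/(cm·MHz) for attenuation); the
parabolic step may extend this threefold.

Protocols: pass 1 sweeps its frequency list ascending, sound speed only;
pass 2 sweeps a list staggered half a step above pass 1, alternating a
sound-speed block then an attenuation block per frequency (the ordering
within a frequency is a documented choice; the alternative is symmetric).
Each block runs 3 CG iterations. The frequency-difference kickstart is a
single ascending sweep over the Δf grid, sound speed only, 2 CG iterations
per frequency, never updating attenuation. The engine is one code path: it
never inspects data provenance, so the difference-frequency objective is
structurally identical to the measured-data objective.

The inversion grid is fixed per run, sized for the highest frequency in the
run at ~10 ppw (a multiscale grid-per-frequency scheme would be cheaper but
complicates bookkeeping; at these problem sizes the single grid is fine).
The kickstart runs on its own coarser grid sized for the top difference
frequency, then is resampled bilinearly onto the two-pass grid. Because the
kickstart is only trusted at low wavenumbers, it is smoothed with a Gaussian
of a quarter of the shortest kickstart wavelength before use as a starting
model.

## Synthetic data and the inverse-crime safeguard

Observed spectra are synthesized by the same Helmholtz machinery but on a
grid ≥1.5× finer than any inversion grid and with bilinear (not
nearest-pixel) source injection, so the inversion never sees data generated
by its own discrete operator. Synthesis is noise-free by default, matching
the study design this package mirrors; complex Gaussian noise at a configured
SNR is available for robustness experiments. Spectra are weighted by a
Gaussian pulse amplitude spectrum parameterized by its −6 dB fractional
bandwidth (datasheet convention); since source amplitudes are re-estimated
per transmit and frequency, the pulse shape only matters for SNR studies.

The phantom is the canonical 10-ellipse modified Shepp-Logan pattern,
evaluated analytically at pixel centers (no raster resampling) and mapped
affinely onto properties: `c = c_bg + c_contrast·I`, `a = a_bg +
a_contrast·I` with intensity `I ∈ [0, 1]`. Property ranges are configurable;
there is no canonical acoustic assignment for this pattern.

### Desk-scale study conditions

The shipped cycle-skipping demonstration uses a 6 cm, 64-element ring;
phantom radius 2.2 cm; water background 1480 m/s; sound-speed contrast scale
450 m/s (chosen so the bulk time-of-flight error from the homogeneous start
is ~1.1 cycles at the lowest directly-inverted frequency — firmly in the
cycle-skipping regime); attenuation contrast 0.3 dB/(cm·MHz). The recorded
band is 0.45–0.80 MHz in 25 kHz steps; the two-pass schedules are
0.45:0.05:0.60 and 0.475:0.05:0.625 MHz; frequency differencing synthesizes
0.05–0.225 MHz in 25 kHz steps. Data are simulated at 12 ppw at the band top
(0.15 mm grid) and inverted at 10 ppw at 0.625 MHz (0.24 mm grid): a 1.5×
finer data grid plus a different source-injection stencil, per the
inverse-crime safeguard. These sizes keep the full three-reconstruction
comparison to minutes on one core. Relative to the full-scale protocol this
scaling has coarser resolution in ring radii (the ring is 4 wavelengths
across at the lowest Δf, versus ~22 at full scale), so kickstart models are
blurrier relative to the anatomy than their full-scale counterparts; the
qualitative ordering — homogeneous start cycle-skips, FD start does not — is
what the desk scale preserves, not the printed full-scale metric values.

The parameter-recovery study replaces the phantom with a +2% Gaussian
sound-speed inclusion (σ = 8 mm) — no cycle skipping at that contrast — and
checks that the kickstart alone recovers the inclusion's mean sound speed to
well under 1%.

## Metrics

RMSE in m/s over the evaluation region; PSNR = 20·log₁₀(peak/RMSE) with the
peak defaulting to the truth's dynamic range over the region (no universal
convention exists for physical-unit images; the choice is recorded in every
report); SSIM with the standard 11×11 Gaussian window, σ = 1.5, K₁ = 0.01,
K₂ = 0.03, dynamic range from the truth map. The default region is the
largest axis-aligned square inscribed in the ring interior.

## What the tests show — and what they don't

The suite verifies: exactness of frequency differencing on linear-phase
signals; forward-solver accuracy against the analytic Green's function with
second-order convergence; PML efficacy; discrete reciprocity; adjoint
gradients against finite differences; monotone objectives; recovery of a
low-contrast inclusion through the full FD pipeline; and the desk-scale
ordering FD-started > homogeneous-started under cycle-skipping conditions
with the inverse-crime safeguard on. They do not demonstrate performance on
measured transducer data (element directivity, electromechanical response,
3-D spreading, and real noise are unmodeled), nor the full-scale 512-element
protocol, which runs for hours and whose printed metrics additionally depend
on unpublished phantom property ranges and PSNR conventions.

## Known limitations

* 2-D physics; no out-of-plane spreading correction when applied to real
  ring data.
* Attenuation is linear-in-frequency with no associated velocity dispersion.
* The FD kickstart inherits the linear-phase assumption; strong scatterers
  (bone-like contrasts) displace energy into halo artifacts, as expected
  from the method's premise.
* Direct sparse factorization bounds problem sizes to roughly 1M unknowns
  per frequency in 8 GB of memory; full-scale 512-element runs at MHz
  frequencies are hours-long on one core.
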