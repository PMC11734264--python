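# fdfwi — frequency-difference kickstarted FWI for ring-array ultrasound tomography

Full-waveform inversion (FWI) reconstructs quantitative sound-speed and
attenuation maps from through-transmission ultrasound, but it needs
low-frequency data: if the simulated waveform is more than half a cycle off
the measured one at the lowest inverted frequency, the model updates in the
wrong direction (*cycle skipping*) and the reconstruction locks into
artifacts. Clinical ring transducers are driven at high frequencies for
B-mode resolution, so that low-frequency content is often simply not
recorded.

`fdfwi` implements the frequency-differencing remedy, end to end, in 2-D:

1. **Simulate** (or load) transmission channel spectra `p_obs,i(ω)` for every
   single-element transmit `i` on a ring array, through heterogeneous
   sound-speed/attenuation maps, with a frequency-domain Helmholtz solver
   (PML boundaries, sparse direct factorization shared across transmits).
2. **Extrapolate** low-frequency channel data from the recorded band
   `[ω_lo, ω_hi]` by the normalized cross-frequency product

   ```
   p̄_obs,i(Δω) = Σ_k p_obs,i(ω_k + Δω) ⊙ p*_obs,i(ω_k)
                 ─────────────────────────────────────
                 Σ_k p_obs,i(ω_k) ⊙ p*_obs,i(ω_k)
   ```

   which is exact for linear-phase (pure time-of-flight) channels:
   `p ∝ e^{jωτᵢ}` gives `p̄ = e^{jΔωτᵢ}`.
3. **Invert.** The per-frequency misfit
   `E(ω, s) = ½ Σᵢ ‖pᵢ(ω, s) − p_obs,i(ω)‖²` is minimized by adjoint-state
   nonlinear conjugate gradient. Three protocols are provided: the two-pass
   reconstruction (pass 1 sound speed only, pass 2 alternating sound speed
   and attenuation, 3 CG iterations per block); the *kickstart* — a
   single-pass, sound-speed-only, 2-iterations-per-frequency inversion of the
   frequency-differenced data; and the combination, where the kickstart
   replaces the homogeneous starting model so the two-pass inversion no
   longer cycle-skips.

The package ships the canonical modified Shepp-Logan acoustic phantom,
ring-array geometry, an HDF5 channel-data container, schedule presets for
the published ring-array protocols (simulated, breast phantom, preserved
brain, transcranial), RMSE/PSNR/SSIM reporting, and a CLI
(`fdfwi simulate|freqdiff|invert|metrics`).

## Worked example

The linear-phase identity, in six lines — synthesize channels that contain
*nothing below 0.6 MHz*, then recover their 0.2 MHz content:

```python
import numpy as np
import fdfwi as fw
from fdfwi.freqdiff import FDBand, frequency_difference
from fdfwi.presets import frange

taus  = np.random.default_rng(0).uniform(20e-6, 160e-6, (4, 4))  # times of flight
freqs = frange(0.6e6, 5.0e6, 50e3)                  # recorded band only
vals  = np.exp(2j*np.pi*taus[:, :, None]*np.asarray(freqs)[None, None, :])
spectra = fw.ChannelSpectra(vals, freqs, fw.make_ring_array(0.22, 4))
out = frequency_difference(spectra, FDBand(0.6e6, 5.0e6, (0.2e6,)))
print(np.max(np.abs(out.values[:, :, 0] - np.exp(2j*np.pi*0.2e6*taus))))
```

prints `3.438825091121782e-14`: the 0.2 MHz signal is recovered to rounding
error even though the band starts at 0.6 MHz.

The full desk-scale cycle-skipping study (a 6 cm, 64-element ring around a
scaled Shepp-Logan phantom whose contrast puts the homogeneous start ~1.1
cycles off at the lowest inverted frequency):

```python
from fdfwi.experiments import run_cycle_skip_demo
out = run_cycle_skip_demo(verbose=True)   # ~12 minutes on one core
```

```
homogeneous   RMSE  118.2 m/s  PSNR  11.6 dB  SSIM 0.482
kickstart     RMSE   91.5 m/s  PSNR  13.8 dB  SSIM 0.682
fd_started    RMSE   49.6 m/s  PSNR  19.2 dB  SSIM 0.591
```

Reading the three rows: the two-pass inversion from a homogeneous 1480 m/s
start cycle-skips (RMSE 118 m/s, heavy artifacts); the kickstart recovered
from frequency-differenced 0.05–0.225 MHz data is blurry but captures the
bulk compartments; and the same two-pass inversion started from the
kickstart escapes the skipped basin — +0.11 SSIM and +7.5 dB PSNR over the
homogeneous start, the qualitative ordering the method exists to produce.

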