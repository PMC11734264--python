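"""Frequency differencing: synthesize low-frequency channel spectra from a
high-frequency band.

For each channel (transmit, receiver) the difference-frequency signal at
``df`` is the normalized cross-frequency autocorrelation over the recorded
band ``[f_low, f_high]``:

    p_bar(df) = sum_k p(f_k + df) * conj(p(f_k)) / sum_k |p(f_k)|^2

with ``f_k`` the uniform samples of the band and both sums taken over the same
set of samples. If the channel spectrum has a linear phase
``p(f) = exp(i 2 pi f tau)`` — i.e. a pure time-of-flight arrival — the output
is *exactly* ``exp(i 2 pi df tau)``: the linear phase is extrapolated to the
(possibly unrecorded) low frequency ``df``. Diffraction through heterogeneous
tissue bends the phase away from linear, which is why the synthesized data is
used only to build a starting model, not as a final measurement.

The band integral is a uniform Riemann sum; the common ``df_k`` step cancels
between numerator and denominator, so no quadrature weights appear. Difference
frequencies must be integer multiples of the band's sampling step — silent
interpolation would corrupt the phase relation the method relies on, so
misalignment is a hard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import ChannelSpectra
from .exceptions import AlignmentError, DegenerateChannelError

__all__ = ["FDBand", "frequency_difference", "fd_kickstart_data"]


@dataclass(frozen=True)
class FDBand:
    """The recorded band and the difference-frequency grid to synthesize.

    The method's accuracy regime is ``df << f_low``; difference frequencies
    above ``f_low / 2`` are allowed (published configurations reach all the
    way to ``f_low``) but emit a warning since they stretch that assumption.
    A ``df`` must still leave at least one usable sample pair inside the band,
    which :func:`frequency_difference` enforces.
    """

    f_low: float
    f_high: float
    delta_frequencies: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_high:
            raise ValueError(
                f"need 0 < f_low < f_high, got [{self.f_low}, {self.f_high}]"
            )
        deltas = tuple(float(d) for d in self.delta_frequencies)
        object.__setattr__(self, "delta_frequencies", deltas)
        if any(d < 0 for d in deltas):
            raise ValueError("difference frequencies must be nonnegative")
        if any(d > self.f_high - self.f_low for d in deltas):
            bad = [d for d in deltas if d > self.f_high - self.f_low]
            raise ValueError(
                f"difference frequencies {bad} exceed the band width "
                f"{self.f_high - self.f_low}: no sample pairs available"
            )
        loose = [d for d in deltas if d > self.f_low / 2]
        if loose:
            warnings.warn(
                f"difference frequencies {loose} exceed f_low/2; the df << f_low "
                "assumption is stretched",
                stacklevel=2,
            )


def _band_indices(freqs: np.ndarray, band: FDBand, rtol: float = 1e-6):
    """Locate the band on the spectra grid; validate uniform sampling."""
    scale = max(band.f_high, 1.0)
    i_low = int(np.argmin(np.abs(freqs - band.f_low)))
    i_high = int(np.argmin(np.abs(freqs - band.f_high)))
    if abs(freqs[i_low] - band.f_low) > rtol * scale or abs(freqs[i_high] - band.f_high) > rtol * scale:
        raise AlignmentError(
            f"band [{band.f_low}, {band.f_high}] Hz not present on the spectra grid"
        )
    if i_high <= i_low:
        raise AlignmentError("band contains fewer than two frequency samples")
    steps = np.diff(freqs[i_low:])
    step = steps[0]
    if not np.allclose(steps, step, rtol=1e-9, atol=rtol * scale * 1e-3):
        raise AlignmentError("spectra are not uniformly sampled over the band")
    return i_low, i_high, float(step)


def frequency_difference(
    spectra: ChannelSpectra, band: FDBand, mode: str = "truncate"
) -> ChannelSpectra:
    """Synthesize difference-frequency channel spectra from ``spectra``.

    Parameters
    ----------
    mode : {"truncate", "extend"}
        Handling of the band's upper edge, where ``p(f_k + df)`` reads beyond
        ``f_high``. ``"truncate"`` (default) restricts ``f_k`` to
        ``[f_low, f_high - df]``; ``"extend"`` keeps ``f_k`` over the full
        band whenever samples above ``f_high`` exist, falling back to
        truncation otherwise.

    Returns
    -------
    ChannelSpectra
        Provenance ``"frequency_differenced"``, frequencies equal to the
        band's difference-frequency grid.
    """
    if mode not in ("truncate", "extend"):
        raise ValueError(f"unknown fd band mode {mode!r}")
    if not band.delta_frequencies:
        raise ValueError("band has no difference frequencies to synthesize")
    freqs = spectra.frequencies
    i_low, i_high, step = _band_indices(freqs, band)
    p = spectra.values
    out = np.empty((spectra.n_tx, spectra.n_rx, len(band.delta_frequencies)), dtype=complex)
    band_power = np.sum(np.abs(p[:, :, i_low : i_high + 1]) ** 2, axis=-1)
    power_floor = 1e-30 * float(band_power.max()) if p.size else 0.0
    for j, df in enumerate(band.delta_frequencies):
        m_float = df / step
        m = int(round(m_float))
        if abs(m_float - m) > 1e-6 or m < 0:
            raise AlignmentError(
                f"difference frequency {df} Hz is not an integer multiple of the "
                f"band sampling step {step} Hz"
            )
        if mode == "extend" and i_high + m < len(freqs):
            k_stop = i_high
        else:
            k_stop = i_high - m
        if k_stop < i_low:
            raise AlignmentError(
                f"difference frequency {df} Hz leaves no band samples (band too narrow)"
            )
        ks = np.arange(i_low, k_stop + 1)
        num = np.sum(p[:, :, ks + m] * np.conj(p[:, :, ks]), axis=-1)
        den = np.sum(np.abs(p[:, :, ks]) ** 2, axis=-1)
        bad = den <= max(power_floor, 0.0)
        if np.any(bad):
            tx, rx = np.nonzero(bad)
            listing = ", ".join(f"({t},{r})" for t, r in list(zip(tx, rx))[:10])
            raise DegenerateChannelError(
                f"frequency-differencing denominator vanished on {bad.sum()} "
                f"channel(s): {listing}"
            )
        out[:, :, j] = num / den
    return ChannelSpectra(
        out,
        np.asarray(band.delta_frequencies, dtype=float),
        spectra.array,
        provenance="frequency_differenced",
    )


def fd_kickstart_data(spectra: ChannelSpectra, schedule, mode: str = "truncate") -> ChannelSpectra:
    """Produce the difference-frequency data required by a schedule's FD pass.

    Thin convenience wrapper over :func:`frequency_difference` using
    ``schedule.fd_band``.
    """
    if schedule.fd_band is None:
        raise ValueError("schedule has no frequency-differencing band")
    return frequency_difference(spectra, schedule.fd_band, mode=mode)
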