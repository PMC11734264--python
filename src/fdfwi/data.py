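"""Observed channel data: frequency-domain synthesis, spectral extraction, HDF5 I/O.

A :class:`ChannelSpectra` holds the complex pressure received on every element
for every single-element transmit at a list of frequencies — the observed data
the inversion misfit is computed against. Spectra can come from the built-in
frequency-domain simulator, from a DFT of recorded time traces, or from
frequency differencing (tagged by provenance).

Fourier sign convention (load-bearing for frequency differencing): the forward
transform kernel is exp(-i w t), so a signal delayed by tau has spectrum phase
exp(-i 2 pi f tau) and *propagating fields accumulate positive phase with
travel time* under the exp(-i w t) field convention of :mod:`fdfwi.helmholtz`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .exceptions import FormatError, ResolutionError
from .geometry import RingArray, make_ring_array
from .helmholtz import PMLConfig, assemble_helmholtz, sample_at_receivers, solve_fields
from .phantom import AcousticModel, Pulse, pulse_spectrum

__all__ = [
    "ChannelSpectra",
    "TimeSeriesData",
    "simulate_channel_spectra",
    "extract_spectrum",
    "read_channel_h5",
    "write_channel_h5",
]


@dataclass
class ChannelSpectra:
    """Complex channel spectra indexed (transmit, receiver, frequency).

    Attributes
    ----------
    values : ndarray, complex, shape (n_tx, n_rx, n_freq)
    frequencies : ndarray, Hz, strictly increasing
    array : RingArray
    provenance : str
        One of ``"simulated"``, ``"measured"``, ``"frequency_differenced"``.
    """

    values: np.ndarray
    frequencies: np.ndarray
    array: RingArray
    provenance: str = "simulated"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must have shape (n_tx, n_rx, n_freq)")
        if self.values.shape[2] != len(self.frequencies):
            raise ValueError("frequency axis length mismatch")
        if not np.all(np.diff(self.frequencies) > 0):
            raise ValueError("frequencies must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("channel spectra contain NaN/Inf")

    @property
    def n_tx(self) -> int:
        return self.values.shape[0]

    @property
    def n_rx(self) -> int:
        return self.values.shape[1]

    def frequency_index(self, f: float, rtol: float = 1e-6) -> int:
        """Index of frequency ``f`` in the grid (raises FrequencyLookupError)."""
        from .exceptions import FrequencyLookupError

        i = int(np.argmin(np.abs(self.frequencies - f)))
        if abs(self.frequencies[i] - f) > rtol * max(abs(f), 1.0):
            raise FrequencyLookupError(
                f"{f} Hz not in spectra frequency grid (nearest {self.frequencies[i]} Hz)"
            )
        return i

    def at_frequency(self, f: float) -> np.ndarray:
        """(n_tx, n_rx) slice at one frequency."""
        return self.values[:, :, self.frequency_index(f)]

    def with_provenance(self, provenance: str) -> "ChannelSpectra":
        return replace(self, provenance=provenance)


@dataclass
class TimeSeriesData:
    """Raw received time traces indexed (transmit, receiver, time sample)."""

    traces: np.ndarray
    sample_rate: float
    time_origin: float = 0.0

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if not self.sample_rate > 0:
            raise ValueError("sample rate must be positive")
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("time traces contain NaN/Inf")


def simulate_channel_spectra(
    model: AcousticModel,
    array: RingArray,
    pulse: Pulse | None,
    frequencies: Sequence[float],
    pml: PMLConfig | None = None,
    source_stencil: str = "bilinear",
    noise_snr_db: float | None = None,
    rng: np.random.Generator | None = None,
    min_ppw: float = 4.0,
) -> ChannelSpectra:
    """Synthesize observed channel spectra through a ground-truth model.

    For each frequency: assemble and factorize the Helmholtz system once,
    solve all ``n_elements`` transmits by back-substitution, sample every
    receiver bilinearly, and scale by the pulse amplitude spectrum. The
    synthesis is deterministic; complex Gaussian noise at ``noise_snr_db``
    (per-frequency RMS signal-to-noise) can be added for robustness studies
    but is off by default.

    The default ``source_stencil='bilinear'`` differs deliberately from the
    nearest-pixel injection the inversion uses — one half of the inverse-crime
    safeguard (the other is simulating on a finer grid).
    """
    frequencies = np.asarray(sorted(frequencies), dtype=float)
    c_min = float(model.sound_speed.min())
    for f in frequencies:
        ppw = c_min / (f * model.grid.spacing)
        if ppw < min_ppw:
            raise ResolutionError(
                f"{f/1e6:.3g} MHz is above the grid support: {ppw:.1f} points per "
                f"wavelength < {min_ppw}"
            )
    n = array.n_elements
    values = np.empty((n, n, len(frequencies)), dtype=complex)
    sources = [(tuple(pos), 1.0 + 0.0j) for pos in array.element_positions]
    for kf, f in enumerate(frequencies):
        op = assemble_helmholtz(model, f, pml=pml)
        fields = solve_fields(op, sources, stencil=source_stencil)
        amp = pulse_spectrum(pulse, f) if pulse is not None else 1.0
        for i, fld in enumerate(fields):
            values[i, :, kf] = amp * sample_at_receivers(fld, array)
    if noise_snr_db is not None:
        rng = rng or np.random.default_rng()
        for kf in range(len(frequencies)):
            sl = values[:, :, kf]
            sig = np.sqrt(np.mean(np.abs(sl) ** 2))
            scale = sig * 10 ** (-noise_snr_db / 20.0) / np.sqrt(2.0)
            sl += scale * (rng.standard_normal(sl.shape) + 1j * rng.standard_normal(sl.shape))
    return ChannelSpectra(values, frequencies, array, provenance="simulated")


def extract_spectrum(
    data: TimeSeriesData,
    frequencies: Sequence[float],
    array: RingArray | None = None,
    window: np.ndarray | None = None,
) -> ChannelSpectra:
    """Direct DFT of time traces at arbitrary (not bin-snapped) frequencies.

    ``S(f) = (2 / N) * sum_n x_n w_n exp(-i 2 pi f t_n)`` with ``t_n`` the
    absolute sample times, so a unit-amplitude sinusoid at ``f0`` yields
    amplitude 1 at ``f0`` under a rectangular window spanning an integer
    number of periods, and a delayed impulse yields phase exp(-i 2 pi f tau).

    Raises an aliasing error for any frequency at or above Nyquist.
    """
    frequencies = np.asarray(sorted(frequencies), dtype=float)
    nyquist = data.sample_rate / 2.0
    bad = frequencies[frequencies >= nyquist]
    if bad.size:
        raise ResolutionError(
            f"frequencies {bad.tolist()} Hz at/above Nyquist ({nyquist} Hz): aliasing"
        )
    n_t = data.traces.shape[2]
    t = data.time_origin + np.arange(n_t) / data.sample_rate
    w = np.ones(n_t) if window is None else np.asarray(window, dtype=float)
    if w.shape != (n_t,):
        raise ValueError("window must match the trace length")
    kernel = (2.0 / n_t) * w[None, :] * np.exp(-2j * np.pi * frequencies[:, None] * t[None, :])
    values = np.einsum("trn,fn->trf", data.traces, kernel)
    return ChannelSpectra(
        values, frequencies, array or _dummy_array(data.traces.shape[0]), provenance="measured"
    )


def _dummy_array(n: int) -> RingArray:
    """Placeholder geometry for spectra extracted without a known array."""
    return make_ring_array(1.0, max(n, 3))


def write_channel_h5(path, data: ChannelSpectra | TimeSeriesData) -> None:
    """Persist channel data to the documented HDF5 layout.

    Layout: ``/spectra/real``, ``/spectra/imag`` [n_tx, n_rx, n_freq],
    ``/frequencies`` [Hz], ``/array/positions`` [n, 2 m], ``/array/radius``,
    ``/array/center``, ``/meta/provenance``; or ``/timeseries/traces`` +
    ``/timeseries/sample_rate`` + ``/timeseries/time_origin`` for raw
    captures. All floats are float64; round trips are bit exact.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        if isinstance(data, ChannelSpectra):
            f.create_dataset("spectra/real", data=np.real(data.values).astype("f8"))
            f.create_dataset("spectra/imag", data=np.imag(data.values).astype("f8"))
            f.create_dataset("frequencies", data=data.frequencies.astype("f8"))
            f.create_dataset("array/positions", data=data.array.element_positions.astype("f8"))
            f.create_dataset("array/radius", data=float(data.array.radius))
            f.create_dataset("array/center", data=np.asarray(data.array.center, dtype="f8"))
            f.create_dataset("meta/provenance", data=np.bytes_(data.provenance))
        elif isinstance(data, TimeSeriesData):
            f.create_dataset("timeseries/traces", data=data.traces.astype("f8"))
            f.create_dataset("timeseries/sample_rate", data=float(data.sample_rate))
            f.create_dataset("timeseries/time_origin", data=float(data.time_origin))
        else:
            raise TypeError(f"cannot serialize {type(data).__name__}")


def _require(f: h5py.File, name: str):
    if name not in f:
        raise FormatError(f"HDF5 file is missing required dataset {name!r}")
    return f[name]


def read_channel_h5(path) -> ChannelSpectra | TimeSeriesData:
    """Read back a container written by :func:`write_channel_h5`."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "timeseries" in f:
            traces = _require(f, "timeseries/traces")[()]
            rate = float(_require(f, "timeseries/sample_rate")[()])
            t0 = float(f["timeseries/time_origin"][()]) if "timeseries/time_origin" in f else 0.0
            return TimeSeriesData(traces, rate, t0)
        real = _require(f, "spectra/real")[()]
        imag = _require(f, "spectra/imag")[()]
        freqs = _require(f, "frequencies")[()]
        pos = _require(f, "array/positions")[()]
        radius = float(_require(f, "array/radius")[()])
        center = tuple(f["array/center"][()]) if "array/center" in f else (0.0, 0.0)
        provenance = "measured"
        if "meta/provenance" in f:
            provenance = f["meta/provenance"][()].decode()
        angles = np.arctan2(pos[:, 1] - center[1], pos[:, 0] - center[0])
        array = RingArray(
            center=center,
            radius=radius,
            n_elements=pos.shape[0],
            element_positions=pos,
            element_angles=angles,
        )
        return ChannelSpectra(real + 1j * imag, freqs, array, provenance=provenance)
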