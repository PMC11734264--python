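"""Acoustic property maps, the modified Shepp-Logan phantom, and transmit pulses.

The phantom is evaluated *analytically* at pixel centers from the canonical
10-ellipse parameter table — no raster image is resampled — so a phantom on a
fine data-simulation grid and one on a coarser inversion grid describe the
same physical object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidGeometryError
from .geometry import Grid, RingArray

__all__ = [
    "AcousticModel",
    "Pulse",
    "pulse_spectrum",
    "SHEPP_LOGAN_ELLIPSES",
    "shepp_logan_intensity",
    "make_shepp_logan_model",
    "make_gaussian_inclusion_model",
    "homogeneous_model",
]

#: Canonical modified Shepp-Logan ellipse table.
#: Columns: additive intensity, semi-axis a (x), semi-axis b (y),
#: center x0, center y0, rotation angle in degrees (counterclockwise).
#: Coordinates live in the unit square [-1, 1]^2; summed intensity lies in [0, 1].
SHEPP_LOGAN_ELLIPSES: tuple[tuple[float, float, float, float, float, float], ...] = (
    (1.0, 0.69, 0.92, 0.0, 0.0, 0.0),
    (-0.8, 0.6624, 0.8740, 0.0, -0.0184, 0.0),
    (-0.2, 0.1100, 0.3100, 0.22, 0.0, -18.0),
    (-0.2, 0.1600, 0.4100, -0.22, 0.0, 18.0),
    (0.1, 0.2100, 0.2500, 0.0, 0.35, 0.0),
    (0.1, 0.0460, 0.0460, 0.0, 0.1, 0.0),
    (0.1, 0.0460, 0.0460, 0.0, -0.1, 0.0),
    (0.1, 0.0460, 0.0230, -0.08, -0.605, 0.0),
    (0.1, 0.0230, 0.0230, 0.0, -0.606, 0.0),
    (0.1, 0.0230, 0.0460, 0.06, -0.605, 0.0),
)


@dataclass
class AcousticModel:
    """Sound-speed and attenuation maps over a grid.

    Attributes
    ----------
    sound_speed : ndarray, shape (ny, nx)
        Sound speed in m/s. Physically plausible values in (0, 1e4).
    attenuation : ndarray, shape (ny, nx)
        Attenuation power-law slope in dB/(cm·MHz), nonnegative. Attenuation
        in dB/cm at frequency f is ``attenuation * f_MHz`` (linear-in-f law).
    grid : Grid
    """

    sound_speed: np.ndarray
    attenuation: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        self.sound_speed = np.asarray(self.sound_speed, dtype=float)
        self.attenuation = np.asarray(self.attenuation, dtype=float)
        if self.sound_speed.shape != self.grid.shape:
            raise InvalidGeometryError(
                f"sound_speed shape {self.sound_speed.shape} != grid shape {self.grid.shape}"
            )
        if self.attenuation.shape != self.grid.shape:
            raise InvalidGeometryError(
                f"attenuation shape {self.attenuation.shape} != grid shape {self.grid.shape}"
            )
        if not (np.all(self.sound_speed > 0) and np.all(self.sound_speed < 1e4)):
            raise ValueError("sound speed must lie in (0, 1e4) m/s everywhere")
        if not np.all(self.attenuation >= 0):
            raise ValueError("attenuation must be nonnegative everywhere")

    def copy(self) -> "AcousticModel":
        return AcousticModel(self.sound_speed.copy(), self.attenuation.copy(), self.grid)


def homogeneous_model(grid: Grid, sound_speed: float, attenuation: float = 0.0) -> AcousticModel:
    """Constant-property model (the usual FWI starting model)."""
    return AcousticModel(
        np.full(grid.shape, float(sound_speed)),
        np.full(grid.shape, float(attenuation)),
        grid,
    )


def shepp_logan_intensity(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Modified Shepp-Logan intensity at unit-square coordinates ``(x, y)``.

    Sums the additive contribution of every ellipse whose interior contains
    the point. Returns values in [0, 1]; 0 outside the outer (skull) ellipse.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = np.zeros(np.broadcast(x, y).shape, dtype=float)
    for value, a, b, x0, y0, phi_deg in SHEPP_LOGAN_ELLIPSES:
        phi = np.deg2rad(phi_deg)
        xr = (x - x0) * np.cos(phi) + (y - y0) * np.sin(phi)
        yr = -(x - x0) * np.sin(phi) + (y - y0) * np.cos(phi)
        inside = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
        out += value * inside
    # the canonical sum lies in [0, 1]; clip the ~1e-16 cancellation residue
    return np.clip(out, 0.0, 1.0)


def make_shepp_logan_model(
    grid: Grid,
    c_background: float = 1480.0,
    c_contrast: float = 100.0,
    a_background: float = 0.0,
    a_contrast: float = 0.5,
    phantom_radius: float | None = None,
    phantom_center: tuple[float, float] = (0.0, 0.0),
    ring: RingArray | None = None,
) -> AcousticModel:
    """Map the modified Shepp-Logan intensity affinely onto acoustic properties.

    ``sound_speed = c_background + c_contrast * I`` and
    ``attenuation = a_background + a_contrast * I`` where I in [0, 1] is the
    canonical phantom intensity evaluated analytically at pixel centers.

    Parameters
    ----------
    phantom_radius : float, optional
        Physical half-extent (m) the unit square is scaled to. Defaults to
        40% of the shorter grid extent. The phantom should fit inside the
        ring with a water margin; if ``ring`` is given this is checked and a
        warning emitted when the margin is under 10% of the ring radius.
    """
    if phantom_radius is None:
        phantom_radius = 0.4 * min(grid.extent)
    if ring is not None and phantom_radius > 0.9 * ring.radius:
        warnings.warn(
            f"phantom radius {phantom_radius:.4g} m leaves less than a 10% water "
            f"margin inside the ring (radius {ring.radius:.4g} m)",
            stacklevel=2,
        )
    X, Y = grid.meshgrid()
    u = (X - phantom_center[0]) / phantom_radius
    v = (Y - phantom_center[1]) / phantom_radius
    intensity = shepp_logan_intensity(u, v)
    return AcousticModel(
        sound_speed=c_background + c_contrast * intensity,
        attenuation=np.maximum(a_background + a_contrast * intensity, 0.0),
        grid=grid,
    )


def make_gaussian_inclusion_model(
    grid: Grid,
    c_background: float = 1480.0,
    relative_contrast: float = 0.02,
    sigma: float = 0.01,
    center: tuple[float, float] = (0.0, 0.0),
    attenuation: float = 0.0,
) -> AcousticModel:
    """Smooth Gaussian sound-speed inclusion on a homogeneous background.

    Used for low-contrast parameter-recovery studies where cycle skipping is
    not in play: ``c = c_background * (1 + relative_contrast * exp(-r^2/(2 sigma^2)))``.
    """
    X, Y = grid.meshgrid()
    r2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2
    bump = np.exp(-0.5 * r2 / sigma**2)
    return AcousticModel(
        sound_speed=c_background * (1.0 + relative_contrast * bump),
        attenuation=np.full(grid.shape, float(attenuation)),
        grid=grid,
    )


@dataclass(frozen=True)
class Pulse:
    """Transmit pulse described by its Gaussian amplitude spectrum.

    ``fractional_bandwidth`` is the -6 dB full width divided by the center
    frequency, the usual transducer datasheet convention (e.g. 0.75 for a
    75% bandwidth probe).
    """

    center_frequency: float
    fractional_bandwidth: float

    def __post_init__(self) -> None:
        if not self.center_frequency > 0:
            raise ValueError("center frequency must be positive")
        if not self.fractional_bandwidth > 0:
            raise ValueError("fractional bandwidth must be positive")

    @property
    def sigma(self) -> float:
        """Gaussian spectral standard deviation in Hz.

        Solves ``exp(-(hw)^2 / (2 sigma^2)) = 1/2`` for the -6 dB (amplitude
        one-half) half-width ``hw = fractional_bandwidth * fc / 2``.
        """
        half_width = 0.5 * self.fractional_bandwidth * self.center_frequency
        return half_width / np.sqrt(2.0 * np.log(2.0))

    def amplitude(self, f) -> np.ndarray:
        return pulse_spectrum(self, f)


def pulse_spectrum(pulse: Pulse, f) -> np.ndarray:
    """Gaussian amplitude spectrum of ``pulse`` at frequencies ``f`` (Hz).

    Normalized to 1 at the center frequency. Raises on negative frequencies.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("pulse_spectrum is defined for f >= 0 only")
    return np.exp(-0.5 * ((f - pulse.center_frequency) / pulse.sigma) ** 2)
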