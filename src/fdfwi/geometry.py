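"""Regular grids and ring-array transducer geometry.

Conventions used throughout the package (stated once, here):

* Maps over a grid are 2-D arrays of shape ``(ny, nx)`` — row index is y,
  column index is x, both 0-based.
* ``Grid.origin`` is the physical position of the *center* of pixel
  ``(ix=0, iy=0)``; pixel ``(ix, iy)`` sits at
  ``origin + (ix * spacing, iy * spacing)``.
* Ring-array element 0 sits at angle 0 (positive x axis from the ring
  center) and elements proceed counterclockwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidGeometryError

__all__ = ["Grid", "RingArray", "make_ring_array", "centered_grid"]


@dataclass(frozen=True)
class Grid:
    """A regular 2-D grid of pixel centers.

    Parameters
    ----------
    nx, ny : int
        Number of pixels along x and y. Must be positive.
    spacing : float
        Pixel pitch in meters (isotropic). Must be positive.
    origin : tuple of float
        Physical (x, y) position in meters of the center of pixel (0, 0).
    """

    nx: int
    ny: int
    spacing: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise InvalidGeometryError("grid must have at least one pixel per axis")
        if not self.spacing > 0:
            raise InvalidGeometryError(f"grid spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape ``(ny, nx)`` of maps defined on this grid."""
        return (self.ny, self.nx)

    @property
    def extent(self) -> tuple[float, float]:
        """Physical extent ``((nx - 1) * spacing, (ny - 1) * spacing)`` in meters."""
        return ((self.nx - 1) * self.spacing, (self.ny - 1) * self.spacing)

    @property
    def x(self) -> np.ndarray:
        """x coordinates of pixel centers, shape ``(nx,)``."""
        return self.origin[0] + self.spacing * np.arange(self.nx)

    @property
    def y(self) -> np.ndarray:
        """y coordinates of pixel centers, shape ``(ny,)``."""
        return self.origin[1] + self.spacing * np.arange(self.ny)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical coordinates ``(X, Y)`` of every pixel, each shape ``(ny, nx)``."""
        return np.meshgrid(self.x, self.y)

    def index_to_point(self, ix: int, iy: int) -> tuple[float, float]:
        """Physical position of pixel center ``(ix, iy)``."""
        return (self.origin[0] + ix * self.spacing, self.origin[1] + iy * self.spacing)

    def point_to_index(self, x: float, y: float) -> tuple[int, int]:
        """Nearest pixel ``(ix, iy)`` to a physical point (inverse of
        :meth:`index_to_point` to within half a pixel)."""
        ix = int(round((x - self.origin[0]) / self.spacing))
        iy = int(round((y - self.origin[1]) / self.spacing))
        return ix, iy

    def fractional_index(self, x: float, y: float) -> tuple[float, float]:
        """Continuous (possibly non-integer) pixel coordinates of a point."""
        return ((x - self.origin[0]) / self.spacing, (y - self.origin[1]) / self.spacing)


def centered_grid(nx: int, ny: int, spacing: float, center: tuple[float, float] = (0.0, 0.0)) -> Grid:
    """Build a grid whose physical midpoint is ``center``."""
    x0 = center[0] - 0.5 * (nx - 1) * spacing
    y0 = center[1] - 0.5 * (ny - 1) * spacing
    return Grid(nx=nx, ny=ny, spacing=spacing, origin=(x0, y0))


@dataclass(frozen=True)
class RingArray:
    """A circular transducer array of point-like elements.

    Elements are uniformly spaced in angle starting at angle 0 (the +x axis
    from the ring center) and proceeding counterclockwise. Each element acts
    as both a transmitter and a receiver.
    """

    center: tuple[float, float]
    radius: float
    n_elements: int
    element_positions: np.ndarray = field(repr=False, default=None)  # (n, 2), derived
    element_angles: np.ndarray = field(repr=False, default=None)  # (n,), derived

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise InvalidGeometryError(f"ring radius must be positive, got {self.radius}")
        if self.n_elements < 3:
            raise InvalidGeometryError(
                f"a ring array needs at least 3 elements, got {self.n_elements}"
            )
        if self.element_positions is None:
            angles = 2.0 * np.pi * np.arange(self.n_elements) / self.n_elements
            pos = np.column_stack(
                [
                    self.center[0] + self.radius * np.cos(angles),
                    self.center[1] + self.radius * np.sin(angles),
                ]
            )
            object.__setattr__(self, "element_angles", angles)
            object.__setattr__(self, "element_positions", pos)
        if len(self.element_positions) != self.n_elements:
            raise InvalidGeometryError("element_positions length must equal n_elements")


def make_ring_array(
    diameter: float, n_elements: int, center: tuple[float, float] = (0.0, 0.0)
) -> RingArray:
    """Construct a ring array of ``n_elements`` point elements.

    Parameters
    ----------
    diameter : float
        Ring diameter in meters (e.g. 0.22 for a 22 cm clinical ring).
    n_elements : int
        Number of elements, at least 3 (e.g. 512).
    center : tuple of float
        Ring center (x, y) in meters.

    Returns
    -------
    RingArray
        Elements uniformly spaced in angle, element 0 on the +x axis,
        counterclockwise ordering.
    """
    if not diameter > 0:
        raise InvalidGeometryError(f"ring diameter must be positive, got {diameter}")
    return RingArray(center=tuple(center), radius=diameter / 2.0, n_elements=int(n_elements))
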