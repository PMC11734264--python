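"""Exception types raised by fdfwi."""


class FdfwiError(Exception):
    """Base class for all fdfwi errors."""


class InvalidGeometryError(FdfwiError, ValueError):
    """Ring-array or grid parameters are not physically meaningful."""


class ResolutionError(FdfwiError, ValueError):
    """A requested frequency is not supported by the grid sampling."""


class InvalidSourceError(FdfwiError, ValueError):
    """A point source was placed outside the usable (non-PML) interior."""


class OutOfBoundsError(FdfwiError, ValueError):
    """A sampling position falls outside the grid."""


class AlignmentError(FdfwiError, ValueError):
    """A difference frequency does not align with the spectral sampling grid."""


class DegenerateChannelError(FdfwiError, ValueError):
    """Frequency-differencing denominator vanished on one or more channels."""


class DegenerateSourceError(FdfwiError, ValueError):
    """Source estimation attempted against an all-zero simulated channel."""


class FormatError(FdfwiError, KeyError):
    """An HDF5 container is missing a required dataset."""


class FrequencyLookupError(FdfwiError, KeyError):
    """A requested frequency is absent from a channel-spectra frequency grid."""
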