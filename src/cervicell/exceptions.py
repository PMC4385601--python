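"""Exception hierarchy shared by all cervicell modules."""


class CervicellError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CervicellError, ValueError):
    """An input file or array does not have the expected format."""


class ConfigError(CervicellError, ValueError):
    """A configuration value violates its documented constraints."""


class GeometryError(CervicellError, ValueError):
    """A geometric precondition is violated (areas, bounds, containment)."""


class PairingError(CervicellError, ValueError):
    """Nucleus-to-cell pairing cannot be performed."""


class ValidationError(CervicellError, ValueError):
    """Inconsistent or incomplete tabular/feature input."""


class DegenerateInputError(CervicellError, ValueError):
    """Too few data points for the requested fit or computation."""


class PlacementError(CervicellError, RuntimeError):
    """Synthetic cells could not be placed on the canvas."""
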