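"""Exception types shared across the package."""


class ChronotopyError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(ChronotopyError, ValueError):
    """A simulation or analysis configuration violates its invariants."""


class DegenerateGeometryError(ChronotopyError, ValueError):
    """Midline anchors coincide; the section rotation is undefined."""


class LandmarkOrderError(ChronotopyError, ValueError):
    """Anchor y-coordinates are not in dorsoventral order; names the offenders."""


class FrameMismatchError(ChronotopyError, ValueError):
    """An operation received cell tables in incompatible coordinate frames."""


class NoSignalError(ChronotopyError, ValueError):
    """All mean co-labeling fractions are zero; a cumulative curve is undefined."""


class DegenerateBandwidthError(ChronotopyError, ValueError):
    """Automatic bandwidth selection failed (zero spread on an axis)."""
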