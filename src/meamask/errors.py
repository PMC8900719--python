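"""Exception hierarchy shared across the package."""


class MeamaskError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(MeamaskError, ValueError):
    """A numeric or enum parameter violates its documented constraint."""


class GeometryError(MeamaskError, ValueError):
    """A microstructure design is geometrically inconsistent
    (overlapping nodes, dangling channel, colliding redirects)."""


class PlacementError(MeamaskError, ValueError):
    """A layout does not fit inside the sensing area of the grid."""


class CapacityError(MeamaskError, ValueError):
    """A routing pattern exceeds the number of simultaneously
    recordable channels."""


class AlignmentError(MeamaskError, ValueError):
    """Recordings and routing patterns do not line up channel-for-channel."""


class SchemaError(MeamaskError, ValueError):
    """An HDF5 recording file does not match the documented layout."""
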