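"""Exception hierarchy shared by all hivesense modules."""


class HiveSenseError(Exception):
    """Base class for every error raised by this package."""


class InputError(HiveSenseError):
    """Missing, unreadable, or malformed input data."""


class TooShortError(InputError):
    """A recording is too short to yield any usable analysis window."""


class ShapeError(HiveSenseError):
    """An array does not have the shape a contract requires."""


class ParameterError(HiveSenseError):
    """A numeric parameter violates its documented constraints."""


class ConfigError(HiveSenseError):
    """A configuration value (band table, architecture, ...) is invalid."""


class RoutingError(HiveSenseError):
    """An input vector length matches no known classifier strand."""


class StateError(HiveSenseError):
    """An operation was requested on a model in the wrong state (e.g. untrained)."""
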