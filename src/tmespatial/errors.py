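"""Exception hierarchy shared across the package.

All errors raised on bad user input derive from :class:`TmeSpatialError` so
callers can catch one base class; the subclasses name the failure mode.
"""


class TmeSpatialError(Exception):
    """Base class for all tmespatial errors."""


class ConfigError(TmeSpatialError, ValueError):
    """A configuration object violates its invariants."""


class SchemaError(TmeSpatialError, ValueError):
    """A tabular input is missing required columns or has unparseable rows."""


class InputError(TmeSpatialError, ValueError):
    """A runtime input (values, labels, geometry) is invalid or inconsistent."""
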