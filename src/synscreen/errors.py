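"""Exception hierarchy shared across the pipeline.

Schema/configuration problems and numerical failures are kept distinct so the
CLI can map them onto different exit codes (2 and 3 respectively).
"""


class SynscreenError(Exception):
    """Base class for all package errors."""


class SchemaError(SynscreenError):
    """Malformed input file or table (missing column, bad row, duplicate id)."""


class ConfigError(SchemaError):
    """Invalid configuration value; message names the violated invariant."""


class FitError(SynscreenError):
    """A model fit could not be performed on the given data."""


class NumericalError(SynscreenError):
    """A numerical procedure failed to converge or produced invalid output."""
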