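"""Exception hierarchy for prnftp.

All library errors derive from :class:`PrnftpError` so callers can catch one
base class at pipeline boundaries.
"""


class PrnftpError(Exception):
    """Base class for all prnftp errors."""


class ConfigurationError(PrnftpError):
    """Invalid parameter values (e.g. cardinal temperatures out of order)."""


class SchemaError(PrnftpError):
    """Malformed input table; message carries file and line context."""


class InsufficientWeatherError(PrnftpError):
    """A thermal-time threshold was not reached before the weather record ends."""

    def __init__(self, message, env_id=None, shortfall=None):
        super().__init__(message)
        self.env_id = env_id
        self.shortfall = shortfall


class FitError(PrnftpError):
    """A reaction-norm fit could not be performed on the given data."""


class DegenerateFitError(FitError):
    """The fit is formally computable but unidentifiable (e.g. constant response)."""
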