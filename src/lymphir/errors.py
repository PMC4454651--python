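"""Exception taxonomy for the pipeline.

Each subclass maps to a distinct failure mode so callers can react
programmatically (e.g. a CLI turning a :class:`ConfigurationError` into a
usage message rather than a traceback).
"""


class LymphirError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LymphirError):
    """A file is syntactically malformed (missing or garbled fields)."""


class IntegrityError(LymphirError):
    """A file parses but is internally inconsistent (e.g. size mismatch)."""


class RangeError(LymphirError):
    """A requested spectral/spatial range or index is empty or out of bounds."""


class ConfigurationError(LymphirError):
    """A configuration value is invalid for the data it is applied to."""


class IncompatibilityError(LymphirError):
    """Two objects that must share an axis/pitch/shape do not."""


class EstimationError(LymphirError):
    """A statistical estimate cannot be formed from the available pixels."""


class UndefinedDistanceError(LymphirError):
    """A spectral distance is undefined (e.g. zero-variance input)."""
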