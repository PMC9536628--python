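"""Exception hierarchy.

Every error raised by this package derives from :class:`GaitError`, so
callers can catch one type at a pipeline boundary. Stage-aware wrappers
(see :func:`gaitspeed.features.extract_features`) re-raise with the stage
name prefixed.
"""


class GaitError(Exception):
    """Base class for all gaitspeed errors."""


class FormatError(GaitError):
    """A file or table does not have the expected structure."""


class DataError(GaitError):
    """Data present but invalid (non-monotone time, gaps, out-of-range values)."""


class ParameterError(GaitError):
    """A parameter is outside its valid domain."""


class InsufficientDataError(GaitError):
    """Not enough steps/strides/samples to compute the requested quantity."""


class OrientationError(GaitError):
    """Sensor orientation cannot be recovered (e.g. near-zero mean acceleration)."""


class ModelInputError(GaitError):
    """A required model predictor is missing or invalid; message names it."""
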