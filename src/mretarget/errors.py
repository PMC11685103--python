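"""Exception hierarchy shared across the package.

CLI exit-code mapping: ``DataError`` -> 3, ``ModelError`` -> 4,
usage problems -> 2 (handled by click).
"""


class MreTargetError(Exception):
    """Base class for all package errors."""


class DataError(MreTargetError):
    """Malformed, inconsistent, or missing input data."""


class ConfigurationError(DataError):
    """Invalid configuration (model spec, run config, missing mapping)."""


class ModelError(MreTargetError):
    """Failure while building, training, or applying a model."""
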