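"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`DeepHistoClassError`, so callers (and the CLI) can separate
package-level failures from genuine bugs.
"""


class DeepHistoClassError(Exception):
    """Base class for all package errors."""


class ConfigError(DeepHistoClassError):
    """Invalid configuration or parameter value (CLI exit code 2)."""


class DataError(DeepHistoClassError):
    """Invalid, missing or inconsistent input data (CLI exit code 3)."""


class FormatError(DataError):
    """A file could not be parsed as the expected on-disk format."""


class ValidationError(DataError):
    """Parsed data violates a domain invariant (e.g. intensity out of range)."""


class TrainingError(DeepHistoClassError):
    """Optimization failed (e.g. the loss became non-finite)."""
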