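"""Exception hierarchy.

``MibciError`` marks user-correctable problems (bad configuration, malformed
input files, invalid requests); anything else escaping the library is a bug.
"""


class MibciError(Exception):
    """Base class for user-facing errors."""


class ConfigurationError(MibciError):
    """Invalid parameter or configuration value."""


class SchemaError(MibciError):
    """On-disk table does not match the acquisition schema."""


class DecompositionError(MibciError):
    """Wavelet decomposition request is infeasible for the given signal."""


class TrainingError(MibciError):
    """Classifier training preconditions violated."""


class StreamError(MibciError):
    """Streaming engine abort (schema mismatch, exhausted source, ...)."""


class ReportError(MibciError):
    """Report rendering requested on empty or inconsistent results."""
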