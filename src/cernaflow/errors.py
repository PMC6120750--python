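"""Exception hierarchy shared by the library and the CLI.

The CLI maps these onto exit codes: configuration errors -> 2, input format
errors -> 3, missing step dependencies -> 4.
"""


class CernaflowError(Exception):
    """Base class for all cernaflow errors."""


class ConfigurationError(CernaflowError):
    """Invalid parameter, config file value, or unusable option."""


class FormatError(CernaflowError):
    """Malformed input file (expression TSV, FASTA, GMT, annotation, ...)."""


class DependencyError(CernaflowError):
    """A pipeline step was requested before the step it depends on."""


class UndefinedCorrelationError(CernaflowError):
    """Pearson correlation requested for a constant vector."""
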