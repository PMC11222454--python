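"""Exception hierarchy used across the pipeline."""


class TemponetError(Exception):
    """Base class for all temponet errors."""


class InvalidParameterError(TemponetError, ValueError):
    """A parameter is outside its valid range or combination."""


class InvalidInputError(TemponetError, ValueError):
    """Input data violates a precondition (e.g. p-value outside [0, 1])."""


class DegenerateRowError(TemponetError, ValueError):
    """A matrix row is constant and cannot be standardised."""


class EmptyModelError(TemponetError, ValueError):
    """Variable selection produced an empty model input."""


class ConfigurationError(TemponetError, ValueError):
    """Pipeline configuration is inconsistent or refers to missing inputs."""


class ParseError(TemponetError, ValueError):
    """A file could not be parsed; message carries the offending location."""
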