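"""Exception hierarchy."""


class EarmechError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EarmechError):
    """A model or scenario configuration is invalid or incomplete."""


class TopologyError(EarmechError):
    """The element network is disconnected or misses a required node."""


class SolverError(EarmechError):
    """The harmonic system could not be solved at a requested frequency."""


class DataError(EarmechError):
    """Audiometric or tabular input violates its invariants."""


class FormatError(EarmechError):
    """A structured-text file does not match the documented dialect."""
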