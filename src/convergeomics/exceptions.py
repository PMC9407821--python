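"""Exception types raised across the package."""


class ConvergeomicsError(Exception):
    """Base class for package errors."""


class FormatError(ConvergeomicsError, ValueError):
    """A file failed validation against its expected format."""


class ConfigurationError(ConvergeomicsError, ValueError):
    """A simulation or analysis configuration is invalid."""


class AnalysisError(ConvergeomicsError, ValueError):
    """An analysis step received inputs it cannot operate on."""
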