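"""Exception types shared across the package."""


class SurveyError(Exception):
    """Base class for all ssrsurvey errors."""


class FormatError(SurveyError):
    """A sequence or annotation file violates its format contract."""


class GFFParseError(FormatError):
    """A GFF3 line could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class ConfigError(SurveyError):
    """An invalid run or simulation configuration."""
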