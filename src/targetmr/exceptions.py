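"""Exception hierarchy for targetmr."""


class TargetMRError(Exception):
    """Base class for all targetmr errors."""


class SchemaError(TargetMRError):
    """A file does not conform to the expected column schema."""


class ParseError(TargetMRError):
    """A line of an input file could not be parsed."""


class EmptyInputError(TargetMRError):
    """An input file contained no data rows."""


class DataValidationError(TargetMRError, ValueError):
    """A value violates a documented invariant (names the offending field)."""


class EmptySelectionError(TargetMRError):
    """No candidate variant survived instrument selection."""


class InsufficientInstrumentsError(TargetMRError):
    """An estimator was called with fewer instruments than its minimum."""


class HarmonizationError(TargetMRError, KeyError):
    """A selected variant is missing from one of the trait files."""
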