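"""Exception hierarchy shared by every stage of the pipeline."""


class BrcaPathError(Exception):
    """Base class for all package-specific errors."""


class FormatError(BrcaPathError, ValueError):
    """A file does not conform to its declared format (TSV/GMT)."""


class EmptyInputError(BrcaPathError, ValueError):
    """An operation received input with no usable content."""


class ParameterError(BrcaPathError, ValueError):
    """A parameter is outside its admissible range."""


class InputError(BrcaPathError, ValueError):
    """Input data violate an operation's precondition."""
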