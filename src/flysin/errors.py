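"""Exception hierarchy shared across the pipeline."""


class FlysinError(Exception):
    """Base class for all package errors."""


class FormatError(FlysinError):
    """A file does not match the declared format (missing column, attribute...)."""


class EmptyInputError(FlysinError):
    """An input file or collection contained no usable records."""


class IdentifierError(FlysinError):
    """A fly id is unknown, duplicated, or used where two distinct ids are required."""


class ParameterError(FlysinError):
    """A parameter is out of range or names an unknown option."""


class DegenerateInputError(FlysinError):
    """The input is too small or too degenerate for the requested computation."""
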