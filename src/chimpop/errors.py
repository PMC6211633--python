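"""Exception hierarchy shared across the pipeline."""


class ChimpopError(Exception):
    """Base class for all pipeline errors."""


class FormatError(ChimpopError):
    """A file does not conform to the expected text format."""


class UnsupportedInputError(ChimpopError):
    """Input is well-formed but outside the supported dialect (e.g. multi-contig VCF)."""


class ParameterError(ChimpopError, ValueError):
    """A parameter value is outside its documented domain."""


class AlignmentError(ChimpopError):
    """Sequences expected to be aligned have inconsistent lengths."""


class NoInformationError(ChimpopError):
    """The requested inference has no informative input (e.g. empty site map)."""
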