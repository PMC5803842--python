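"""Exception hierarchy shared by all modules.

The CLI maps these onto exit codes: input/format problems -> 2, bad
parameters -> 3, internal invariant violations -> 4.
"""


class PtbscanError(Exception):
    """Base class for all package errors."""


class FormatError(PtbscanError):
    """An input file does not parse in the expected format."""


class MoltypeError(PtbscanError, TypeError):
    """A nucleotide operation received a protein record or vice versa."""


class ParameterError(PtbscanError, ValueError):
    """A user-supplied parameter is outside its valid range."""


class AlignmentError(PtbscanError):
    """An alignment is structurally invalid (ragged rows, missing ids, ...)."""
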