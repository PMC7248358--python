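"""Exception taxonomy.

Every error raised deliberately by this package derives from :class:`ToomeError`,
so callers (and the CLI) can distinguish our diagnostics from genuine bugs.
The subclasses separate the three failure families: malformed input files,
contract violations on in-memory values, and invalid user parameters.
"""


class ToomeError(Exception):
    """Base class for all errors raised by toome."""


class ParseError(ToomeError):
    """A cell or record in an input file could not be parsed."""


class FormatError(ToomeError):
    """An input table violates the expected layout (missing/duplicate columns)."""


class EmptyInputError(ToomeError):
    """An operation received no usable records after filtering."""


class ContractError(ToomeError):
    """A numeric precondition was violated (e.g. non-normalized class weights)."""


class StructureError(ToomeError):
    """Tree bookkeeping is inconsistent (e.g. child sizes do not sum to parent)."""


class ParameterError(ToomeError):
    """A user-supplied parameter is out of its valid range."""


class ShapeError(ToomeError):
    """An array has the wrong number of rows or columns for the operation."""
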