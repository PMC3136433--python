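"""Exception hierarchy for cppscreen.

Every error raised by the library derives from :class:`CppScreenError` so
callers can catch the package's failures with a single ``except`` clause.
"""


class CppScreenError(Exception):
    """Base class for all cppscreen errors."""


class EmptySequence(CppScreenError):
    """A peptide sequence was empty after whitespace stripping."""


class InvalidResidue(CppScreenError):
    """A character outside the 20 canonical one-letter codes was found."""

    def __init__(self, char: str, position: int, context: str = ""):
        self.char = char
        self.position = position
        msg = f"invalid residue {char!r} at position {position}"
        if context:
            msg += f" in {context}"
        super().__init__(msg)


class ParseError(CppScreenError):
    """Malformed input file; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UnknownDataset(CppScreenError):
    """Requested bundled dataset name does not exist."""


class EmptyInput(CppScreenError):
    """An operation received an empty collection or matrix."""


class InvalidModel(CppScreenError):
    """A frequency or classifier model violates its invariants."""


class PoolTooSmall(CppScreenError):
    """Biological negative pool smaller than the number of draws requested."""


class MissingGenerator(CppScreenError):
    """A strategy needing a residue-frequency model was run without one."""


class DimensionError(CppScreenError):
    """Feature-vector dimensions do not match."""


class DegenerateLabels(CppScreenError):
    """Training data contains a single class."""


class EmptySubset(CppScreenError):
    """A feature subset was empty or contained unknown names."""


class StratificationError(CppScreenError):
    """Cross-validation folds cannot contain both classes."""


class ShortlistUnderflow(CppScreenError):
    """Fewer predicted positives/negatives than the shortlist requested."""
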