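"""Exception hierarchy for the afdip package."""


class AfdipError(Exception):
    """Base class for all afdip-specific errors."""


class FormatError(AfdipError):
    """An input table does not conform to the expected dialect."""


class DesignError(AfdipError):
    """A sample design violates its invariants."""


class DegenerateProfileError(AfdipError):
    """A peptide profile carries no usable signal (all zero / all missing)."""


class StructureParseError(AfdipError):
    """A PDB record could not be parsed."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class LigandNotFoundError(AfdipError):
    """The requested ligand residue name is absent from the structure."""
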