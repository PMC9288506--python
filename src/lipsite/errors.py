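"""Named exceptions raised by the lipsite readers and analysis stages.

Readers never coerce silently: every invalid input maps to one of these,
carrying enough context (column name, row numbers, atom identity, match
positions) for the caller to locate the offending record.
"""


class LipsiteError(Exception):
    """Base class for all package errors."""


class MissingColumnError(LipsiteError):
    """A required column is absent from an input table."""

    def __init__(self, column: str, available: list[str]):
        self.column = column
        self.available = list(available)
        super().__init__(
            f"required column {column!r} not found; available columns: {available}"
        )


class EmptyTableError(LipsiteError):
    """An input table contains no data rows."""


class InvalidQuantityError(LipsiteError):
    """Non-positive or non-numeric quantities, reported with row numbers."""

    def __init__(self, rows: list[int]):
        self.rows = list(rows)
        super().__init__(
            f"non-positive or non-numeric quantity in {len(self.rows)} row(s): "
            f"{self.rows[:20]}"
        )


class DuplicateKeyError(LipsiteError):
    """Duplicate (peptide, dose, replicate) key in a quant table."""

    def __init__(self, keys: list[tuple]):
        self.keys = list(keys)
        super().__init__(f"duplicate (peptide, dose, replicate) key(s): {self.keys[:5]}")


class DoseParseError(LipsiteError):
    """A dose label could not be converted to a molar concentration."""


class StructureParseError(LipsiteError):
    """A structure file yielded no usable ATOM records."""


class UnknownElementError(LipsiteError):
    """An atom's element could not be resolved from the record or its name."""

    def __init__(self, atom_desc: str):
        self.atom_desc = atom_desc
        super().__init__(f"cannot resolve element for atom: {atom_desc}")


class UnmappedPeptideError(LipsiteError):
    """A peptide sequence does not occur in the target chain (non-fatal marker)."""


class AmbiguousMappingError(LipsiteError):
    """A peptide matches the chain sequence at more than one position."""

    def __init__(self, peptide: str, positions: list[int]):
        self.peptide = peptide
        self.positions = list(positions)
        super().__init__(
            f"peptide {peptide!r} matches chain at {len(positions)} positions "
            f"(0-based offsets {positions}); disambiguate the chain or sequence"
        )


class ConfigError(LipsiteError):
    """Invalid pipeline configuration value."""


class StageError(LipsiteError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
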