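"""Exception hierarchy shared across the toolkit."""


class CrydiscovError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CrydiscovError):
    """A generator or analysis was configured with invalid parameters."""


class GenerationError(CrydiscovError):
    """A synthetic-data request cannot be satisfied (e.g. unsatisfiable geometry)."""


class MoleculeParseError(CrydiscovError):
    """A SMILES/SDF record could not be parsed; carries the offending record id."""

    def __init__(self, record_id: str, message: str = "unparseable SMILES"):
        self.record_id = record_id
        super().__init__(f"{message}: record {record_id!r}")


class StructureParseError(CrydiscovError):
    """A PDB file could not be parsed; carries the line number when known."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)


class AnalysisError(CrydiscovError):
    """An analysis precondition failed (mismatched atoms, empty input, ...)."""


class UnidentifiableFitError(CrydiscovError):
    """A kinetic fit has no identifiable rate (flat trace, k <= 0)."""
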