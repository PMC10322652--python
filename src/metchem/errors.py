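"""Exception hierarchy for the metchem pipeline.

Every error raised by the library derives from :class:`MetChemError`, so
callers (including the CLI) can catch one type at the pipeline boundary.
"""


class MetChemError(Exception):
    """Base class for all metchem errors."""


class FormatError(MetChemError):
    """A file does not match the expected tabular/XML format."""


class AlignmentError(MetChemError):
    """Panel and concentration matrix share no metabolite names."""


class StructureError(MetChemError):
    """A SMILES string could not be parsed into a molecule."""

    def __init__(self, smiles: str, message: str | None = None):
        self.smiles = smiles
        super().__init__(message or f"unparseable SMILES: {smiles!r}")


class IncompatibleFingerprintError(MetChemError):
    """Two fingerprints differ in length or generating scheme."""


class InsufficientDataError(MetChemError):
    """Too few valid records/samples for the requested operation."""


class ParameterError(MetChemError):
    """A parameter value is outside its admissible range."""


class DegeneracyError(MetChemError):
    """Input is degenerate (e.g. no positive MDS eigenvalue, rank-0 module)."""


class UndefinedIndexError(MetChemError):
    """The silhouette index is undefined (fewer than two clusters)."""


class ContrastError(MetChemError):
    """A requested contrast level is missing or underpowered."""
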