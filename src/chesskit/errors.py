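"""Exception hierarchy.

Every failure mode named in the module contracts maps to one class here, so
the CLI can translate them into stable exit codes and named error classes.
"""


class ChessError(Exception):
    """Base class for all errors raised by chesskit."""


class EmptyInputError(ChessError):
    """Raised when a structure string or file is empty."""


class FormatError(ChessError):
    """Raised when a structure string cannot be parsed in the declared format."""


class RepresentabilityError(ChessError):
    """Raised for structures outside the identifier scheme's scope.

    Multi-component species (salts, mixtures) and anything standard InChI
    cannot canonicalize are rejected rather than heuristically split.
    """


class NumberingError(ChessError):
    """Raised when an atom lacks a canonical or derived index."""


class IncompleteGraphError(ChessError):
    """Raised when a triple graph lacks the parthood/bond assertions needed
    to reconstitute a chemical graph; carries the orphaned entity IRIs."""

    def __init__(self, message, orphans=()):
        super().__init__(message)
        self.orphans = tuple(orphans)


class ConnectivityError(ChessError):
    """Raised when a custom group's member atoms do not induce a connected
    subgraph."""


class DegenerateConfigurationError(ChessError):
    """Raised for a chemical configuration with no annotations."""


class MissingConfigurationError(ChessError):
    """Raised for a variable descriptor constructed without a configuration."""


class ProvenanceError(ChessError):
    """Raised for inconsistent provenance (e.g. parameters without software)."""


class MalformedReactionError(ChessError):
    """Raised when a reaction lacks inputs or products, or has non-positive
    stoichiometry."""


class MappingError(ChessError):
    """Raised when a transforms-into mapping references a non-participant."""


class PatternError(ChessError):
    """Raised for invalid query graphs (disconnected, undeclared variables)."""


class SerializationError(ChessError):
    """Raised when a graph cannot be written in the requested dialect."""


class KnowledgebaseError(ChessError):
    """Raised when a knowledgebase file fails to parse; names the file."""


class FixtureConfigError(ChessError):
    """Raised for unknown fixture families or malformed annotation plans."""
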