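"""Exception hierarchy.

Errors are grouped by pipeline stage so the CLI can map them onto distinct
exit codes (input, chemistry, fitting, I/O).
"""


class RotafitError(Exception):
    """Base class for all rotafit errors."""


# --- input / parsing -------------------------------------------------------

class InputError(RotafitError):
    """Problems with user-supplied structures or annotations."""


class FormatError(InputError):
    """The structure text could not be parsed in the declared format."""


class AnnotationError(InputError):
    """Backbone annotation missing, ambiguous, or referring to absent atoms."""


class ConnectivityError(InputError):
    """The molecular graph is not a single connected component."""


class RotlibParseError(InputError):
    """A rotamer-library file line could not be parsed."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


# --- chemistry -------------------------------------------------------------

class ChemistryError(RotafitError):
    """Valence/sanitization failures while building or editing molecules."""


class GenerationError(ChemistryError):
    """Conformer embedding produced no usable poses."""


class ScoringError(ChemistryError):
    """Force-field setup or evaluation failed."""


class GeometryError(RotafitError):
    """Degenerate geometry (collinear frame atoms, point on the frame axis)."""


# --- fitting ---------------------------------------------------------------

class FitError(RotafitError):
    """Mixture fitting failed to converge after the configured retries."""


class EmptyLibraryError(RotafitError):
    """Every fitted peak fell below the density threshold."""


# --- output ----------------------------------------------------------------

class RotlibFormatError(RotafitError):
    """A library violates the constraints of the rotlib text format."""


class NamingError(RotafitError):
    """Atom-name collision while writing PDB output."""
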