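"""Exception hierarchy.

Every reader/writer failure mode raises a distinct, named error so callers
(and the CLI) can report precisely what was wrong with an input artifact.
"""


class PancyanError(Exception):
    """Base class for all package errors."""


# --- file / format errors ---------------------------------------------------

class MissingFileError(PancyanError):
    """Input path does not exist."""


class EmptyFileError(PancyanError):
    """Input file exists but contains no records."""


class FastaFormatError(PancyanError):
    """Content is not well-formed FASTA."""


class DuplicateIdError(PancyanError):
    """Duplicate record / genome / gene / leaf identifier."""


class AnnotationFormatError(PancyanError):
    """Malformed annotation row (bad coordinates, strand, or columns)."""


class MatrixFormatError(PancyanError):
    """Presence/absence matrix is ragged or contains non-binary cells."""


class ConfigError(PancyanError):
    """Unknown or out-of-range configuration key."""


# --- analysis errors --------------------------------------------------------

class AlignmentInputError(PancyanError):
    """Empty sequence or alphabet problem handed to an aligner."""


class UndefinedDistanceError(PancyanError):
    """A pairwise distance (e.g. ANI) is undefined and blocks clustering."""


class DegenerateInputError(PancyanError):
    """An operation's preconditions exclude this input (e.g. < 3 genomes)."""
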