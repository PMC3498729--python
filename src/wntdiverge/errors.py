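"""Exception hierarchy.

Validation problems (bad data, bad config) and I/O problems are kept as
separate branches so the command-line layer can map them to distinct exit
codes.
"""


class WntDivergeError(Exception):
    """Base class for all package errors."""


class ValidationError(WntDivergeError):
    """Input data violates a structural contract (exit code 3 at the CLI)."""


class MalformedColumnError(ValidationError):
    """An alignment column is missing one of the five sequence roles."""


class AlphabetError(ValidationError):
    """A residue character is not an amino-acid letter or the gap symbol."""


class AlignmentError(ValidationError):
    """Ragged rows, all-gap columns, or duplicated/missing roles."""


class VocabularyError(ValidationError):
    """A territory id does not resolve against the controlled vocabulary."""


class StageError(ValidationError):
    """A developmental stage is not in the species' stage series, or a
    cross-species comparison lacks a stage correspondence."""


class IncompleteSubfamilyError(ValidationError):
    """Fewer than the four required genes are registered for a subfamily."""


class ConfigError(ValidationError):
    """A simulation or pipeline configuration is inconsistent."""


class UndefinedSimilarityError(ValidationError):
    """Percent similarity has a zero denominator (no mutually ungapped
    columns)."""


class UndefinedIndexError(ValidationError):
    """A divergence index has no applicable cells to average over."""


class InputOutputError(WntDivergeError):
    """A referenced path is missing or unreadable (exit code 4 at the CLI)."""
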