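"""Exception hierarchy shared across the pipeline.

Every error raised on bad user input derives from :class:`CryodivError`
so callers (and the CLI) can catch one base class.
"""


class CryodivError(Exception):
    """Base class for all cryodiv errors."""


class FormatError(CryodivError):
    """A file violates its format contract (ragged rows, duplicate labels...)."""


class AlignmentError(FormatError):
    """Sequences in an alignment are not all the same length."""


class RangeError(CryodivError):
    """A numeric value is outside its permitted range (e.g. latitude 95)."""


class VocabularyError(CryodivError):
    """A categorical label is outside the controlled vocabulary."""


class DataError(CryodivError):
    """Values are structurally valid but semantically impossible (NaN distance,
    a non-endemic OTU with no match environments)."""


class DepthError(CryodivError):
    """Rarefaction depth exceeds an available sample total."""


class LabelError(CryodivError):
    """A referenced label (tip, sample, OTU) does not exist."""


class EmptySampleError(CryodivError):
    """An operation requires at least one positive count."""


class GroupingError(CryodivError):
    """A sample has no group assignment."""


class DesignError(CryodivError):
    """A statistical design requirement is violated (e.g. a group of size 1)."""


class MappingError(CryodivError):
    """A sequence is not mapped to any site."""


class ComparabilityError(CryodivError):
    """A sequence pair shares no comparable (ungapped, unambiguous) sites."""


class DegenerateError(CryodivError):
    """A test statistic is undefined (zero variance in a distance matrix)."""


class SaturationError(CryodivError):
    """Requested divergence exceeds what an uncorrected distance can express."""
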