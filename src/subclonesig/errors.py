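"""Exception hierarchy.

Every anticipated failure mode raises a subclass of :class:`SubcloneSigError`
so callers (and the CLI) can distinguish bad input from genuine bugs.
"""


class SubcloneSigError(Exception):
    """Base class for all errors raised by subclonesig."""


class InvalidInputError(SubcloneSigError, ValueError):
    """Malformed or out-of-contract input (bad bases, bad interval, ...)."""


class NotADoubletError(InvalidInputError):
    """A dinucleotide change where one position is unchanged."""


class IndelTooLargeError(InvalidInputError):
    """Indel at or above the 100 bp small-indel limit."""


class ReferenceLookupError(SubcloneSigError, KeyError):
    """A record's locus cannot be resolved in the reference sequence."""


class SchemeMismatchError(SubcloneSigError, ValueError):
    """Two objects built on different channel schemes were combined."""


class CollapseMapError(SubcloneSigError, KeyError):
    """A fine-scheme label has no entry in the collapse map."""


class InsufficientDataError(SubcloneSigError, ValueError):
    """Too few observations for the check to be conclusive."""


class MissingSampleError(SubcloneSigError, KeyError):
    """A manifest sample is absent from the data it is checked against."""


class MissingControlsError(SubcloneSigError, ValueError):
    """An operation requiring control subclones received none (or one)."""


class ZeroBurdenError(SubcloneSigError, ValueError):
    """A sample with zero classified mutations where a profile is required."""


class EmptySampleError(ZeroBurdenError):
    """Bootstrap requested on a sample with no mutations."""


class UndefinedSimilarityError(SubcloneSigError, ValueError):
    """Cosine similarity against an all-zero profile."""


class DegenerateSubtractionError(SubcloneSigError, ValueError):
    """Background subtraction collapsed: signal indistinguishable from background."""


class PlacementError(SubcloneSigError, ValueError):
    """No reference locus with the context required by a signature channel."""


class ConfigError(SubcloneSigError, ValueError):
    """Inconsistent simulation or run configuration."""


class CatalogParseError(SubcloneSigError, ValueError):
    """A catalog TSV that does not round-trip (unknown label, non-integer)."""


class VcfParseError(SubcloneSigError, ValueError):
    """Malformed VCF input."""
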