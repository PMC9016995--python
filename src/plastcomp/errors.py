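"""Exception hierarchy for plastcomp.

Every operational failure raises a subclass of :class:`PlastcompError` so
callers can distinguish pipeline-stage failures from programming errors.
"""


class PlastcompError(Exception):
    """Base class for all plastcomp errors."""


class NoIRFound(PlastcompError):
    """No inverted-repeat pair of the required length/identity exists."""


class AmbiguousPartition(PlastcompError):
    """Two or more non-equivalent maximal IR pairs tie.

    The candidate pairs are carried in ``candidates`` as
    ``(start1, start2, length)`` tuples on the circle.
    """

    def __init__(self, message, candidates=()):
        super().__init__(message)
        self.candidates = list(candidates)


class EmptyRegion(PlastcompError):
    """A genomic region contains no usable (unambiguous) bases."""


class ZeroVariance(PlastcompError):
    """A correlation was requested on a constant vector."""


class DegenerateGroups(PlastcompError):
    """A two-group comparison was requested with too few values per group."""


class MissingAnchorGene(PlastcompError):
    """None of the junction anchor genes is present in the annotation."""


class OverlappingGenes(PlastcompError):
    """Adjacent genes overlap, so the spacer between them is undefined."""


class EmptyAfterTrim(PlastcompError):
    """Terminal-gap trimming removed every alignment column."""


class UndefinedSV(PlastcompError):
    """Sequence variability undefined: zero informative sites."""


class DoubleGapColumn(PlastcompError):
    """A pairwise alignment column is gapped in both rows."""


class UnknownTaxon(PlastcompError):
    """An event carrier is not a leaf of the chronogram."""


class ZeroDuration(PlastcompError):
    """A branch with assigned events has no positive time duration."""


class FrameError(PlastcompError):
    """A codon sequence is out of frame, has stops, or ambiguous bases."""


class SaturationError(PlastcompError):
    """Proportion of differences too large for the Jukes-Cantor correction."""


class InsufficientData(PlastcompError):
    """Not enough defined values to run a per-gene statistical screen."""


class LayoutConflict(PlastcompError):
    """Planted elements of a simulated genome overlap incompatibly."""


class ExtinctSequence(PlastcompError):
    """Simulated deletions exhausted a genomic region."""


class ConfigError(PlastcompError):
    """Pipeline configuration is invalid; message lists offending fields."""
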