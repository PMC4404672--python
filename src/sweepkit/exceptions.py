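"""Exception hierarchy shared across sweepkit modules."""


class SweepkitError(Exception):
    """Base class for all sweepkit errors."""


class FormatError(SweepkitError):
    """A file does not conform to its declared format."""


class LabelingError(SweepkitError):
    """Population labels do not match the genotype samples."""


class EstimationError(SweepkitError):
    """A statistic cannot be estimated from the available data."""


class UndefinedSiteError(EstimationError):
    """A per-site quantity is undefined (e.g. no called genotypes)."""


class UndefinedPairError(EstimationError):
    """A pairwise quantity is undefined (e.g. < 2 complete genotype pairs)."""


class AnchoringError(SweepkitError):
    """A genetic interval cannot be anchored to physical coordinates."""


class ExtrapolationError(SweepkitError):
    """A map query lies outside the mapped range of its chromosome."""
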