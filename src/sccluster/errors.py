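"""Named exceptions raised by sccluster.

Every failure mode that callers may reasonably want to catch gets its own
class; all inherit from :class:`SCClusterError` so a bare ``except
SCClusterError`` catches anything the library raises deliberately.
"""


class SCClusterError(Exception):
    """Base class for all sccluster errors."""


class MissingSidecarError(SCClusterError):
    """A 10x-style MTX matrix is missing its barcodes or features file."""


class NonIntegerEntryError(SCClusterError):
    """A count matrix contains negative or non-integral entries."""


class DuplicateIdentifierError(SCClusterError):
    """Cell or gene identifiers are not unique."""


class EmptyResultError(SCClusterError):
    """A filter removed every cell (or every gene)."""


class ZeroTotalCountError(SCClusterError):
    """A cell has zero total counts and cannot be normalized."""


class DegenerateInputError(SCClusterError):
    """Input is too degenerate for the requested operation (e.g. all gene
    means zero for the variance-trend fit, or fewer than 3 usable genes)."""


class ConstantRowError(SCClusterError):
    """A cell's expression vector is constant and cannot be scaled or
    correlated."""


class TrainingDivergedError(SCClusterError):
    """The autoencoder loss became non-finite during training."""


class NoSharedGenesError(SCClusterError):
    """Query and reference share fewer than two gene identifiers."""
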