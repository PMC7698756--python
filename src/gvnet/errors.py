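"""Exception hierarchy for gvnet.

Every load-time validation failure has its own class so callers (and the
CLI) can name the offending condition precisely.
"""


class GvnetError(Exception):
    """Base class for all gvnet errors."""


class MissingColumnError(GvnetError):
    """A required column is absent from an input table."""


class DanglingEndpointError(GvnetError):
    """An edge or association references a gene absent from the node table."""


class SelfLoopError(GvnetError):
    """An edge connects a gene to itself; networks here are inter-molecular."""


class UnknownInteractionTypeError(GvnetError):
    """An edge carries an interaction type outside the controlled vocabulary."""


class UnknownPhenotypeError(GvnetError):
    """A phenotype id is not present in the association table."""


class EmptyNetworkError(GvnetError):
    """An operation requiring a non-empty network received an empty one."""


class InconsistentCountsError(GvnetError):
    """Hypergeometric counts violate k <= min(K, n) <= N."""


class RankingMismatchError(GvnetError):
    """A ranked gene list does not cover the gene set it is validated against."""


class InfeasibleConfigError(GvnetError):
    """A synthetic-data configuration cannot be realised."""
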