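"""Exception hierarchy for orcci."""


class OrcciError(Exception):
    """Base class for all orcci-specific errors."""


class ParseError(OrcciError):
    """A malformed line or field in an input file."""


class ConfigError(OrcciError, ValueError):
    """An invalid configuration value (probabilities, fractions, grids)."""


class GraphError(OrcciError, ValueError):
    """A structural problem with a graph, partition or side-information object."""


class UndefinedDistributionError(GraphError):
    """Requested the neighbor mass distribution of an isolated node."""


class TransportUndefinedError(OrcciError, ValueError):
    """Wasserstein distance requested across an infinite ground distance."""


class UndefinedModularityError(GraphError):
    """Modularity requested on an edgeless graph."""
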