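"""Exception hierarchy shared across the package.

Configuration problems (bad options, malformed specs) are distinguished from
data problems (records violating observability, degenerate samples) so the
command-line layer can map them to distinct exit codes.
"""


class DelayCorrectError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DelayCorrectError, ValueError):
    """Invalid option, parameter or file layout (missing column, bad range)."""


class DataError(DelayCorrectError, ValueError):
    """Input records violate a contract (e.g. diagnosis after archive closure)."""


class InfiniteWeightError(DelayCorrectError, ValueError):
    """A registration probability of zero would produce an infinite HT weight."""


class UndefinedVarianceError(DelayCorrectError, ValueError):
    """Greenwood-type variance undefined: a risk set is exhausted by its events."""
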