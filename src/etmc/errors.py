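"""Exception hierarchy.

All package errors derive from :class:`EtmcError` so callers can catch one
base class; subclasses distinguish validation failures (bad graphs, dead
ends) from analysis failures (non-minimal chains, infeasible equilibria).
"""


class EtmcError(Exception):
    """Base class for all errors raised by this package."""


class MalformedGraphError(EtmcError):
    """A state or event graph violates a structural convention."""


class DeadEndError(EtmcError):
    """An event has no outgoing transition, so no Markov chain exists."""


class MinimalityError(EtmcError):
    """The chain is reducible or periodic; spectral analysis is undefined."""


class ConfigError(EtmcError):
    """Invalid configuration value (unknown condition, bad rate, ...)."""


class LookupError_(EtmcError):
    """A requested product or event is absent from the graph."""


class EquilibriumError(EtmcError):
    """The stability equation has no admissible root in (0, 1)."""
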