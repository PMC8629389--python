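"""Exception types shared across the package."""


class InvalidGraphError(ValueError):
    """The population graph violates a structural requirement."""


class EnumerationLimitError(ValueError):
    """Exact enumeration of stochastic-payoff scenarios is intractable."""


class LumpingError(ValueError):
    """A proposed state aggregation is not exactly lumpable."""


class SolverError(RuntimeError):
    """The fixation linear system could not be solved to tolerance."""
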