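"""Exception hierarchy for gcrscope."""


class GcrScopeError(Exception):
    """Base class for all gcrscope errors."""


class ConfigurationError(GcrScopeError):
    """Invalid configuration (overlapping features, bad parameters...)."""


class SimulationError(GcrScopeError):
    """An event could not be implanted or simulated as requested."""


class AmbiguousConsensusError(GcrScopeError):
    """Junction-sequencing reads disagree beyond the allowed conflict rate."""

    def __init__(self, message, conflicting_reads=()):
        super().__init__(message)
        self.conflicting_reads = list(conflicting_reads)


class ReconstructionError(GcrScopeError):
    """No copy-number-consistent walk through the junction graph exists."""

    def __init__(self, message, orphan_junctions=()):
        super().__init__(message)
        self.orphan_junctions = list(orphan_junctions)
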