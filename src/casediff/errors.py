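"""Exception hierarchy shared across the pipeline stages."""


class CasediffError(Exception):
    """Base class for all errors raised by casediff."""


class ValidationError(CasediffError):
    """A summary-statistics table or cohort violates its invariants."""


class HarmonizeError(CasediffError):
    """The two studies cannot be brought to a common allele frame."""


class DegenerateInputError(CasediffError):
    """Input has no usable variation (constant LD scores, empty vectors, ...)."""


class SeparationError(CasediffError):
    """Logistic regression is perfectly separated; no finite estimate exists."""


class SimulationError(CasediffError):
    """The simulator cannot satisfy its configuration (e.g. rejection cap hit)."""
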