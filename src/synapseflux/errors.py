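"""Exception types shared across the package."""


class SynapsefluxError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SynapsefluxError, ValueError):
    """A parameter or configuration value violates its documented constraints."""


class NonPositiveBaselineError(SynapsefluxError, ValueError):
    """Raw fluorescence contains values <= 0, so F0 = min(F) cannot normalise.

    Usually indicates background-subtracted or corrupt input; deltaF/F needs a
    strictly positive baseline.
    """


class DegenerateTestError(SynapsefluxError, ValueError):
    """A statistical test cannot be formed (e.g. a survival group with no events)."""


class AmbiguityError(SynapsefluxError, ValueError):
    """Input rows are ambiguous (e.g. duplicate animal/ROI combinations)."""
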