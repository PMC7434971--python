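"""Exception hierarchy for textphase."""


class TextPhaseError(Exception):
    """Base class for all textphase errors."""


class ConfigurationError(TextPhaseError, ValueError):
    """Invalid parameters or configuration."""


class DegenerateInputError(TextPhaseError, ValueError):
    """Input is structurally valid but analytically degenerate
    (e.g. zero inertia, single class, constant series)."""


class FitError(TextPhaseError, RuntimeError):
    """A statistical fit failed (non-convergence, separation)."""
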