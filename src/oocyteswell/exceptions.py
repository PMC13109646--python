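"""Exception hierarchy for the swelling-assay pipeline.

Every error raised on a user-facing path derives from :class:`SwellError`
so the CLI can map failures to stage-named exit codes.
"""


class SwellError(Exception):
    """Base class for all package errors."""


class ConfigError(SwellError):
    """Invalid configuration, assay label, or parameter set."""


class IntegrationFailureError(SwellError):
    """The forward ODE integration produced a non-finite or non-physical state."""


class EmptyGroupError(SwellError):
    """A cohort or statistical group with zero members."""


class InsufficientDataError(SwellError):
    """Fewer samples than the operation requires (traces need >= 3 points)."""


class DegenerateFitError(SwellError):
    """A regression with zero variance in the predictor."""


class ZeroGradientError(SwellError):
    """Osmotic or solute driving gradient is exactly zero; permeability undefined."""


class TraceParseError(SwellError):
    """Malformed trace CSV; message names the offending row or oocyte."""
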