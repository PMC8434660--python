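"""Exception hierarchy for the gait-analysis pipeline.

Every error raised by the library derives from :class:`GaitPathError`, so
callers (and the CLI) can catch one base class.  Subclasses are grouped by the
pipeline stage that raises them.
"""


class GaitPathError(Exception):
    """Base class for all gaitpath errors."""


class FormatError(GaitPathError):
    """A file does not conform to the declared skeleton dialect."""


class ValidationError(GaitPathError):
    """A sequence violates a structural invariant (e.g. non-monotone time)."""


class MissingJointError(GaitPathError):
    """A required joint is absent or untracked too often."""

    def __init__(self, joints, message=None):
        self.joints = list(joints)
        super().__init__(message or f"required joint(s) missing: {', '.join(self.joints)}")


class InsufficientDataError(GaitPathError):
    """Too few frames/samples for the requested operation."""


class SequencingError(GaitPathError):
    """Pipeline stages called out of order (e.g. filter before resample)."""


class WindowNotFoundError(GaitPathError):
    """The COM distance never crosses a VGAP threshold."""

    def __init__(self, threshold_m, which, message=None):
        self.threshold_m = threshold_m
        self.which = which  # "enter" or "exit"
        super().__init__(
            message
            or f"COM distance never crossed the {which} threshold ({threshold_m:g} m)"
        )


class NoStepsError(GaitPathError):
    """No usable step events inside the analysis window; trial unusable."""


class FeasibilityError(GaitPathError):
    """A synthetic gait specification cannot produce detectable steps."""


class DegenerateSampleError(GaitPathError):
    """A statistical routine received a degenerate (e.g. constant) sample."""
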