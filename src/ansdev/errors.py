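"""Exception hierarchy shared across the package."""


class AnsdevError(Exception):
    """Base class for all package-specific errors."""


class InfeasibleGeometryError(AnsdevError):
    """No wagon-array geometry satisfies the perceptual-control constraints."""


class MalformedDesignError(AnsdevError):
    """A task response set does not follow the required trial design."""


class InsufficientDataError(AnsdevError):
    """Too few observations for the requested estimate."""


class DegenerateInputError(AnsdevError):
    """Input has no variance (or an empty margin) where variance is required."""


class CollinearCovariatesError(AnsdevError):
    """The covariate design matrix is rank deficient."""


class CalibrationError(AnsdevError):
    """Generator calibration targets cannot be met with positive variances."""
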