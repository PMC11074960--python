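"""Exception hierarchy shared across the package."""


class KinidError(Exception):
    """Base class for all package-specific errors."""


class UnknownIdentifierError(KinidError, KeyError):
    """An individual or sample id is not present in the pedigree/dataset."""


class DisconnectedError(KinidError):
    """No connecting pedigree path exists under the requested lineage filter."""


class ParameterError(KinidError, ValueError):
    """A numeric parameter is outside its valid range."""


class InsufficientDataError(KinidError):
    """Not enough overlapping data to compute the requested statistic."""


class ConsistencyError(KinidError):
    """Inputs that must be built on the same site set / axes disagree."""


class DegenerateCovarianceError(KinidError):
    """Covariance matrix is singular; no confidence ellipse can be fit."""


class DamageEstimationError(KinidError):
    """Damage profile estimation received no usable observations."""


class NonReportableProfileError(KinidError):
    """Too few qualifying replicate amplifications for a composite profile."""
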