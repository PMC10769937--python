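"""Exception hierarchy for the registration pipeline."""


class EarRegError(Exception):
    """Base class for all package errors."""


class InvalidTransformError(EarRegError):
    """A rigid transform violates orthonormality / det(+1)."""


class DegenerateFitError(EarRegError):
    """Too few or geometrically degenerate correspondences for a rigid fit."""


class ConfigError(EarRegError):
    """Invalid configuration value or unknown backend name."""


class ModelError(EarRegError):
    """Structurally invalid ear model (missing joints, count mismatch, ...)."""


class RegistrationFailureError(EarRegError):
    """Stage-1 alignment found no usable inlier correspondences."""


class NumericalFailureError(EarRegError):
    """Non-finite loss encountered during pyramid optimization."""


class ParseError(EarRegError):
    """Malformed on-disk point cloud / artifact file."""
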