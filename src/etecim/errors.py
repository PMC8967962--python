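"""Exception hierarchy shared across the package.

Every failure mode callers are expected to handle gets a dedicated class so
that cohort-level drivers can distinguish "this pair is broken" from
programming errors.
"""


class EtecimError(Exception):
    """Base class for all package-specific errors."""


class MaskValidationError(EtecimError):
    """A mask volume violates its contract (spacing, dimensionality, ...)."""


class ManifestError(EtecimError):
    """A cohort manifest is malformed (missing columns, duplicate ids)."""


class EmptyForegroundError(EtecimError):
    """An operation that requires foreground voxels received none."""


class GeometryMismatchError(EtecimError):
    """Two masks that must share lattice shape and spacing do not."""


class GeometryError(EtecimError):
    """A phantom or transform does not fit inside its lattice."""


class UndefinedMetricError(EtecimError):
    """A metric is undefined for the given inputs (e.g. both masks empty)."""


class DegenerateVarianceError(EtecimError):
    """A statistical test received data with zero variance."""
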