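"""Exception hierarchy.

Everything raised on purpose derives from :class:`PetMrVolError` so callers
can catch pipeline failures without masking programming errors.
"""


class PetMrVolError(Exception):
    """Base class for all errors raised by petmrvol."""


class InvalidGeometryError(PetMrVolError, ValueError):
    """A grid, spacing or region specification is physically invalid."""


class GridMismatchError(InvalidGeometryError):
    """Two volumes that must share a grid have different shape or spacing."""


class EmptyInputError(PetMrVolError, ValueError):
    """An operation received an empty mask, series or table."""


class DomainError(PetMrVolError, ValueError):
    """A scalar argument is outside its physical domain."""


class InvalidVolumeError(DomainError):
    """A volume that must be non-negative is negative."""


class DegenerateInputError(PetMrVolError, ValueError):
    """Clustering input has fewer distinct feature vectors than clusters."""


class EmptyFitError(PetMrVolError, RuntimeError):
    """No voxel in a diffusion series had enough usable samples to fit."""


class InsufficientDataError(PetMrVolError, ValueError):
    """Too few complete pairs for a paired statistic."""


class UndefinedStatisticError(PetMrVolError, ValueError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


class ConfigError(PetMrVolError, ValueError):
    """A pipeline configuration is inconsistent or references missing paths."""
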