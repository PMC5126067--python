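"""Exception hierarchy shared across the pipeline."""


class PhenometError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PhenometError, ValueError):
    """A generator or extraction parameter is out of its valid range."""


class FormatError(PhenometError, ValueError):
    """An input image or table does not have the expected format."""


class LayoutError(PhenometError, ValueError):
    """Tray layout (number of views, plant ids, quadrants) is inconsistent."""


class PanelDetectionError(PhenometError, RuntimeError):
    """No separating panel was found and no fallback coordinate is configured."""


class DomainError(PhenometError, ValueError):
    """A physical quantity violates its domain (e.g. dry weight > fresh weight)."""


class DegenerateDataError(PhenometError, ValueError):
    """A statistic is undefined on the given data (e.g. constant vector)."""


class NormalizationError(PhenometError, ValueError):
    """Normalization cannot proceed (zero totals, missing baseline, ...)."""


class ContractError(PhenometError, ValueError):
    """An operation received data violating a documented pre-condition."""


class ScalingError(PhenometError, ValueError):
    """Autoscaling failed, e.g. a constant column with no drop policy."""


class InsufficientDataError(PhenometError, ValueError):
    """Too few rows/groups/shared keys for the requested analysis."""
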