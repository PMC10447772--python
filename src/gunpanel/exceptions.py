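"""Exception taxonomy for gunpanel."""


class GunPanelError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(GunPanelError):
    """A required column is missing or the schema mapping is invalid."""


class PanelValidationError(GunPanelError):
    """One or more panel rows violate the record invariants.

    Carries the offending 1-based data-row numbers in ``rows``.
    """

    def __init__(self, message: str, rows: list[int] | None = None):
        super().__init__(message)
        self.rows = rows or []


class DegenerateVarianceError(GunPanelError):
    """Standardization requested for a (near-)constant vector."""


class MissingGroupError(GunPanelError):
    """A group index has no observations."""


class ConfigurationError(GunPanelError):
    """Inconsistent model/data/parameter configuration."""


class InsufficientDataError(GunPanelError):
    """Too few draws or observations for the requested operation."""


class InitializationError(GunPanelError):
    """No finite starting point found for the sampler."""


class GenerationError(GunPanelError):
    """The synthetic-data configuration produced invalid rates."""
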