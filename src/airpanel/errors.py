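"""Exception hierarchy.

All package-raised errors derive from :class:`AirPanelError` so callers (and
the CLI) can distinguish user/data problems from genuine bugs.
"""


class AirPanelError(Exception):
    """Base class for all errors raised by airpanel."""


class SchemaError(AirPanelError):
    """A table is missing a required column or has the wrong dtype."""


class IntegrityError(AirPanelError):
    """Data violate a panel invariant (duplicates, gaps, weekend counts...)."""


class ConfigError(AirPanelError):
    """Invalid simulation or analysis configuration."""


class DesignError(AirPanelError):
    """Design matrix cannot be built (rank deficiency, empty cells...)."""


class FitError(AirPanelError):
    """Model fitting failed in a way no optimizer restart can repair."""


class SimulationError(AirPanelError):
    """Synthetic-data generation produced out-of-range intermediates."""
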