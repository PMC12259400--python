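"""Exception types used across the package."""


class TaxivError(Exception):
    """Base class for package errors."""


class ConfigError(TaxivError):
    """Invalid configuration or simulation truth."""


class DataError(TaxivError):
    """Malformed or inconsistent input data (hard validation failures)."""


class EstimationError(TaxivError):
    """An estimator failed (rank deficiency, separation, non-convergence...)."""
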