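"""Exception hierarchy.

All package errors derive from :class:`GrapeMxError` so callers can catch one
base class; subclasses map onto the CLI exit codes (config 2, data 3,
numerical 4).
"""


class GrapeMxError(Exception):
    """Base class for all grapemx errors."""


class ConfigError(GrapeMxError):
    """Invalid configuration (bad field, unknown preset, schema violation)."""


class DataError(GrapeMxError):
    """Malformed or missing input data (bad CSV, missing column, pairing)."""


class NumericalError(GrapeMxError):
    """A numerical procedure failed or was asked something impossible."""


class InvalidSignalError(DataError):
    """A fluorescence channel is non-positive after offset correction."""


class PairingError(DataError):
    """Paired cluster-side vectors do not align."""


class DegenerateFitError(NumericalError):
    """Too few points or no predictor variance to fit a calibration."""


class FitFailureError(NumericalError):
    """Nonlinear fit failed to converge after bounded restarts."""

    def __init__(self, message, residual_norm=None):
        super().__init__(message)
        self.residual_norm = residual_norm


class UnsupportedFamilyError(NumericalError):
    """Operation not defined for this calibration family (e.g. polynomial inverse)."""


class OutOfRangeError(NumericalError):
    """Value outside the open range of an invertible calibration model."""


class InvalidRatioError(DataError):
    """Skin-to-berry percentage outside (0, 100]."""


class InvalidLifetimeError(ConfigError):
    """Investment lifetime below one year."""


class InvalidDistributionError(ConfigError):
    """Monte Carlo distribution with negative width."""


class SelectionFailureError(NumericalError):
    """No candidate calibration family could be fitted."""
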