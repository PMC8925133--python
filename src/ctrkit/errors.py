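"""Exception hierarchy shared across the pipeline."""


class CTRKitError(Exception):
    """Base class for all ctrkit errors."""


class ParameterError(CTRKitError, ValueError):
    """A configuration value is outside its legal range."""


class ResolutionError(CTRKitError, ValueError):
    """The raster is too small to realise the requested geometry at 1-px resolution."""


class ContractError(CTRKitError, ValueError):
    """An operation was called with inputs violating its contract (e.g. shape mismatch)."""


class DataError(CTRKitError, ValueError):
    """A dataset is empty, malformed, or inconsistent."""


class MeasurementFailure(CTRKitError, RuntimeError):
    """A mask was empty after cleaning; the case must be graded *poor*, not crash."""
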