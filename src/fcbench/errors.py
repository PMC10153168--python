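"""Exception types raised across the package."""


class FCBenchError(Exception):
    """Base class for all package-specific errors."""


class FilePairingError(FCBenchError):
    """A BOLD image has no sibling confounds file at the expected path."""


class InputError(FCBenchError):
    """Malformed or unsupported input (bad suffix, non-finite values...)."""


class MissingConfoundError(FCBenchError):
    """A strategy requires confound columns that are absent from the table."""


class StrategyMismatchError(FCBenchError):
    """Strategy and image variant are incompatible (e.g. AROMA on preproc)."""


class RegistryError(FCBenchError):
    """Unknown strategy name requested from the registry."""


class DegreesOfFreedomError(FCBenchError):
    """More regressors than retained volumes; the regression is singular."""
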