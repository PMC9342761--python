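"""Exception hierarchy for the package."""


class LvadCeaError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(LvadCeaError):
    """A parameter or cost configuration is malformed or incomplete."""


class ValidationError(LvadCeaError, ValueError):
    """A value violates a model invariant (range, sign, stochasticity)."""


class ModelError(LvadCeaError):
    """A built strategy model is internally inconsistent."""


class SupplementaryDataMissing(LvadCeaError, FileNotFoundError):
    """The user-supplied supplementary cost file is not present.

    The confidential micro-costing values are not shipped with the
    package; analyses that need them must be given the file explicitly.
    """
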