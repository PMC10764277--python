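"""Exception types shared across the package."""


class MagphenoError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(MagphenoError, ValueError):
    """A simulation or run configuration failed validation."""


class InvalidParameterError(MagphenoError, ValueError):
    """An operation received an out-of-range or unknown parameter."""


class InvalidInputError(MagphenoError, ValueError):
    """An operation received structurally invalid input data."""


class DegenerateModelError(MagphenoError, ValueError):
    """A model cannot be fitted (constant response, too few observations)."""


class RankDeficiencyError(MagphenoError, ValueError):
    """The fixed-effect design matrix is rank deficient."""


class InvalidDesignError(MagphenoError, ValueError):
    """A model design is invalid (for example a one-level grouping factor)."""


class InsufficientDataError(MagphenoError, ValueError):
    """Not enough paired observations for the requested statistic."""


class UndefinedCallError(MagphenoError, ValueError):
    """A consensus call cannot be made because every method abstained."""
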