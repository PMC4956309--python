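"""Exception hierarchy for pascreen."""


class PAScreenError(Exception):
    """Base class for all pascreen errors."""


class ConfigurationError(PAScreenError):
    """The study configuration is malformed or refers to missing columns."""


class DataError(PAScreenError):
    """The survey table violates a declared constraint (bad coding, unseen level, empty)."""


class EstimationError(PAScreenError):
    """An estimator cannot be computed (degenerate margin, separation, non-convergence)."""


class PositivityError(EstimationError):
    """A confounder stratum contains exposed respondents but no unexposed ones."""
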