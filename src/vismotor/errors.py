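"""Exception hierarchy shared across the pipeline stages."""


class VismotorError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(VismotorError):
    """An invalid configuration value; the message names the field."""


class DataIntegrityError(VismotorError):
    """Input data violates a structural invariant (e.g. errors > entered)."""


class MissingDataError(VismotorError):
    """A required record collection is empty or entirely missing."""


class UndefinedBaselineError(VismotorError):
    """A ratio's denominator is zero or otherwise undefined."""


class UndefinedRatioError(VismotorError):
    """A pre/post ratio is requested with a non-positive baseline."""


class EstimationFailureError(VismotorError):
    """A model fit cannot proceed (non-identifiable or degenerate data)."""


class ValidationError(VismotorError):
    """A table failed schema/range validation; carries the offending stage."""

    def __init__(self, stage: str, violations):
        self.stage = stage
        self.violations = list(violations)
        super().__init__(
            f"validation failed in stage '{stage}': "
            + "; ".join(str(v) for v in self.violations[:10])
        )
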