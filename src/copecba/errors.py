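"""Exception hierarchy for the cost-benefit pipeline.

The CLI maps these onto exit codes: data problems (malformed or
inconsistent input records) exit 1, configuration problems (bad unit-cost
or payment-model parameters) exit 2.
"""


class CBAError(Exception):
    """Base class for all package errors."""


class ConfigError(CBAError):
    """A unit-cost or pipeline configuration value is missing or invalid."""


class ParameterError(CBAError):
    """A function was called with an out-of-domain parameter."""


class CostingError(CBAError):
    """One or more utilization records could not be costed.

    ``failures`` holds (record identifier, reason) pairs so a whole batch
    can be reported at once instead of failing on the first bad record.
    """

    def __init__(self, message: str, failures: list[tuple[str, str]] | None = None):
        super().__init__(message)
        self.failures = failures or []


class DataError(CBAError):
    """Input records violate an integrity constraint (e.g. a dyad appears
    in both trial arms)."""
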