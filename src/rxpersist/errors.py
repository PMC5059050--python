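"""Exception hierarchy for rxpersist."""


class RxPersistError(Exception):
    """Base class for all package errors."""


class ConfigError(RxPersistError):
    """Invalid or unknown configuration values."""


class SchemaError(RxPersistError):
    """An input table does not match its documented schema."""


class NoIndexTherapyError(RxPersistError):
    """A supply schedule was requested for a patient with no fills."""


class MalformedIntervalError(RxPersistError):
    """A hospitalization interval ends before it starts."""


class ContractViolationError(RxPersistError):
    """An upstream invariant (e.g. positive daily dose) was broken."""


class CollinearityError(RxPersistError):
    """The Cox design matrix is rank deficient."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear or constant "
            f"columns: {', '.join(self.columns)}"
        )
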