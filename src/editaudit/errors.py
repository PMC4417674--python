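"""Exception taxonomy shared across the pipeline."""


class EditAuditError(ValueError):
    """Base class for all pipeline errors."""


class SizingError(EditAuditError):
    """A requested construct does not fit in the available sequence."""


class ConfigError(EditAuditError):
    """A scenario or run configuration is internally inconsistent."""


class InputError(EditAuditError):
    """Malformed input data (bad alphabet, bad interval, missing field)."""


class ContractError(EditAuditError):
    """A documented precondition between pipeline stages was violated."""
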