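"""Exception hierarchy shared by all toolrec modules."""


class ToolrecError(Exception):
    """Base class for all toolrec-specific errors."""


class FormatError(ToolrecError, ValueError):
    """An input table violates the documented TSV dialect."""


class ValidationError(ToolrecError, ValueError):
    """An argument violates an operation's precondition."""


class ContractError(ToolrecError):
    """An internal contract was violated (e.g. a cyclic graph where a DAG is required)."""


class CorruptStoreError(ToolrecError):
    """A model store is missing one of its required groups."""
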