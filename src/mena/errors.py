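"""Exception hierarchy shared across the package."""


class MenaError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MenaError, ValueError):
    """A file does not conform to its declared format."""


class DegenerateInputError(MenaError, ValueError):
    """Input is syntactically valid but statistically empty (e.g. all-zero sample)."""


class ContractError(MenaError, ValueError):
    """A documented precondition of an operation was violated."""


class DesignError(MenaError, ValueError):
    """A synthetic-data design is internally inconsistent."""
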