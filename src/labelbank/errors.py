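"""Exception hierarchy shared across the package."""


class LabelBankError(Exception):
    """Base class for package errors (user-facing, exit code 1 in the CLI)."""


class ValidationError(LabelBankError):
    """Invalid parameter or configuration value."""


class FormatError(LabelBankError):
    """A file on disk does not match the expected format."""


class ConsistencyError(LabelBankError):
    """Mutually inconsistent artifacts (e.g. image/label count mismatch)."""


class PoolError(LabelBankError):
    """Feature-pool contract violation (deficient banks, dim mismatch, ...)."""


class DataError(LabelBankError):
    """Non-finite or otherwise unusable numeric data."""
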