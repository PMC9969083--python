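"""Exception hierarchy shared across the package."""


class CpetError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CpetError):
    """A table is structurally malformed (missing column, unknown dialect, bad header)."""


class DataError(CpetError):
    """A table parses but violates a data invariant (non-monotone time, missing cell)."""


class DetectionError(CpetError):
    """An event detector could not produce an estimate (no breakpoint, no complete minute)."""


class ConfigError(CpetError):
    """A run configuration is invalid (unknown key, out-of-range value)."""
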