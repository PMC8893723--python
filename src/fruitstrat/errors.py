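"""Exception hierarchy shared across the package."""


class FruitstratError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FruitstratError):
    """A file or table violates its format contract."""


class ReconciliationError(FruitstratError):
    """Two inputs that must agree (e.g. matrix columns vs. sample design) do not."""


class ConfigError(FruitstratError):
    """A configuration value is outside its legal range."""
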