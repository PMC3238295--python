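"""Exception hierarchy shared across the pipeline."""


class OhnologForgeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OhnologForgeError):
    """Invalid simulation or analysis configuration."""


class InputError(OhnologForgeError):
    """Malformed or inconsistent input data (trees, tables, networks)."""


class ComputationError(OhnologForgeError):
    """A computation cannot proceed (e.g. zero denominator)."""
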