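"""Exception hierarchy used across the package."""


class ClonalQCError(Exception):
    """Base class for all package errors."""


class InputError(ClonalQCError):
    """A required input file is missing, unreadable, or malformed."""


class ConfigError(ClonalQCError):
    """An invalid or inconsistent configuration value."""
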