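"""Exception hierarchy shared across the package."""


class MendelscanError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MendelscanError, ValueError):
    """Invalid simulation or pipeline configuration."""


class FormatError(MendelscanError, ValueError):
    """Malformed input table or matrix."""


class AnalysisError(MendelscanError, ValueError):
    """A statistical operation received inputs it cannot analyse."""
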