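"""Exception hierarchy shared across the package."""


class CoexrankError(Exception):
    """Base class for all errors raised by coexrank."""


class LoadError(CoexrankError):
    """A file could not be parsed into a valid in-memory object."""


class ConfigError(CoexrankError):
    """A run or category configuration is inconsistent or incomplete."""


class AnalysisError(CoexrankError):
    """Inputs are well-formed but the requested computation is impossible
    (absent reference gene, zero-variance profile, bound violations, ...)."""
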