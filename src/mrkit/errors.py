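"""Exception types shared across the package."""


class MrkitError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MrkitError):
    """A configuration problem: missing column mapping, bad threshold, etc."""


class DataError(MrkitError):
    """Invalid or inconsistent input data (e.g. SNP absent from the LD matrix)."""


class EstimationError(MrkitError):
    """An estimator cannot run on the given instruments (too few, degenerate design)."""
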