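"""Exception hierarchy shared across the package."""


class PlexdiffError(Exception):
    """Base class for all package errors."""


class FormatError(PlexdiffError):
    """A file does not conform to the expected tabular schema."""


class IntegrityError(PlexdiffError):
    """Data violate a structural invariant (duplicates, negative counts...)."""


class ConfigError(PlexdiffError):
    """Invalid configuration value."""


class DesignError(PlexdiffError):
    """Study design inconsistent with the quantification data."""


class InitializationError(PlexdiffError):
    """MCMC could not be initialized (non-finite log density)."""


class ConvergenceError(PlexdiffError):
    """Convergence assessment could not be performed."""
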