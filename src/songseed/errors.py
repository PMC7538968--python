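"""Exception types shared across the package."""


class SongseedError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SongseedError):
    """A parameter value violates its documented constraints."""


class IntegrationError(SongseedError):
    """The network state became non-finite during integration."""

    def __init__(self, message: str, t_ms: float | None = None):
        super().__init__(message)
        self.t_ms = t_ms


class ScoringError(SongseedError):
    """An outcome could not be scored (e.g. empty ensemble assignments)."""


class AnalysisError(SongseedError):
    """A spike-train statistic could not be computed on the given session."""
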