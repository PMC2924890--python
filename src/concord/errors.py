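"""Exception hierarchy shared across the package."""


class ConcordError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ConcordError):
    """Invalid simulation or pipeline configuration."""


class InputError(ConcordError):
    """Malformed or inconsistent input data (files, tables, sequences)."""


class NormalizationError(ConcordError):
    """Array normalization cannot proceed (e.g. fewer than two arrays)."""


class QuantitationError(ConcordError):
    """Protein-level quantitation refused or impossible."""


class PipelineStageError(ConcordError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
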