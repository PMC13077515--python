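"""Exception hierarchy for benchmark validation and analysis failures."""


class PrimeLLMError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PrimeLLMError):
    """Input data violates a schema or value constraint."""


class GradingError(PrimeLLMError):
    """Responses cannot be graded against the supplied answer keys."""


class DegeneratePolygonError(PrimeLLMError):
    """A radar polygon needs at least three vertices to have an area."""


class AnalysisError(PrimeLLMError):
    """A statistical procedure received data it cannot handle."""
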