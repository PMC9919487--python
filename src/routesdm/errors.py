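"""Package exception types."""


class GenerationError(RuntimeError):
    """Random generation failed (e.g. no eligible cells, route retries exhausted)."""


class FitError(RuntimeError):
    """All ensemble learners failed to fit."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but degenerate for the requested statistic."""


class UndefinedCorrelationError(ValueError):
    """Correlation undefined (a map is constant); reported as missing in tables."""
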