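"""Exception hierarchy for memraft."""


class MemraftError(Exception):
    """Base class for all memraft errors."""


class FormatError(MemraftError):
    """A coordinate file does not conform to its declared dialect."""


class SchemaError(MemraftError):
    """A tabular input is missing required columns or contains invalid labels."""


class TopologyError(MemraftError):
    """Per-atom annotation is inconsistent (missing roles, radii, reference atoms)."""


class SpecError(MemraftError):
    """A generator or analysis specification violates its invariants."""


class AnalysisError(MemraftError):
    """An analysis precondition is not met (degenerate input, empty selection)."""
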