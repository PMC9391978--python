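"""Exception hierarchy for the conceptkg pipeline.

Every stage raises a subclass of :class:`ConceptKGError` so the pipeline
driver can report which stage failed and why without string matching.
"""


class ConceptKGError(Exception):
    """Base class for all conceptkg errors."""


class CorpusFormatError(ConceptKGError):
    """A corpus file or record violates the line-delimited document format."""


class ConfigError(ConceptKGError):
    """Invalid filter or pipeline configuration."""


class EmptyVocabularyError(ConceptKGError):
    """All concepts were removed by the filters."""


class ConditionAbsentError(ConceptKGError):
    """A configured condition concept occurs in no document."""


class EmptyCorpusError(ConceptKGError):
    """An operation that needs documents received none."""


class ZeroVectorError(ConceptKGError):
    """A concept's embedding vector has zero norm; cosine is undefined."""


class DegenerateMatrixError(ConceptKGError):
    """The PPMI matrix carries no structure (all zeros) and cannot be embedded."""


class SchemaError(ConceptKGError):
    """A knowledge graph violates the property-graph schema invariants."""
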