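"""Exception hierarchy for the pipeline.

Every error raised on bad input derives from :class:`GwasPathnetError` so
callers (and the CLI) can catch one type.
"""


class GwasPathnetError(Exception):
    """Base class for all package errors."""


class ConfigError(GwasPathnetError):
    """Invalid or infeasible simulation / pipeline configuration."""


class MappingError(GwasPathnetError):
    """SNP-to-gene mapping failed (e.g. unknown chromosome)."""


class AnnotationError(GwasPathnetError):
    """Inconsistent structural annotation (e.g. exon outside gene span)."""


class ClosureError(GwasPathnetError):
    """GO annotation refers to a term missing from the DAG."""


class GroupingError(GwasPathnetError):
    """Gene groups that must be disjoint overlap."""


class MatrixError(GwasPathnetError):
    """Degenerate membership matrix (e.g. empty gene universe)."""


class ReferentialIntegrityError(GwasPathnetError):
    """Evidence record refers to an unknown SNP or gene id."""
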