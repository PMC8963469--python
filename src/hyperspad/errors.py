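"""Exception hierarchy for the pipeline.

Every error a reader/operator can raise on bad input derives from
:class:`HyperspadError`, so callers can catch one type at pipeline level.
"""


class HyperspadError(Exception):
    """Base class for all package errors."""


class CorruptFileError(HyperspadError):
    """On-disk binary size disagrees with the header, or a file is truncated."""


class MetadataError(HyperspadError):
    """A required header/metadata key is missing or malformed."""


class SchemaError(HyperspadError):
    """A sample table lacks required columns or has unparseable ones."""


class IntegrityError(HyperspadError):
    """Duplicate sample keys or otherwise inconsistent table content."""


class CoverageError(HyperspadError):
    """Input spectrum does not cover the spectral support an operator needs."""


class RankDeficiencyError(HyperspadError):
    """A per-band regression cannot be fitted (degenerate panel values)."""


class UndefinedResultError(HyperspadError):
    """A quantity (red-edge position, R^2 on constant y, ...) is undefined."""
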