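"""Exception hierarchy.

All package-specific failures derive from :class:`OccutreeError` so callers
can catch one base class at pipeline boundaries.
"""


class OccutreeError(Exception):
    """Base class for all occutree errors."""


class BackboneStructureError(OccutreeError):
    """The taxonomy table is not a single rooted tree (cycle, orphan, duplicate)."""


class UnknownTaxonError(OccutreeError, KeyError):
    """A taxon id or name could not be resolved."""


class AmbiguousTaxonError(OccutreeError):
    """A name query matched more than one node at the requested rank."""


class AlgebraError(OccutreeError):
    """Tree-algebra operands are incompatible (different backbones)."""


class ParameterError(OccutreeError, ValueError):
    """An operation parameter is out of its valid range."""


class StateError(OccutreeError):
    """An operation was called before its prerequisite state was established."""


class GeometryError(OccutreeError):
    """A geometric input is degenerate or out of domain."""


class GridError(OccutreeError):
    """A grid specification is degenerate."""


class EmptyClipError(OccutreeError):
    """A raster clip polygon does not intersect the raster extent."""
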