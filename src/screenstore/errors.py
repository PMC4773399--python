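"""Exception hierarchy.

Every contract violation raises a subclass of :class:`ScreenStoreError`, so
callers (and the CLI) can distinguish contract errors (exit code 1) from
genuine bugs.
"""


class ScreenStoreError(Exception):
    """Base class for all contract errors raised by this package."""


class DanglingRefError(ScreenStoreError):
    """An ObjectRef points at a deleted or never-created object."""


class PlateFormatError(ScreenStoreError):
    """Unsupported standard plate format."""


class BoundsError(ScreenStoreError):
    """Index outside a plate grid or table row range."""


class DomainHierarchyError(ScreenStoreError):
    """Requested object type is not reachable through containment."""


class DeleteRestrictedError(ScreenStoreError):
    """Deleting an object that still has inbound links, without cascade."""


class DimensionError(ScreenStoreError):
    """Unit conversion across incompatible dimensions."""


class UnitRegistryError(ScreenStoreError):
    """Unknown or malformed unit symbol."""


class QuantityParseError(ScreenStoreError):
    """Value text does not parse as a real number."""


class AnnotationError(ScreenStoreError):
    """Malformed annotation (empty key, empty tag label, ...)."""


class SchemaError(ScreenStoreError):
    """Invalid table schema (empty, duplicate names, bad widths)."""


class TableCollisionError(ScreenStoreError):
    """Table creation at a path that already holds a table."""


class ShapeError(ScreenStoreError):
    """Ragged or incomplete row block on append."""


class ColumnTypeError(ScreenStoreError):
    """Value does not match the column kind."""


class ColumnNameError(ScreenStoreError):
    """Unknown column name."""


class ConditionError(ScreenStoreError):
    """Invalid query condition (unknown column, bad operator or literal)."""


class SheetMappingError(ScreenStoreError):
    """Bulk-annotation sheet lacks the key column."""


class SheetMatchError(ScreenStoreError):
    """A sheet row key matched no well/image and on_unmatched is 'error'."""


class SheetParseError(ScreenStoreError):
    """Malformed CSV/TSV sheet."""


class AccessError(ScreenStoreError):
    """Caller lacks permission for the attempted action."""


class PolicyError(ScreenStoreError):
    """Invalid group-policy change (e.g. lowering a level with data present)."""


class SearchQueryError(ScreenStoreError):
    """Empty or unusable search query."""


class RenderSettingsError(ScreenStoreError):
    """Invalid rendering settings (inverted window, missing channel)."""


class PlaneError(ScreenStoreError):
    """Empty or non-2D pixel plane."""
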