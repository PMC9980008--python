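"""Exception hierarchy shared across the package.

Every error raised by ngffkit derives from :class:`NgffError`, so callers
(and the CLI) can catch one type. Subclasses exist where the contract
distinguishes failure modes (conflicting metadata vs. unsupported dtype,
corrupt chunks vs. out-of-bounds requests, ...).
"""

from __future__ import annotations


class NgffError(Exception):
    """Base class for all ngffkit errors."""


class ConflictError(NgffError):
    """Target path already holds conflicting data or metadata."""


class UnsupportedDtypeError(NgffError):
    """Requested dtype code is outside the supported set."""


class UnsupportedCodecError(NgffError):
    """Requested compression codec is not available."""


class BoundsError(NgffError):
    """Requested region falls outside the array's shape."""


class EmptyRegionError(NgffError):
    """Requested region has zero extent along some axis."""


class ShapeMismatchError(NgffError):
    """Block extents disagree with the target region or template."""


class DtypeError(NgffError):
    """Value dtype cannot be coerced losslessly to the stored dtype."""


class CorruptChunkError(NgffError):
    """A chunk file could not be decoded.

    ``key`` names the offending chunk within its array.
    """

    def __init__(self, message: str, key: str | None = None):
        super().__init__(message)
        self.key = key


class NotFoundError(NgffError):
    """A named well, field, level or array does not exist."""


class DuplicateWellError(NgffError):
    """The same (row, column) well was specified twice."""


class DuplicatePlaneError(NgffError):
    """Two planes claim the same (t, c, z) coordinate."""


class FactorError(NgffError):
    """Invalid downsampling factor (non-positive, or ≠1 on a non-space axis)."""


class LevelError(NgffError):
    """Pyramid level index out of range."""


class CapacityError(NgffError):
    """Synthetic scene cannot hold the requested number of objects."""


class InvalidMetadataError(NgffError):
    """A metadata document violates the NGFF v0.4 invariants.

    ``issues`` carries the full list of :class:`~ngffkit.validate.ValidationIssue`
    objects; all violations are reported at once, not fail-fast.
    """

    def __init__(self, issues):
        self.issues = list(issues)
        codes = ", ".join(i.code for i in self.issues)
        super().__init__(f"invalid metadata: {codes}")


class InputError(NgffError):
    """Converter input could not be read."""
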