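"""NGFF v0.4 image metadata: multiscales, axes, coordinate transformations.

The multiscales document declares what an image *is*: its named axes
(time, channel, space — canonical order t, c, z, y, x; 2 to 5 axes), the
relative path of every pyramid level, and per-level scale/translation
transforms that map array indices to physical coordinates. This module
builds those documents, serializes them to the exact v0.4 attribute
shape, and parses them back with full (non-fail-fast) invariant
checking.

Documents written in another axis order are rejected rather than
silently reordered, and unknown metadata keys survive a parse/serialize
round trip untouched (forward compatibility with later drafts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .errors import InvalidMetadataError, LevelError, FactorError

__all__ = [
    "NGFF_VERSION",
    "KNOWN_SPACE_UNITS",
    "KNOWN_TIME_UNITS",
    "AxisSpec",
    "TransformSpec",
    "DatasetLevel",
    "MultiscaleDoc",
    "validate_axes",
    "build_multiscales",
    "parse_multiscales",
    "multiscales_issues",
    "effective_scale",
]

NGFF_VERSION = "0.4"

# Unit vocabulary is advisory: an unrecognized unit is a warning, never an error.
KNOWN_SPACE_UNITS = frozenset(
    """angstrom attometer centimeter decimeter exameter femtometer foot gigameter
    hectometer inch kilometer megameter meter micrometer mile millimeter nanometer
    parsec petameter picometer terameter yard yoctometer yottameter zeptometer
    zettameter""".split()
)
KNOWN_TIME_UNITS = frozenset(
    """attosecond centisecond day decisecond exasecond femtosecond hectosecond hour
    kilosecond megasecond microsecond millisecond minute nanosecond petasecond
    picosecond second terasecond yoctosecond yottasecond zeptosecond
    zettasecond""".split()
)


@dataclass(frozen=True)
class AxisSpec:
    name: str
    kind: str  # time | channel | space
    unit: str | None = None

    def to_json(self) -> dict:
        obj = {"name": self.name, "type": self.kind}
        if self.unit is not None:
            obj["unit"] = self.unit
        return obj

    @classmethod
    def from_json(cls, obj: dict) -> "AxisSpec":
        return cls(name=str(obj.get("name", "")), kind=str(obj.get("type", "")), unit=obj.get("unit"))


@dataclass(frozen=True)
class TransformSpec:
    type: str  # scale | translation
    vector: tuple[float, ...]

    def to_json(self) -> dict:
        return {"type": self.type, self.type: list(self.vector)}

    @classmethod
    def from_json(cls, obj: dict) -> "TransformSpec":
        kind = obj.get("type", "")
        vec = obj.get(kind, [])
        return cls(type=kind, vector=tuple(float(v) for v in vec) if isinstance(vec, list) else ())


@dataclass(frozen=True)
class DatasetLevel:
    path: str
    transforms: tuple[TransformSpec, ...]

    @property
    def scale(self) -> tuple[float, ...]:
        for t in self.transforms:
            if t.type == "scale":
                return t.vector
        raise LevelError(f"level {self.path!r} has no scale transform")


@dataclass
class MultiscaleDoc:
    """One image's multiscales metadata block."""

    axes: tuple[AxisSpec, ...]
    levels: tuple[DatasetLevel, ...]
    version: str = NGFF_VERSION
    name: str | None = None
    global_transforms: tuple[TransformSpec, ...] = ()
    method: str | None = None
    extras: dict = field(default_factory=dict)  # unknown keys, preserved verbatim

    # -- serialization -----------------------------------------------------
    def to_json(self) -> dict:
        obj: dict = {"version": self.version}
        if self.name is not None:
            obj["name"] = self.name
        obj["axes"] = [a.to_json() for a in self.axes]
        obj["datasets"] = [
            {
                "path": lvl.path,
                "coordinateTransformations": [t.to_json() for t in lvl.transforms],
            }
            for lvl in self.levels
        ]
        if self.global_transforms:
            obj["coordinateTransformations"] = [t.to_json() for t in self.global_transforms]
        if self.method is not None:
            obj["type"] = self.method
        obj.update(self.extras)
        return obj


def validate_axes(axes: Sequence[AxisSpec]):
    """Check the v0.4 axis invariants; returns a list of issues (empty == valid).

    Rules: 2–5 axes; unique names; kinds from {time, channel, space};
    at most one time and one channel axis; 2 or 3 space axes, contiguous
    and last; canonical order time, channel, space. Unknown units are
    warnings only.
    """
    from .validate import ValidationIssue  # late import: validate depends on this module

    issues: list[ValidationIssue] = []
    n = len(axes)
    if not 2 <= n <= 5:
        issues.append(
            ValidationIssue("AXIS_COUNT", "error", "", f"axis count {n} outside 2-5")
        )
        return issues

    kinds = [a.kind for a in axes]
    names = [a.name for a in axes]
    order_ok = True
    if len(set(names)) != n:
        order_ok = False
        issues.append(ValidationIssue("AXIS_ORDER", "error", "", "axis names are not unique"))
    if any(k not in ("time", "channel", "space") for k in kinds):
        bad = [k for k in kinds if k not in ("time", "channel", "space")]
        issues.append(
            ValidationIssue("AXIS_ORDER", "error", "", f"unknown axis type(s) {bad}")
        )
        return issues
    n_time = kinds.count("time")
    n_chan = kinds.count("channel")
    n_space = kinds.count("space")
    if n_time > 1 or n_chan > 1:
        issues.append(
            ValidationIssue(
                "AXIS_ORDER", "error", "", f"{n_time} time and {n_chan} channel axes (max 1 each)"
            )
        )
        order_ok = False
    if not 2 <= n_space <= 3:
        issues.append(
            ValidationIssue("AXIS_ORDER", "error", "", f"{n_space} space axes (need 2 or 3)")
        )
        order_ok = False
    canonical = ["time"] * min(n_time, 1) + ["channel"] * min(n_chan, 1) + ["space"] * n_space
    if order_ok and kinds != canonical:
        issues.append(
            ValidationIssue(
                "AXIS_ORDER",
                "error",
                "",
                f"axis kinds {kinds} not in canonical time, channel, space order",
            )
        )
    for a in axes:
        if a.unit is None:
            continue
        vocab = KNOWN_TIME_UNITS if a.kind == "time" else KNOWN_SPACE_UNITS
        if a.kind in ("time", "space") and a.unit not in vocab:
            issues.append(
                ValidationIssue(
                    "UNKNOWN_UNIT", "warning", "", f"axis {a.name!r}: unrecognized unit {a.unit!r}"
                )
            )
    return issues


def build_multiscales(
    axes: Sequence[AxisSpec],
    n_levels: int,
    base_scale: Sequence[float],
    factors: Sequence[int],
    method: str | None = None,
    name: str | None = None,
) -> MultiscaleDoc:
    """Construct a pyramid document: level ``i`` at path ``str(i)`` with
    scale ``base_scale * factors**i`` elementwise.

    Downsampling factors must be 1 on time and channel axes — a pyramid
    reduces spatial detail, never timepoints or channels.
    """
    axes = tuple(axes)
    issues = [i for i in validate_axes(axes) if i.severity == "error"]
    if issues:
        raise InvalidMetadataError(issues)
    if n_levels < 1:
        raise LevelError(f"n_levels must be >= 1, got {n_levels}")
    if len(base_scale) != len(axes) or len(factors) != len(axes):
        raise InvalidMetadataError(
            [_issue("TRANSFORM_LENGTH", f"base_scale/factors length must equal axis count {len(axes)}")]
        )
    if any(s <= 0 for s in base_scale):
        raise InvalidMetadataError([_issue("MISSING_SCALE", "scale entries must be positive")])
    for a, f in zip(axes, factors):
        if f < 1:
            raise FactorError(f"factor {f} on axis {a.name!r} must be >= 1")
        if a.kind in ("time", "channel") and f != 1:
            raise FactorError(f"factor must be 1 on {a.kind} axis {a.name!r}, got {f}")
    levels = []
    for i in range(n_levels):
        scale = tuple(float(s) * float(f) ** i for s, f in zip(base_scale, factors))
        levels.append(DatasetLevel(path=str(i), transforms=(TransformSpec("scale", scale),)))
    return MultiscaleDoc(axes=axes, levels=tuple(levels), method=method, name=name)


def _issue(code: str, message: str, path: str = ""):
    from .validate import ValidationIssue

    return ValidationIssue(code, "error", path, message)


_KNOWN_KEYS = {"version", "name", "axes", "datasets", "coordinateTransformations", "type", "metadata"}


def multiscales_issues(obj, path: str = "") -> list:
    """All invariant violations in one parsed multiscales entry (non-fail-fast)."""
    from .validate import ValidationIssue

    issues: list[ValidationIssue] = []
    if not isinstance(obj, dict):
        return [ValidationIssue("BAD_JSON", "error", path, "multiscales entry is not an object")]
    if obj.get("version") != NGFF_VERSION:
        issues.append(
            ValidationIssue(
                "BAD_VERSION", "error", path, f"version {obj.get('version')!r}, expected {NGFF_VERSION!r}"
            )
        )
    axes_json = obj.get("axes")
    axes = tuple(AxisSpec.from_json(a) for a in axes_json) if isinstance(axes_json, list) else ()
    axis_issues = validate_axes(axes)
    for iss in axis_issues:
        issues.append(ValidationIssue(iss.code, iss.severity, path, iss.message))
    if any(i.code == "AXIS_COUNT" for i in axis_issues):
        # rank itself is wrong; transform-length checks against it would be noise
        return issues
    n_axes = len(axes)

    datasets = obj.get("datasets")
    if not isinstance(datasets, list) or not datasets:
        issues.append(ValidationIssue("MISSING_SCALE", "error", path, "no datasets listed"))
        return issues
    for k, ds in enumerate(datasets):
        where = f"{path}/datasets/{k}" if path else f"datasets/{k}"
        transforms = ds.get("coordinateTransformations", []) if isinstance(ds, dict) else []
        issues.extend(_transform_issues(transforms, n_axes, where, require_scale=True))
    issues.extend(
        _transform_issues(
            obj.get("coordinateTransformations", []), n_axes, path, require_scale=False
        )
    )
    return issues


def _transform_issues(transforms, n_axes: int, where: str, require_scale: bool) -> list:
    from .validate import ValidationIssue

    issues = []
    parsed = [TransformSpec.from_json(t) for t in transforms if isinstance(t, dict)]
    scales = [t for t in parsed if t.type == "scale"]
    if require_scale and (not parsed or parsed[0].type != "scale" or not scales):
        issues.append(
            ValidationIssue("MISSING_SCALE", "error", where, "first transform must be a scale")
        )
    if sum(1 for t in parsed if t.type == "translation") > 1:
        issues.append(
            ValidationIssue("BAD_JSON", "error", where, "at most one translation transform allowed")
        )
    for t in parsed:
        if t.type not in ("scale", "translation"):
            issues.append(
                ValidationIssue("BAD_JSON", "error", where, f"unknown transform type {t.type!r}")
            )
            continue
        if len(t.vector) != n_axes:
            issues.append(
                ValidationIssue(
                    "TRANSFORM_LENGTH",
                    "error",
                    where,
                    f"{t.type} vector length {len(t.vector)} != axis count {n_axes}",
                )
            )
        if t.type == "scale" and any(v <= 0 for v in t.vector):
            issues.append(
                ValidationIssue("MISSING_SCALE", "error", where, "scale entries must be > 0")
            )
    return issues


def parse_multiscales(obj: dict) -> MultiscaleDoc:
    """Parse one multiscales entry; raises with *all* violations at once."""
    issues = [i for i in multiscales_issues(obj) if i.severity == "error"]
    if issues:
        raise InvalidMetadataError(issues)
    axes = tuple(AxisSpec.from_json(a) for a in obj["axes"])
    levels = tuple(
        DatasetLevel(
            path=str(ds["path"]),
            transforms=tuple(
                TransformSpec.from_json(t) for t in ds.get("coordinateTransformations", [])
            ),
        )
        for ds in obj["datasets"]
    )
    global_transforms = tuple(
        TransformSpec.from_json(t) for t in obj.get("coordinateTransformations", [])
    )
    extras = {k: v for k, v in obj.items() if k not in _KNOWN_KEYS}
    return MultiscaleDoc(
        axes=axes,
        levels=levels,
        version=obj["version"],
        name=obj.get("name"),
        global_transforms=global_transforms,
        method=obj.get("type"),
        extras=extras,
    )


def effective_scale(doc: MultiscaleDoc, level_index: int) -> tuple[float, ...]:
    """Physical step per array index at one level: the elementwise product
    of all global scale transforms and the level's own scale. Translations
    shift the origin and never change the step."""
    if not 0 <= level_index < len(doc.levels):
        raise LevelError(f"level {level_index} out of range [0, {len(doc.levels)})")
    step = list(doc.levels[level_index].scale)
    for t in doc.global_transforms:
        if t.type == "scale":
            step = [a * b for a, b in zip(step, t.vector)]
    return tuple(step)
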