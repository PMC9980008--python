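"""Structural and schema validation of OME-Zarr stores, plus size summaries.

``validate`` walks a store, checks every JSON document against the
in-repo v0.4 schema texts (see ``schemas/``; authored for this package,
see the note in each file) and against the structural invariants the
schemas cannot express (level shapes non-increasing, dtype consistency
across levels, chunk decodability sampling, plate path algebra, label
dtype and source resolution). It never fails fast: the report lists
every issue found. ``summarize`` computes the per-image size statistics
a curator wants before committing to a transfer: shapes per level,
chunk counts, raw bytes (shape x dtype width) and bytes actually stored.

Severity policy: metadata violations are errors; unrecognized units are
warnings (the unit vocabulary is advisory). A defective document
short-circuits the checks that depend on it, so one defect yields one
code, not a cascade.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator

import numpy as np

from . import ngff
from .chunkstore import ArraySpec, decode_chunk
from .errors import CorruptChunkError, NgffError

__all__ = [
    "ISSUE_CODES",
    "ValidationIssue",
    "ValidationReport",
    "LevelSummary",
    "ImageSummary",
    "StoreSummary",
    "validate",
    "summarize",
]

#: The validator's issue catalog. Every code has a defect-injection
#: counterpart in :mod:`ngffkit.synth`.
ISSUE_CODES = (
    "MISSING_GROUP_META",
    "MISSING_ARRAY_META",
    "BAD_JSON",
    "BAD_VERSION",
    "AXIS_COUNT",
    "AXIS_ORDER",
    "TRANSFORM_LENGTH",
    "MISSING_SCALE",
    "LEVEL_PATH_MISSING",
    "NONDECREASING_LEVELS",
    "DTYPE_INCONSISTENT",
    "CHUNK_UNDECODABLE",
    "WELL_PATH_MISMATCH",
    "WELL_INDEX_RANGE",
    "LABEL_DTYPE",
    "LABEL_SOURCE_MISSING",
    "UNKNOWN_UNIT",
)


@dataclass(frozen=True)
class ValidationIssue:
    code: str
    severity: str  # error | warning
    path: str
    message: str


@dataclass
class ValidationReport:
    root: str
    profile: str
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    @property
    def exit_status(self) -> int:
        if any(i.code == "UNREADABLE" for i in self.issues):
            return 2
        return 1 if self.errors else 0

    def codes(self) -> set[str]:
        return {i.code for i in self.issues}

    def to_json(self) -> dict:
        return {
            "root": self.root,
            "profile": self.profile,
            "n_errors": len(self.errors),
            "n_warnings": len(self.warnings),
            "issues": [asdict(i) for i in self.issues],
        }


# ---------------------------------------------------------------------------
# Minimal JSON-Schema subset checker.
#
# Supports exactly the keywords the in-repo schema documents use: type,
# properties, required, items, enum, const, minItems, maxItems, minimum,
# maximum. Returns (pointer, keyword, message) triples.

_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "number": (int, float),
    "boolean": bool,
    "null": type(None),
}


def _schema_check(instance, schema: dict, pointer: str = "") -> list[tuple[str, str, str]]:
    out: list[tuple[str, str, str]] = []
    t = schema.get("type")
    if t is not None:
        py = _TYPES[t]
        ok = isinstance(instance, py) and not (t in ("integer", "number") and isinstance(instance, bool))
        if not ok:
            out.append((pointer, "type", f"expected {t}, got {type(instance).__name__}"))
            return out
    if "const" in schema and instance != schema["const"]:
        out.append((pointer, "const", f"expected {schema['const']!r}, got {instance!r}"))
    if "enum" in schema and instance not in schema["enum"]:
        out.append((pointer, "enum", f"{instance!r} not one of {schema['enum']}"))
    if isinstance(instance, dict):
        for key in schema.get("required", []):
            if key not in instance:
                out.append((pointer, "required", f"missing required key {key!r}"))
        for key, sub in schema.get("properties", {}).items():
            if key in instance:
                out.extend(_schema_check(instance[key], sub, f"{pointer}/{key}"))
    if isinstance(instance, list):
        if "minItems" in schema and len(instance) < schema["minItems"]:
            out.append((pointer, "minItems", f"{len(instance)} items, need >= {schema['minItems']}"))
        if "maxItems" in schema and len(instance) > schema["maxItems"]:
            out.append((pointer, "maxItems", f"{len(instance)} items, need <= {schema['maxItems']}"))
        if "items" in schema:
            for k, item in enumerate(instance):
                out.extend(_schema_check(item, schema["items"], f"{pointer}/{k}"))
    if isinstance(instance, (int, float)) and not isinstance(instance, bool):
        if "minimum" in schema and instance < schema["minimum"]:
            out.append((pointer, "minimum", f"{instance} < {schema['minimum']}"))
        if "maximum" in schema and instance > schema["maximum"]:
            out.append((pointer, "maximum", f"{instance} > {schema['maximum']}"))
    return out


def _load_schema(name: str) -> dict:
    path = Path(__file__).parent / "schemas" / f"{name}.synthetic.schema.json"
    return json.loads(path.read_text(encoding="utf-8"))


def _schema_issues(instance, schema_name: str, where: str) -> list[ValidationIssue]:
    """Schema violations mapped onto the issue catalog.

    Version mismatches and axis-count bounds are also caught (with better
    messages) by the structural checks, so those keywords are skipped here
    to keep one defect mapped to one code.
    """
    issues = []
    for pointer, keyword, message in _schema_check(instance, _load_schema(schema_name)):
        if keyword == "const" and pointer.endswith("/version"):
            continue
        if keyword in ("minItems", "maxItems") and pointer.endswith("/axes"):
            continue
        issues.append(
            ValidationIssue("BAD_JSON", "error", f"{where}{pointer}", f"schema: {message}")
        )
    return issues


# ---------------------------------------------------------------------------
# Store walking


def _read_json(path: Path):
    """Returns (obj, issue); exactly one is None."""
    try:
        return json.loads(path.read_text(encoding="utf-8")), None
    except FileNotFoundError:
        return None, None
    except (OSError, ValueError) as exc:
        rel = str(path)
        return None, ValidationIssue("BAD_JSON", "error", rel, f"unparseable JSON: {exc}")


def _prefix(issue: ValidationIssue, gpath: str) -> ValidationIssue:
    path = f"{gpath}/{issue.path}" if issue.path else gpath
    return ValidationIssue(issue.code, issue.severity, path, issue.message)


def _validate_image_group(root: Path, gpath: str, issues: list[ValidationIssue]) -> None:
    gdir = root / gpath if gpath else root
    if not (gdir / ".zgroup").exists():
        issues.append(
            ValidationIssue("MISSING_GROUP_META", "error", gpath, "group has no .zgroup marker")
        )
    attrs, bad = _read_json(gdir / ".zattrs")
    if bad is not None:
        issues.append(ValidationIssue(bad.code, bad.severity, gpath or ".", bad.message))
        return  # nothing downstream is meaningful with unreadable attributes
    if attrs is None or "multiscales" not in attrs:
        issues.append(
            ValidationIssue("BAD_JSON", "error", gpath or ".", "image group has no multiscales attribute")
        )
        return
    issues.extend(_schema_issues(attrs, "image", gpath))
    ms = attrs["multiscales"]
    if not isinstance(ms, list) or not ms:
        return
    doc_issues = ngff.multiscales_issues(ms[0], gpath)
    issues.extend(doc_issues)
    if any(i.severity == "error" for i in doc_issues):
        return  # level checks would cascade off a broken document

    datasets = ms[0].get("datasets", [])
    level_specs: list[tuple[str, ArraySpec]] = []
    axes = [ngff.AxisSpec.from_json(a) for a in ms[0].get("axes", [])]
    for ds in datasets:
        lvl_path = str(ds.get("path", ""))
        lvl_rel = f"{gpath}/{lvl_path}" if gpath else lvl_path
        lvl_dir = root / lvl_rel
        if not lvl_dir.is_dir():
            issues.append(
                ValidationIssue("LEVEL_PATH_MISSING", "error", lvl_rel, "dataset path has no array")
            )
            continue
        meta, bad = _read_json(lvl_dir / ".zarray")
        if bad is not None:
            issues.append(ValidationIssue(bad.code, bad.severity, lvl_rel, bad.message))
            continue
        if meta is None:
            issues.append(
                ValidationIssue("MISSING_ARRAY_META", "error", lvl_rel, "array has no .zarray file")
            )
            continue
        try:
            spec = ArraySpec.from_zarray(meta)
        except NgffError as exc:
            issues.append(ValidationIssue("BAD_JSON", "error", lvl_rel, str(exc)))
            continue
        level_specs.append((lvl_rel, spec))

    # cross-level structure
    for (prev_rel, prev), (cur_rel, cur) in zip(level_specs, level_specs[1:]):
        if cur.dtype_code != prev.dtype_code:
            issues.append(
                ValidationIssue(
                    "DTYPE_INCONSISTENT",
                    "error",
                    cur_rel,
                    f"dtype {cur.dtype_code} differs from previous level {prev.dtype_code}",
                )
            )
        if len(cur.shape) != len(prev.shape):
            issues.append(
                ValidationIssue(
                    "NONDECREASING_LEVELS", "error", cur_rel, "level ranks differ"
                )
            )
            continue
        grew = [c > p for c, p in zip(cur.shape, prev.shape)]
        space_flags = [a.kind == "space" for a in axes] if len(axes) == len(cur.shape) else [True] * len(cur.shape)
        space_prev = [p for p, s in zip(prev.shape, space_flags) if s]
        space_cur = [c for c, s in zip(cur.shape, space_flags) if s]
        if any(grew):
            issues.append(
                ValidationIssue(
                    "NONDECREASING_LEVELS",
                    "error",
                    cur_rel,
                    f"shape {cur.shape} exceeds previous level {prev.shape}",
                )
            )
        elif space_cur == space_prev and any(p > 1 for p in space_prev):
            issues.append(
                ValidationIssue(
                    "NONDECREASING_LEVELS",
                    "error",
                    cur_rel,
                    f"no spatial reduction from previous level {prev.shape}",
                )
            )

    # chunk decodability sampling: first 3 chunk files per level, sorted
    for lvl_rel, spec in level_specs:
        lvl_dir = root / lvl_rel
        files = sorted(
            p for p in lvl_dir.rglob("*") if p.is_file() and not p.name.startswith(".")
        )
        for chunk_file in files[:3]:
            try:
                decode_chunk(chunk_file.read_bytes(), spec)
            except CorruptChunkError as exc:
                key = str(chunk_file.relative_to(lvl_dir))
                issues.append(
                    ValidationIssue(
                        "CHUNK_UNDECODABLE", "error", f"{lvl_rel}/{key}", str(exc)
                    )
                )

    _validate_labels(root, gpath, level_specs, axes, issues)


def _validate_labels(root: Path, gpath: str, level_specs, axes, issues) -> None:
    labels_rel = f"{gpath}/labels" if gpath else "labels"
    labels_dir = root / labels_rel
    if not labels_dir.is_dir():
        return
    lattrs, bad = _read_json(labels_dir / ".zattrs")
    if bad is not None:
        issues.append(ValidationIssue(bad.code, bad.severity, labels_rel, bad.message))
        return
    names = (lattrs or {}).get("labels", [])
    for name in names:
        lrel = f"{labels_rel}/{name}"
        before = len(issues)
        _validate_image_group(root, lrel, issues)
        if len(issues) > before and any(
            i.severity == "error" for i in issues[before:]
        ):
            continue
        lattrs2, _ = _read_json(root / lrel / ".zattrs")
        lattrs2 = lattrs2 or {}
        issues.extend(_schema_issues(lattrs2, "label", lrel))
        meta, _ = _read_json(root / lrel / "0" / ".zarray")
        if meta is not None:
            try:
                spec = ArraySpec.from_zarray(meta)
                if spec.dtype.kind not in "iu":
                    issues.append(
                        ValidationIssue(
                            "LABEL_DTYPE",
                            "error",
                            f"{lrel}/0",
                            f"label dtype {spec.dtype_code} is not integer",
                        )
                    )
            except NgffError:
                pass
        src = (lattrs2.get("image-label") or {}).get("source", {}).get("image", "../../")
        target = (root / lrel / src).resolve()
        tattrs, _ = _read_json(target / ".zattrs")
        if tattrs is None or "multiscales" not in tattrs:
            issues.append(
                ValidationIssue(
                    "LABEL_SOURCE_MISSING",
                    "error",
                    lrel,
                    f"label source {src!r} does not resolve to an image",
                )
            )


def _validate_plate(root: Path, issues: list[ValidationIssue]) -> None:
    if not (root / ".zgroup").exists():
        issues.append(
            ValidationIssue("MISSING_GROUP_META", "error", "", "plate group has no .zgroup marker")
        )
    attrs, bad = _read_json(root / ".zattrs")
    if bad is not None:
        issues.append(bad if bad.path else ValidationIssue(bad.code, bad.severity, ".", bad.message))
        return
    attrs = attrs or {}
    issues.extend(_schema_issues(attrs, "plate", ""))
    plate = attrs.get("plate")
    if not isinstance(plate, dict):
        return
    if plate.get("version") != ngff.NGFF_VERSION:
        issues.append(
            ValidationIssue(
                "BAD_VERSION", "error", ".", f"plate version {plate.get('version')!r}"
            )
        )
    rows = [r.get("name") for r in plate.get("rows", []) if isinstance(r, dict)]
    cols = [c.get("name") for c in plate.get("columns", []) if isinstance(c, dict)]
    for w in plate.get("wells", []):
        if not isinstance(w, dict):
            continue
        path = w.get("path", "")
        ri, ci = w.get("rowIndex"), w.get("columnIndex")
        if not (isinstance(ri, int) and 0 <= ri < len(rows)) or not (
            isinstance(ci, int) and 0 <= ci < len(cols)
        ):
            issues.append(
                ValidationIssue(
                    "WELL_INDEX_RANGE",
                    "error",
                    path,
                    f"well indices ({ri}, {ci}) outside {len(rows)}x{len(cols)} grid",
                )
            )
            continue
        expected = f"{rows[ri]}/{cols[ci]}"
        if path != expected or not (root / path / ".zattrs").exists():
            issues.append(
                ValidationIssue(
                    "WELL_PATH_MISMATCH",
                    "error",
                    path,
                    f"well path {path!r} does not match grid position {expected!r}",
                )
            )
            continue
        wattrs, bad = _read_json(root / path / ".zattrs")
        if bad is not None:
            issues.append(ValidationIssue(bad.code, bad.severity, path, bad.message))
            continue
        wattrs = wattrs or {}
        issues.extend(
            _prefix(i, path) for i in _schema_issues(wattrs, "well", "")
        )
        well = wattrs.get("well")
        if not isinstance(well, dict):
            continue
        if well.get("version") != ngff.NGFF_VERSION:
            issues.append(
                ValidationIssue("BAD_VERSION", "error", path, f"well version {well.get('version')!r}")
            )
        for img in well.get("images", []):
            if isinstance(img, dict) and "path" in img:
                _validate_image_group(root, f"{path}/{img['path']}", issues)


def validate(root, profile: str = "auto") -> ValidationReport:
    """Validate a store; returns a complete (non-fail-fast) report."""
    rootp = Path(root)
    report = ValidationReport(root=str(root), profile=profile)
    try:
        if not rootp.is_dir():
            raise OSError(f"{root} is not a directory")
        attrs, bad = _read_json(rootp / ".zattrs")
    except OSError as exc:
        report.issues.append(ValidationIssue("UNREADABLE", "error", "", str(exc)))
        return report
    if profile == "auto":
        profile = "plate" if attrs and "plate" in attrs else "image"
        report.profile = profile
    if profile == "plate":
        _validate_plate(rootp, report.issues)
    else:
        _validate_image_group(rootp, "", report.issues)
    return report


# ---------------------------------------------------------------------------
# Size summary


@dataclass
class LevelSummary:
    path: str
    shape: tuple[int, ...]
    chunk_shape: tuple[int, ...]
    chunk_count: int
    raw_bytes: int


@dataclass
class ImageSummary:
    path: str
    axes: tuple[str, ...]
    dtype: str
    levels: list[LevelSummary]

    @property
    def raw_bytes(self) -> int:
        return sum(l.raw_bytes for l in self.levels)

    @property
    def chunk_count(self) -> int:
        return sum(l.chunk_count for l in self.levels)


@dataclass
class StoreSummary:
    root: str
    images: list[ImageSummary]
    stored_bytes: int

    @property
    def raw_bytes(self) -> int:
        return sum(img.raw_bytes for img in self.images)

    @property
    def raw_terabytes(self) -> float:
        return self.raw_bytes / 1e12

    @property
    def raw_terabytes_rounded(self) -> int:
        return round(self.raw_terabytes)

    def to_json(self) -> dict:
        return {
            "root": self.root,
            "raw_bytes": self.raw_bytes,
            "raw_terabytes": self.raw_terabytes,
            "raw_terabytes_rounded": self.raw_terabytes_rounded,
            "stored_bytes": self.stored_bytes,
            "images": [
                {
                    "path": img.path,
                    "axes": list(img.axes),
                    "dtype": img.dtype,
                    "raw_bytes": img.raw_bytes,
                    "chunk_count": img.chunk_count,
                    "levels": [
                        {
                            "path": l.path,
                            "shape": list(l.shape),
                            "chunks": list(l.chunk_shape),
                            "chunk_count": l.chunk_count,
                            "raw_bytes": l.raw_bytes,
                        }
                        for l in img.levels
                    ],
                }
                for img in self.images
            ],
        }


def _iter_image_groups(root: Path) -> Iterator[str]:
    for zattrs in sorted(root.rglob(".zattrs")):
        obj, _ = _read_json(zattrs)
        if obj and "multiscales" in obj:
            rel = str(zattrs.parent.relative_to(root))
            yield "" if rel == "." else rel


def summarize(root) -> StoreSummary:
    """Size and shape statistics for every image in a store.

    ``raw_bytes`` is the uncompressed payload (product of shape times
    dtype width, summed over levels) — a metadata-only store still gets
    the full figure. ``stored_bytes`` counts the chunk files actually on
    disk.
    """
    rootp = Path(root)
    images = []
    stored = 0
    for gpath in _iter_image_groups(rootp):
        gdir = rootp / gpath if gpath else rootp
        attrs, _ = _read_json(gdir / ".zattrs")
        ms = (attrs or {}).get("multiscales", [{}])[0]
        axes = tuple(a.get("name", "?") for a in ms.get("axes", []))
        levels = []
        dtype = "?"
        for ds in ms.get("datasets", []):
            lvl_rel = str(ds.get("path", ""))
            meta, _ = _read_json(gdir / lvl_rel / ".zarray")
            if meta is None:
                continue
            shape = tuple(int(s) for s in meta["shape"])
            chunks = tuple(int(c) for c in meta["chunks"])
            dtype = meta["dtype"]
            width = np.dtype(dtype).itemsize
            chunk_count = 1
            for s, c in zip(shape, chunks):
                chunk_count *= -(-s // c)
            raw = width
            for s in shape:
                raw *= s
            levels.append(
                LevelSummary(
                    path=lvl_rel,
                    shape=shape,
                    chunk_shape=chunks,
                    chunk_count=chunk_count,
                    raw_bytes=raw,
                )
            )
            lvl_dir = gdir / lvl_rel
            if lvl_dir.is_dir():
                stored += sum(
                    p.stat().st_size
                    for p in lvl_dir.rglob("*")
                    if p.is_file() and not p.name.startswith(".")
                )
        images.append(ImageSummary(path=gpath or ".", axes=axes, dtype=dtype, levels=levels))
    return StoreSummary(root=str(root), images=images, stored_bytes=stored)
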