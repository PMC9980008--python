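"""High-content-screening plate layout and label-image attachment.

A plate is a group hierarchy: the plate group's attributes name the rows
and columns, each acquired well lives at ``<row>/<column>`` with its own
well document, and each field of view within a well is a full multiscale
image at ``<row>/<column>/<field>``. Segmentations ride along as integer
label images under ``<image>/labels/<name>``, beside the raw image they
were derived from, each with color/source metadata.

``render_plate_montage`` produces the classic plate overview: a mosaic
of one low-resolution plane per field, wells on the plate grid, fields
packed row-major into the smallest near-square grid. Missing wells and
never-written fields render as the fill value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import chunkstore, image as image_mod, ngff, pyramid
from .chunkstore import ArraySpec, CompressorSpec
from .errors import (
    DtypeError,
    DuplicateWellError,
    NotFoundError,
    ShapeMismatchError,
)

__all__ = [
    "PlateDoc",
    "WellDoc",
    "ImageTemplate",
    "default_row_names",
    "default_column_names",
    "create_plate",
    "open_plate",
    "write_field",
    "read_field",
    "render_plate_montage",
    "attach_labels",
]


def default_row_names(n: int) -> list[str]:
    """A, B, C, ... (microtiter convention)."""
    return [chr(ord("A") + i) for i in range(n)]


def default_column_names(n: int) -> list[str]:
    """1, 2, 3, ..."""
    return [str(i + 1) for i in range(n)]


@dataclass(frozen=True)
class WellEntry:
    path: str
    row_index: int
    column_index: int


@dataclass
class PlateDoc:
    rows: tuple[str, ...]
    columns: tuple[str, ...]
    wells: tuple[WellEntry, ...]
    version: str = ngff.NGFF_VERSION
    name: str | None = None
    field_count: int | None = None
    acquisitions: tuple[dict, ...] = ()

    def to_json(self) -> dict:
        obj: dict = {"version": self.version}
        if self.name is not None:
            obj["name"] = self.name
        if self.acquisitions:
            obj["acquisitions"] = [dict(a) for a in self.acquisitions]
        obj["rows"] = [{"name": r} for r in self.rows]
        obj["columns"] = [{"name": c} for c in self.columns]
        obj["wells"] = [
            {"path": w.path, "rowIndex": w.row_index, "columnIndex": w.column_index}
            for w in self.wells
        ]
        if self.field_count is not None:
            obj["field_count"] = self.field_count
        return obj

    @classmethod
    def from_json(cls, obj: dict) -> "PlateDoc":
        return cls(
            rows=tuple(r["name"] for r in obj.get("rows", [])),
            columns=tuple(c["name"] for c in obj.get("columns", [])),
            wells=tuple(
                WellEntry(w["path"], int(w["rowIndex"]), int(w["columnIndex"]))
                for w in obj.get("wells", [])
            ),
            version=obj.get("version", ""),
            name=obj.get("name"),
            field_count=obj.get("field_count"),
            acquisitions=tuple(obj.get("acquisitions", [])),
        )


@dataclass
class WellDoc:
    images: tuple[dict, ...]  # each {"path": "0"} (+ optional "acquisition")
    version: str = ngff.NGFF_VERSION

    def to_json(self) -> dict:
        return {"version": self.version, "images": [dict(i) for i in self.images]}

    @classmethod
    def from_json(cls, obj: dict) -> "WellDoc":
        return cls(
            images=tuple(obj.get("images", [])),
            version=obj.get("version", ""),
        )


@dataclass(frozen=True)
class ImageTemplate:
    """Per-field image layout shared by every field of a plate."""

    shape: tuple[int, ...]
    dtype_code: str = "<u2"
    chunk_shape: tuple[int, ...] | None = None
    axes: tuple[ngff.AxisSpec, ...] | None = None
    compressor: CompressorSpec = dc_field(default_factory=CompressorSpec)
    fill_value: float | int = 0
    n_levels: int = 1
    method: str = "mean"

    def resolved_axes(self) -> tuple[ngff.AxisSpec, ...]:
        return self.axes if self.axes is not None else pyramid.default_axes(len(self.shape))

    def array_spec(self) -> ArraySpec:
        axes = self.resolved_axes()
        chunks = self.chunk_shape
        if chunks is None:
            chunks = tuple(
                1 if a.kind in ("time", "channel") else min(int(s), 256)
                for a, s in zip(axes, self.shape)
            )
        return ArraySpec(
            shape=self.shape,
            chunk_shape=chunks,
            dtype_code=self.dtype_code,
            fill_value=self.fill_value,
            compressor=self.compressor,
        )


def _level_shape(shape, axes, factors, level):
    out = list(shape)
    for _ in range(level):
        out = [
            -(-n // f) for n, f in zip(out, factors)
        ]
    return tuple(out)


def create_plate(
    root,
    row_names: Sequence[str],
    column_names: Sequence[str],
    wells: Sequence[tuple[str, str]] | None = None,
    fields_per_well: int = 1,
    image_template: ImageTemplate | None = None,
    name: str | None = None,
) -> PlateDoc:
    """Lay out a plate store: plate document, well groups, field image groups.

    Every field image gets its multiscales document and (sparse) level
    arrays up front, so an unwritten field is still a valid image that
    reads back as fill value. Re-running with identical arguments is a
    byte-for-byte no-op.
    """
    row_names = list(row_names)
    column_names = list(column_names)
    if len(set(row_names)) != len(row_names) or len(set(column_names)) != len(column_names):
        raise DuplicateWellError("row/column names must be unique")
    if wells is None:
        wells = [(r, c) for r in row_names for c in column_names]
    if not wells:
        raise DuplicateWellError("plate must have at least one well")
    seen = set()
    entries = []
    for r, c in wells:
        if (r, c) in seen:
            raise DuplicateWellError(f"duplicate well ({r}, {c})")
        seen.add((r, c))
        if r not in row_names or c not in column_names:
            raise NotFoundError(f"well ({r}, {c}) not on the plate grid")
        entries.append(WellEntry(f"{r}/{c}", row_names.index(r), column_names.index(c)))
    entries.sort(key=lambda w: (w.row_index, w.column_index))
    if image_template is None:
        image_template = ImageTemplate(shape=(1, 1, 1, 64, 64))

    doc = PlateDoc(
        rows=tuple(row_names),
        columns=tuple(column_names),
        wells=tuple(entries),
        field_count=fields_per_well,
        name=name,
    )
    plate_group = chunkstore.init_group(root, "")
    attrs = chunkstore.read_attributes(plate_group)
    attrs["plate"] = doc.to_json()
    chunkstore.write_attributes(plate_group, attrs)

    axes = image_template.resolved_axes()
    factors = tuple(1 if a.kind in ("time", "channel") else 2 for a in axes)
    ms_doc = ngff.build_multiscales(
        axes, image_template.n_levels, (1.0,) * len(axes), factors, method=image_template.method
    )
    base_spec = image_template.array_spec()
    for w in entries:
        well_group = chunkstore.init_group(root, w.path)
        well_doc = WellDoc(images=tuple({"path": str(i)} for i in range(fields_per_well)))
        wattrs = chunkstore.read_attributes(well_group)
        wattrs["well"] = well_doc.to_json()
        chunkstore.write_attributes(well_group, wattrs)
        for f in range(fields_per_well):
            fpath = f"{w.path}/{f}"
            fgroup = chunkstore.init_group(root, fpath)
            for lvl in range(image_template.n_levels):
                shape = _level_shape(base_spec.shape, axes, factors, lvl)
                chunkstore.init_array(
                    root,
                    f"{fpath}/{lvl}",
                    ArraySpec(
                        shape=shape,
                        chunk_shape=tuple(min(c, s) for c, s in zip(base_spec.chunk_shape, shape)),
                        dtype_code=base_spec.dtype_code,
                        fill_value=base_spec.fill_value,
                        compressor=base_spec.compressor,
                    ),
                )
            fattrs = chunkstore.read_attributes(fgroup)
            fattrs["multiscales"] = [ms_doc.to_json()]
            chunkstore.write_attributes(fgroup, fattrs)
    return doc


def open_plate(root) -> PlateDoc:
    attrs = chunkstore.read_attributes(Path(root))
    if "plate" not in attrs:
        raise NotFoundError("no plate metadata at store root")
    return PlateDoc.from_json(attrs["plate"])


def _well_doc(root, well_path: str) -> WellDoc:
    attrs = chunkstore.read_attributes(Path(root) / well_path)
    if "well" not in attrs:
        raise NotFoundError(f"no well metadata at {well_path!r}")
    return WellDoc.from_json(attrs["well"])


def _check_field(root, well_path: str, field_index: int) -> str:
    plate = open_plate(root)
    if well_path not in {w.path for w in plate.wells}:
        raise NotFoundError(f"well {well_path!r} not in plate")
    well = _well_doc(root, well_path)
    paths = {img["path"] for img in well.images}
    if str(field_index) not in paths:
        raise NotFoundError(f"field {field_index} not in well {well_path!r}")
    return f"{well_path}/{field_index}"


def write_field(root, well_path: str, field_index: int, data: np.ndarray) -> None:
    """Write one field's level-0 data and refresh its derived levels."""
    fpath = _check_field(root, well_path, field_index)
    doc = image_mod.open_image(root, fpath)
    arr = chunkstore.open_array(root, f"{fpath}/{doc.levels[0].path}")
    arr.write(data)
    if len(doc.levels) > 1:
        factors = tuple(1 if a.kind in ("time", "channel") else 2 for a in doc.axes)
        pyramid.build_pyramid(
            root,
            fpath,
            len(doc.levels),
            pyramid.DownsampleSpec(factors=factors, method=doc.method or "mean"),
            axes=doc.axes,
            write_doc=False,
        )


def read_field(root, well_path: str, field_index: int, level: int = 0) -> np.ndarray:
    """Inverse of :func:`write_field`; never-written fields read as fill value."""
    fpath = _check_field(root, well_path, field_index)
    return image_mod.read_level(root, fpath, level)


def _plane_from_field(block: np.ndarray, axes, t: int, c: int, z: int) -> np.ndarray:
    indexer = []
    space_seen = 0
    n_space = sum(1 for a in axes if a.kind == "space")
    for a in axes:
        if a.kind == "time":
            indexer.append(min(t, block.shape[len(indexer)] - 1))
        elif a.kind == "channel":
            indexer.append(min(c, block.shape[len(indexer)] - 1))
        else:
            space_seen += 1
            if n_space == 3 and space_seen == 1:
                indexer.append(min(z, block.shape[len(indexer)] - 1))
            else:
                indexer.append(slice(None))
    plane = block[tuple(indexer)]
    if plane.ndim != 2:
        raise ShapeMismatchError(f"selection left rank {plane.ndim}, expected a 2-D plane")
    return plane


def render_plate_montage(
    root,
    level_index: int = 0,
    t: int = 0,
    c: int = 0,
    z: int = 0,
) -> np.ndarray:
    """Concatenate one low-resolution plane per field into a whole-plate mosaic.

    Output height is ``|rows| x well_tile_height`` and width
    ``|columns| x well_tile_width``, where the well tile packs the F
    fields row-major into a ``ceil(F / ceil(sqrt(F))) x ceil(sqrt(F))``
    grid. Wells absent from the plate and fields never written are
    rendered as fill value.
    """
    plate = open_plate(root)
    n_fields = plate.field_count or 1
    for w in plate.wells:
        try:
            well = _well_doc(root, w.path)
            n_fields = max(n_fields, len(well.images))
        except NotFoundError:
            continue

    # discover the per-field plane geometry at this level
    plane_shape = None
    dtype = None
    fill = 0
    offenders = []
    planes: dict[tuple[str, int], np.ndarray] = {}
    for w in plate.wells:
        try:
            well = _well_doc(root, w.path)
        except NotFoundError:
            continue
        for img in well.images:
            fpath = f"{w.path}/{img['path']}"
            try:
                doc = image_mod.open_image(root, fpath)
            except NotFoundError:
                continue
            if not 0 <= level_index < len(doc.levels):
                continue
            arr = chunkstore.open_array(root, f"{fpath}/{doc.levels[level_index].path}")
            plane = _plane_from_field(arr.read(), doc.axes, t, c, z)
            if plane_shape is None:
                plane_shape = plane.shape
                dtype = plane.dtype
                fill = arr.spec.fill_scalar
            elif plane.shape != plane_shape:
                offenders.append(f"{fpath}: {plane.shape} != {plane_shape}")
                continue
            planes[(w.path, int(img["path"]))] = plane
    if offenders:
        raise ShapeMismatchError("inconsistent field shapes: " + "; ".join(offenders))
    if plane_shape is None:
        raise NotFoundError(f"no field has a level {level_index}")

    grid_cols = math.ceil(math.sqrt(n_fields))
    grid_rows = math.ceil(n_fields / grid_cols)
    tile_h = grid_rows * plane_shape[0]
    tile_w = grid_cols * plane_shape[1]
    out = np.full((len(plate.rows) * tile_h, len(plate.columns) * tile_w), fill, dtype=dtype)
    for w in plate.wells:
        y0 = w.row_index * tile_h
        x0 = w.column_index * tile_w
        for f in range(n_fields):
            plane = planes.get((w.path, f))
            if plane is None:
                continue
            fy, fx = divmod(f, grid_cols)
            out[
                y0 + fy * plane_shape[0] : y0 + (fy + 1) * plane_shape[0],
                x0 + fx * plane_shape[1] : x0 + (fx + 1) * plane_shape[1],
            ] = plane
    return out


def attach_labels(
    root,
    image_path: str,
    label_name: str,
    labels: np.ndarray,
    colors: dict[int, Sequence[int]] | None = None,
    n_levels: int = 1,
    properties: list[dict] | None = None,
) -> None:
    """Store a segmentation as ``<image>/labels/<name>``, a multiscale
    integer image downsampled with ``mode`` (so no spurious label values
    appear at coarse levels), with color and source metadata."""
    labels = np.asarray(labels)
    if labels.dtype.kind not in "iu":
        raise DtypeError(f"label data must be integer, got {labels.dtype}")
    doc = image_mod.open_image(root, image_path)
    base = chunkstore.open_array(
        root, f"{image_path}/{doc.levels[0].path}" if image_path else doc.levels[0].path
    )
    spatial = tuple(
        s for s, a in zip(base.spec.shape, doc.axes) if a.kind == "space"
    )
    if tuple(labels.shape) != spatial:
        raise ShapeMismatchError(
            f"label shape {tuple(labels.shape)} != source spatial shape {spatial}"
        )
    space_axes = tuple(a for a in doc.axes if a.kind == "space")
    lpath = f"{image_path}/labels/{label_name}" if image_path else f"labels/{label_name}"
    label_doc: dict = {"version": ngff.NGFF_VERSION, "source": {"image": "../../"}}
    if colors:
        if len(set(colors)) != len(colors):
            raise DuplicateWellError("label-values in colors must be unique")
        label_doc["colors"] = [
            {"label-value": int(v), "rgba": [int(x) for x in rgba]}
            for v, rgba in sorted(colors.items())
        ]
    if properties:
        label_doc["properties"] = properties
    image_mod.write_multiscale_image(
        root,
        lpath,
        labels,
        axes=space_axes,
        n_levels=n_levels,
        method="mode",
        extra_attrs={"image-label": label_doc},
    )
    labels_group = chunkstore.init_group(
        root, f"{image_path}/labels" if image_path else "labels"
    )
    gattrs = chunkstore.read_attributes(labels_group)
    names = gattrs.get("labels", [])
    if label_name not in names:
        names.append(label_name)
    gattrs["labels"] = names
    chunkstore.write_attributes(labels_group, gattrs)
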