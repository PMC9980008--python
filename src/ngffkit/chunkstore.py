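"""Minimal, interoperable Zarr-v2 storage layer.

An array is a directory holding a ``.zarray`` JSON descriptor plus one
compressed file per chunk; groups are directories holding ``.zgroup``
(and optionally ``.zattrs``). Chunks are the atomic unit of I/O: a
sub-region request touches exactly the chunk files it intersects, so
large images can be read and written piecewise and in parallel.

The dialect is deliberately small — C order, no filters, seven dtype
codes, ``none``/``zlib``/``gzip``/``blosc`` codecs — but every store it
writes is readable by any conforming Zarr v2 implementation and vice
versa. Edge chunks are stored padded to the full chunk shape with the
fill value; a chunk file that does not exist reads back as fill value
(sparse stores are legal, never an error).
"""

from __future__ import annotations

import gzip as _gzip
import json
import zlib as _zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (
    BoundsError,
    ConflictError,
    CorruptChunkError,
    DtypeError,
    EmptyRegionError,
    NotFoundError,
    ShapeMismatchError,
    UnsupportedCodecError,
    UnsupportedDtypeError,
)

__all__ = [
    "SUPPORTED_DTYPES",
    "CompressorSpec",
    "ArraySpec",
    "ChunkPlanEntry",
    "chunk_plan",
    "encode_chunk",
    "decode_chunk",
    "init_group",
    "write_attributes",
    "read_attributes",
    "init_array",
    "open_array",
    "Array",
]

#: Zarr v2 dtype codes this dialect stores. Anything else is rejected
#: loudly rather than silently mis-handled.
SUPPORTED_DTYPES = ("|u1", "<u2", "<u4", "<i2", "<i4", "<f4", "<f8")

_BLOSC_SHUFFLE = {"none": 0, "byte": 1, "bit": 2}
_BLOSC_SHUFFLE_INV = {v: k for k, v in _BLOSC_SHUFFLE.items()}

Region = Sequence[tuple[int, int]]


def _blosc_codec(cname: str, clevel: int, shuffle: str):
    try:
        import numcodecs
        import numcodecs.blosc

        # single-threaded blosc keeps encoded bytes deterministic
        numcodecs.blosc.use_threads = False
        return numcodecs.Blosc(cname=cname, clevel=clevel, shuffle=_BLOSC_SHUFFLE[shuffle])
    except ImportError as exc:  # pragma: no cover - numcodecs ships with zarr
        raise UnsupportedCodecError("blosc codec requires numcodecs") from exc


@dataclass(frozen=True)
class CompressorSpec:
    """Per-chunk compression settings.

    ``codec_id`` selects the algorithm; fields irrelevant to the chosen
    codec are ignored and omitted from the serialized form so the JSON
    round-trips losslessly.
    """

    codec_id: str = "zlib"  # none | zlib | gzip | blosc
    level: int = 5  # zlib / gzip
    blosc_cname: str = "zstd"
    blosc_clevel: int = 5
    blosc_shuffle: str = "byte"  # none | byte | bit

    def __post_init__(self):
        if self.codec_id not in ("none", "zlib", "gzip", "blosc"):
            raise UnsupportedCodecError(f"unsupported codec {self.codec_id!r}")
        if self.codec_id in ("zlib", "gzip") and not 0 <= self.level <= 9:
            raise UnsupportedCodecError(f"{self.codec_id} level must be 0-9, got {self.level}")
        if self.codec_id == "blosc":
            if self.blosc_cname not in ("zstd", "lz4", "zlib"):
                raise UnsupportedCodecError(f"unsupported blosc cname {self.blosc_cname!r}")
            if not 1 <= self.blosc_clevel <= 9:
                raise UnsupportedCodecError(f"blosc clevel must be 1-9, got {self.blosc_clevel}")
            if self.blosc_shuffle not in _BLOSC_SHUFFLE:
                raise UnsupportedCodecError(f"unsupported blosc shuffle {self.blosc_shuffle!r}")

    # -- Zarr v2 JSON form ------------------------------------------------
    def to_json(self):
        """Zarr v2 ``compressor`` value (``None`` for the identity codec)."""
        if self.codec_id == "none":
            return None
        if self.codec_id in ("zlib", "gzip"):
            return {"id": self.codec_id, "level": self.level}
        return {
            "id": "blosc",
            "cname": self.blosc_cname,
            "clevel": self.blosc_clevel,
            "shuffle": _BLOSC_SHUFFLE[self.blosc_shuffle],
            "blocksize": 0,
        }

    @classmethod
    def from_json(cls, obj) -> "CompressorSpec":
        if obj is None:
            return cls(codec_id="none")
        cid = obj.get("id")
        if cid in ("zlib", "gzip"):
            return cls(codec_id=cid, level=int(obj.get("level", 1)))
        if cid == "blosc":
            shuffle = obj.get("shuffle", 1)
            if shuffle not in _BLOSC_SHUFFLE_INV:
                raise UnsupportedCodecError(f"unsupported blosc shuffle {shuffle!r}")
            return cls(
                codec_id="blosc",
                blosc_cname=obj.get("cname", "zstd"),
                blosc_clevel=int(obj.get("clevel", 5)),
                blosc_shuffle=_BLOSC_SHUFFLE_INV[shuffle],
            )
        raise UnsupportedCodecError(f"unsupported codec {cid!r}")

    # -- byte transforms --------------------------------------------------
    def compress(self, raw: bytes) -> bytes:
        if self.codec_id == "none":
            return raw
        if self.codec_id == "zlib":
            return _zlib.compress(raw, self.level)
        if self.codec_id == "gzip":
            # mtime=0: byte-identical output for identical input
            return _gzip.compress(raw, compresslevel=self.level, mtime=0)
        return bytes(_blosc_codec(self.blosc_cname, self.blosc_clevel, self.blosc_shuffle).encode(raw))

    def decompress(self, data: bytes, nbytes: int) -> bytes:
        """Inverse of :meth:`compress`; ``nbytes`` is the expected raw length."""
        try:
            if self.codec_id == "none":
                raw = bytes(data)
            elif self.codec_id == "zlib":
                raw = _zlib.decompress(data)
            elif self.codec_id == "gzip":
                raw = _gzip.decompress(data)
            else:
                # the blosc C decoder tolerates truncated buffers, so verify
                # the frame header (nbytes at 4:8, cbytes at 12:16) first
                if len(data) < 16:
                    raise CorruptChunkError("corrupt chunk: blosc frame shorter than its header")
                header_nbytes = int.from_bytes(data[4:8], "little")
                header_cbytes = int.from_bytes(data[12:16], "little")
                if header_cbytes != len(data) or header_nbytes != nbytes:
                    raise CorruptChunkError(
                        f"corrupt chunk: blosc header claims {header_cbytes} of "
                        f"{header_nbytes} bytes, buffer has {len(data)} of {nbytes}"
                    )
                raw = bytes(_blosc_codec(self.blosc_cname, self.blosc_clevel, self.blosc_shuffle).decode(data))
        except CorruptChunkError:
            raise
        except Exception as exc:
            raise CorruptChunkError(f"corrupt chunk: {exc}") from exc
        if len(raw) != nbytes:
            raise CorruptChunkError(f"corrupt chunk: expected {nbytes} bytes, decoded {len(raw)}")
        return raw


@dataclass(frozen=True)
class ArraySpec:
    """Shape/chunking/dtype/compressor descriptor for one stored array."""

    shape: tuple[int, ...]
    chunk_shape: tuple[int, ...]
    dtype_code: str
    fill_value: float | int | None = 0
    order: str = "C"
    dimension_separator: str = "/"
    compressor: CompressorSpec = field(default_factory=CompressorSpec)

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "chunk_shape", tuple(int(c) for c in self.chunk_shape))
        if self.dtype_code not in SUPPORTED_DTYPES:
            raise UnsupportedDtypeError(
                f"unsupported dtype {self.dtype_code!r}; supported: {', '.join(SUPPORTED_DTYPES)}"
            )
        if not 1 <= len(self.shape) <= 5:
            raise ShapeMismatchError(f"rank must be 1-5, got {len(self.shape)}")
        if len(self.shape) != len(self.chunk_shape):
            raise ShapeMismatchError("shape and chunk_shape must have equal rank")
        if any(s <= 0 for s in self.shape) or any(c <= 0 for c in self.chunk_shape):
            raise ShapeMismatchError("shape and chunk_shape entries must be positive")
        if self.order != "C":
            raise ShapeMismatchError("only C order is supported")
        if self.dimension_separator not in ("/", "."):
            raise ShapeMismatchError("dimension_separator must be '/' or '.'")

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(self.dtype_code)

    @property
    def fill_scalar(self):
        """Fill value as a dtype scalar; null means 0 for reads."""
        return self.dtype.type(0 if self.fill_value is None else self.fill_value)

    def to_zarray(self) -> dict:
        return {
            "zarr_format": 2,
            "shape": list(self.shape),
            "chunks": list(self.chunk_shape),
            "dtype": self.dtype_code,
            "compressor": self.compressor.to_json(),
            "fill_value": self.fill_value,
            "order": self.order,
            "filters": None,
            "dimension_separator": self.dimension_separator,
        }

    @classmethod
    def from_zarray(cls, obj: dict) -> "ArraySpec":
        if obj.get("zarr_format") != 2:
            raise ConflictError(f"not a Zarr v2 array descriptor: zarr_format={obj.get('zarr_format')!r}")
        if obj.get("filters"):
            raise UnsupportedCodecError("filters are not supported")
        return cls(
            shape=tuple(obj["shape"]),
            chunk_shape=tuple(obj["chunks"]),
            dtype_code=obj["dtype"],
            fill_value=obj.get("fill_value"),
            order=obj.get("order", "C"),
            dimension_separator=obj.get("dimension_separator", "."),
            compressor=CompressorSpec.from_json(obj.get("compressor")),
        )


@dataclass(frozen=True)
class ChunkPlanEntry:
    """One chunk's contribution to a requested region.

    ``chunk_slab`` addresses elements inside the chunk, ``out_slab`` the
    matching elements inside the request; both are per-axis half-open
    intervals of identical extent.
    """

    chunk_key: str
    grid_index: tuple[int, ...]
    chunk_slab: tuple[tuple[int, int], ...]
    out_slab: tuple[tuple[int, int], ...]


def _check_region(shape: Sequence[int], region: Region) -> tuple[tuple[int, int], ...]:
    if len(region) != len(shape):
        raise ShapeMismatchError(f"region rank {len(region)} != array rank {len(shape)}")
    out = []
    for ax, ((start, stop), n) in enumerate(zip(region, shape)):
        start, stop = int(start), int(stop)
        if stop <= start:
            raise EmptyRegionError(f"empty region on axis {ax}: [{start}, {stop})")
        if start < 0 or stop > n:
            raise BoundsError(f"region [{start}, {stop}) out of bounds [0, {n}) on axis {ax}")
        out.append((start, stop))
    return tuple(out)


def chunk_plan(
    shape: Sequence[int],
    chunk_shape: Sequence[int],
    region: Region,
    separator: str = "/",
) -> list[ChunkPlanEntry]:
    """Map a region onto the chunk grid.

    Returns entries ordered lexicographically by grid index whose
    ``out_slab``\\ s tile the region exactly once.
    """
    region = _check_region(shape, region)
    grid_ranges = [
        range(start // c, (stop - 1) // c + 1)
        for (start, stop), c in zip(region, chunk_shape)
    ]
    entries = []
    for grid in np.ndindex(*[len(r) for r in grid_ranges]):
        idx = tuple(r[g] for r, g in zip(grid_ranges, grid))
        chunk_slab = []
        out_slab = []
        for ax, (i, c, (start, stop)) in enumerate(zip(idx, chunk_shape, region)):
            lo = max(start, i * c)
            hi = min(stop, (i + 1) * c)
            chunk_slab.append((lo - i * c, hi - i * c))
            out_slab.append((lo - start, hi - start))
        entries.append(
            ChunkPlanEntry(
                chunk_key=separator.join(str(i) for i in idx),
                grid_index=idx,
                chunk_slab=tuple(chunk_slab),
                out_slab=tuple(out_slab),
            )
        )
    return entries


def encode_chunk(block: np.ndarray, spec: ArraySpec) -> bytes:
    """Serialize one full chunk: C-order raw bytes, then the codec."""
    if tuple(block.shape) != spec.chunk_shape:
        raise ShapeMismatchError(
            f"chunk block shape {tuple(block.shape)} != chunk_shape {spec.chunk_shape}"
        )
    raw = np.ascontiguousarray(block, dtype=spec.dtype).tobytes(order="C")
    return spec.compressor.compress(raw)


def decode_chunk(data: bytes, spec: ArraySpec) -> np.ndarray:
    """Exact inverse of :func:`encode_chunk`."""
    nbytes = int(np.prod(spec.chunk_shape)) * spec.dtype.itemsize
    raw = spec.compressor.decompress(data, nbytes)
    return np.frombuffer(raw, dtype=spec.dtype).reshape(spec.chunk_shape).copy()


# -- groups and attributes -------------------------------------------------

def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=False) + "\n", encoding="utf-8")


def init_group(root: str | Path, path: str = "") -> Path:
    """Ensure a group (and all its ancestors) exists with ``.zgroup`` markers."""
    root = Path(root)
    target = root / path if path else root
    target.mkdir(parents=True, exist_ok=True)
    node = target
    while True:
        marker = node / ".zgroup"
        if not marker.exists():
            _write_json(marker, {"zarr_format": 2})
        if node == root:
            break
        node = node.parent
    return target


def write_attributes(group: str | Path, attributes: dict) -> None:
    _write_json(Path(group) / ".zattrs", attributes)


def read_attributes(group: str | Path) -> dict:
    path = Path(group) / ".zattrs"
    if not path.exists():
        return {}
    return json.loads(path.read_text(encoding="utf-8"))


# -- arrays ----------------------------------------------------------------

def init_array(root: str | Path, array_path: str, spec: ArraySpec) -> "Array":
    """Create (or idempotently re-open) an array under ``root/array_path``.

    Re-initialising with an identical spec is a no-op; a conflicting spec
    raises :class:`ConflictError`. All ancestor groups get ``.zgroup``
    markers so the hierarchy stays navigable.
    """
    root = Path(root)
    adir = root / array_path if array_path else root
    meta = adir / ".zarray"
    if meta.exists():
        existing = ArraySpec.from_zarray(json.loads(meta.read_text(encoding="utf-8")))
        if existing != spec:
            raise ConflictError(f"array at {array_path!r} exists with conflicting metadata")
        return Array(root, array_path, spec)
    if array_path:
        init_group(root, str(Path(array_path).parent) if Path(array_path).parent != Path(".") else "")
    adir.mkdir(parents=True, exist_ok=True)
    _write_json(meta, spec.to_zarray())
    return Array(root, array_path, spec)


def open_array(root: str | Path, array_path: str) -> "Array":
    """Re-open an array from its on-disk metadata alone."""
    adir = Path(root) / array_path if array_path else Path(root)
    meta = adir / ".zarray"
    if not meta.exists():
        raise NotFoundError(f"no array at {array_path!r}")
    spec = ArraySpec.from_zarray(json.loads(meta.read_text(encoding="utf-8")))
    return Array(Path(root), array_path, spec)


class Array:
    """Handle to one on-disk chunked array.

    ``io_counters`` tracks chunk files opened/written, which makes the
    locality contract (only intersecting chunks are touched) testable.
    """

    def __init__(self, root: Path, path: str, spec: ArraySpec):
        self.root = Path(root)
        self.path = path
        self.spec = spec
        self.io_counters = {"chunks_read": 0, "chunks_written": 0}

    @property
    def directory(self) -> Path:
        return self.root / self.path if self.path else self.root

    def _chunk_file(self, key: str) -> Path:
        return self.directory / key  # '/' keys map to nested dirs, '.' to flat files

    # -- reading -----------------------------------------------------------
    def read_region(self, region: Region) -> np.ndarray:
        spec = self.spec
        plan = chunk_plan(spec.shape, spec.chunk_shape, region, spec.dimension_separator)
        region = _check_region(spec.shape, region)
        extents = tuple(stop - start for start, stop in region)
        out = np.full(extents, spec.fill_scalar, dtype=spec.dtype)
        for entry in plan:
            path = self._chunk_file(entry.chunk_key)
            if not path.exists():
                continue  # missing chunk == fill value, sparse stores are legal
            self.io_counters["chunks_read"] += 1
            try:
                block = decode_chunk(path.read_bytes(), spec)
            except CorruptChunkError as exc:
                raise CorruptChunkError(f"chunk {entry.chunk_key!r}: {exc}", key=entry.chunk_key) from exc
            src = tuple(slice(lo, hi) for lo, hi in entry.chunk_slab)
            dst = tuple(slice(lo, hi) for lo, hi in entry.out_slab)
            out[dst] = block[src]
        return out

    def read(self) -> np.ndarray:
        """Whole-array convenience read."""
        return self.read_region([(0, s) for s in self.spec.shape])

    # -- writing -----------------------------------------------------------
    def _coerce(self, block: np.ndarray) -> np.ndarray:
        target = self.spec.dtype
        block = np.asarray(block)
        if block.dtype == target:
            return block
        if np.can_cast(block.dtype, target, casting="safe"):
            return block.astype(target)
        with np.errstate(invalid="ignore"):
            cast = block.astype(target)
        if np.array_equal(cast, block):  # value-exact, so e.g. int64 7 → "<u2" is fine
            return cast
        raise DtypeError(f"cannot coerce {block.dtype} values to {target} without loss")

    def write_region(self, region: Region, block: np.ndarray) -> int:
        """Write a block into ``region``; returns the number of chunks touched.

        Partially covered chunks are merged read-modify-write; chunk files
        are the atomic unit, so writers touching disjoint chunks commute.
        """
        spec = self.spec
        region = _check_region(spec.shape, region)
        extents = tuple(stop - start for start, stop in region)
        block = np.asarray(block)
        if tuple(block.shape) != extents:
            raise ShapeMismatchError(f"block shape {tuple(block.shape)} != region extents {extents}")
        block = self._coerce(block)
        plan = chunk_plan(spec.shape, spec.chunk_shape, region, spec.dimension_separator)
        for entry in plan:
            path = self._chunk_file(entry.chunk_key)
            full = all(
                hi - lo == c for (lo, hi), c in zip(entry.chunk_slab, spec.chunk_shape)
            )
            if full:
                chunk = np.empty(spec.chunk_shape, dtype=spec.dtype)
            elif path.exists():
                self.io_counters["chunks_read"] += 1
                try:
                    chunk = decode_chunk(path.read_bytes(), spec)
                except CorruptChunkError as exc:
                    raise CorruptChunkError(
                        f"chunk {entry.chunk_key!r}: {exc}", key=entry.chunk_key
                    ) from exc
            else:
                chunk = np.full(spec.chunk_shape, spec.fill_scalar, dtype=spec.dtype)
            src = tuple(slice(lo, hi) for lo, hi in entry.out_slab)
            dst = tuple(slice(lo, hi) for lo, hi in entry.chunk_slab)
            chunk[dst] = block[src]
            path.parent.mkdir(parents=True, exist_ok=True)
            path.write_bytes(encode_chunk(chunk, spec))
            self.io_counters["chunks_written"] += 1
        return len(plan)

    def write(self, data: np.ndarray) -> int:
        """Whole-array convenience write."""
        return self.write_region([(0, s) for s in self.spec.shape], data)

    def chunk_files(self) -> list[Path]:
        """Existing chunk files, sorted by key."""
        files = [
            p
            for p in sorted(self.directory.rglob("*"))
            if p.is_file() and not p.name.startswith(".")
        ]
        return files
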