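"""TIFF-to-OME-Zarr conversion: the core loop of a plane-based converter.

Input planes — pages of one or more TIFF files, or files matched by an
explicit ``{t}/{c}/{z}`` filename template — are assembled into a 5-D
(t, c, z, y, x) array and written as a chunked multiscale image with
configurable chunk shape, level count, and compression. Missing (t,c,z)
coordinates become fill-value planes (with a warning); duplicates are an
error, as is any filename the template cannot account for: silent
misordering is the worst possible failure mode, so nothing is guessed.

The output is deterministic: the same input and options produce a
byte-identical store no matter how many workers write it, because chunk
files are disjoint write units.
"""

from __future__ import annotations

import re
import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import chunkstore, image as image_mod, ngff, pyramid
from .chunkstore import ArraySpec, CompressorSpec
from .errors import (
    ConflictError,
    DuplicatePlaneError,
    InputError,
    ShapeMismatchError,
)

__all__ = ["ConvertOptions", "CHUNK_PROFILES", "assemble_5d", "read_tiff_planes", "convert"]

#: Named chunk layouts. "dandi" is the repository-recommended profile for
#: lightsheet volumes: one timepoint and channel per chunk, 128^3 spatial.
CHUNK_PROFILES: dict[str, tuple[int, ...]] = {"dandi": (1, 1, 128, 128, 128)}


def default_compressor() -> CompressorSpec:
    """Blosc+Zstd when the codec is importable, else zlib."""
    try:
        import numcodecs.blosc  # noqa: F401

        return CompressorSpec(codec_id="blosc", blosc_cname="zstd", blosc_clevel=5)
    except ImportError:  # pragma: no cover
        warnings.warn("blosc unavailable; falling back to zlib", stacklevel=2)
        return CompressorSpec(codec_id="zlib", level=5)


@dataclass
class ConvertOptions:
    chunk_shape: tuple[int, ...] | str | None = None  # explicit, profile name, or None
    n_resolutions: int | str = "auto"
    compressor: CompressorSpec = field(default_factory=default_compressor)
    method: str = "mean"
    workers: int = 1
    dimension_order_pattern: str | None = None  # e.g. "img_t{t}_c{c}_z{z}.tif"
    pages_as: str = "z"  # multi-page TIFFs map pages to z (or "t")

    def resolved_chunks(self, shape: tuple[int, ...]) -> tuple[int, ...]:
        if isinstance(self.chunk_shape, str):
            if self.chunk_shape not in CHUNK_PROFILES:
                raise InputError(f"unknown chunk profile {self.chunk_shape!r}")
            return CHUNK_PROFILES[self.chunk_shape]
        if self.chunk_shape is None:
            return tuple(
                1 if ax < 2 else min(s, 256) for ax, s in enumerate(shape)
            )
        if len(self.chunk_shape) != len(shape):
            raise ShapeMismatchError(
                f"chunk rank {len(self.chunk_shape)} != data rank {len(shape)}"
            )
        return tuple(int(c) for c in self.chunk_shape)

    def __post_init__(self):
        if self.workers < 1:
            raise InputError(f"workers must be >= 1, got {self.workers}")
        if self.pages_as not in ("z", "t"):
            raise InputError(f"pages_as must be 'z' or 't', got {self.pages_as!r}")


def assemble_5d(
    planes: Sequence[tuple[int, int, int, np.ndarray]],
    fill_value=0,
) -> np.ndarray:
    """Place (t, c, z, plane) records into a dense (T, C, Z, Y, X) array.

    Index sets must be dense from 0; a missing triple becomes a
    fill-value plane and a warning, a duplicate is an error. Supply
    order is irrelevant.
    """
    if not planes:
        raise InputError("no planes to assemble")
    seen: set[tuple[int, int, int]] = set()
    yx = None
    for t, c, z, plane in planes:
        plane = np.asarray(plane)
        if plane.ndim != 2:
            raise ShapeMismatchError(f"plane ({t},{c},{z}) has rank {plane.ndim}, expected 2")
        if yx is None:
            yx = plane.shape
        elif plane.shape != yx:
            raise ShapeMismatchError(
                f"plane ({t},{c},{z}) shape {plane.shape} != first plane {yx}"
            )
        if (t, c, z) in seen:
            raise DuplicatePlaneError(f"duplicate plane at (t={t}, c={c}, z={z})")
        seen.add((t, c, z))
    T = max(t for t, _, _ in seen) + 1
    C = max(c for _, c, _ in seen) + 1
    Z = max(z for _, _, z in seen) + 1
    dtype = np.asarray(planes[0][3]).dtype
    out = np.full((T, C, Z) + yx, fill_value, dtype=dtype)
    for t, c, z, plane in planes:
        out[t, c, z] = np.asarray(plane)
    missing = T * C * Z - len(seen)
    if missing:
        warnings.warn(
            f"{missing} of {T * C * Z} (t,c,z) planes missing; filled with {fill_value}",
            stacklevel=2,
        )
    return out


def _parse_pattern(pattern: str) -> re.Pattern:
    """Turn a ``{t}/{c}/{z}`` filename template into a regex."""
    regex = ""
    pos = 0
    for m in re.finditer(r"\{([tcz])\}", pattern):
        regex += re.escape(pattern[pos : m.start()])
        regex += f"(?P<{m.group(1)}>\\d+)"
        pos = m.end()
    regex += re.escape(pattern[pos:])
    return re.compile(regex + r"\Z")


def read_tiff_planes(
    inputs: Sequence[str | Path] | str | Path,
    pattern: str | None = None,
    pages_as: str = "z",
) -> list[tuple[int, int, int, np.ndarray]]:
    """Load planes from TIFF files.

    A directory input requires ``pattern`` (an explicit ``{t}{c}{z}``
    template); a list of files maps each file's pages along ``pages_as``.
    """
    import tifffile

    if isinstance(inputs, (str, Path)) and Path(inputs).is_dir():
        if pattern is None:
            raise InputError("directory input requires a filename pattern with {t}/{c}/{z}")
        rx = _parse_pattern(pattern)
        planes = []
        matched = False
        for path in sorted(Path(inputs).iterdir()):
            m = rx.match(path.name)
            if not m:
                continue
            matched = True
            idx = {k: int(v) for k, v in m.groupdict().items()}
            try:
                pages = tifffile.imread(path)
            except Exception as exc:
                raise InputError(f"unreadable TIFF {path}: {exc}") from exc
            if pages.ndim == 2:
                pages = pages[None]
            for k, page in enumerate(pages):
                t, c, z = idx.get("t", 0), idx.get("c", 0), idx.get("z", 0)
                if "z" not in idx:
                    z = k
                elif len(pages) > 1:
                    raise InputError(
                        f"{path} has {len(pages)} pages but the pattern already fixes z"
                    )
                planes.append((t, c, z, page))
        if not matched:
            raise InputError(f"pattern {pattern!r} matched no files in {inputs}")
        return planes

    paths = [inputs] if isinstance(inputs, (str, Path)) else list(inputs)
    planes = []
    offset = 0
    for path in paths:
        try:
            pages = tifffile.imread(path)
        except Exception as exc:
            raise InputError(f"unreadable TIFF {path}: {exc}") from exc
        if pages.ndim == 2:
            pages = pages[None]
        elif pages.ndim != 3:
            raise InputError(f"{path}: expected 2-D or 3-D TIFF, got rank {pages.ndim}")
        for k, page in enumerate(pages):
            if pages_as == "z":
                planes.append((0, 0, offset + k, page))
            else:
                planes.append((offset + k, 0, 0, page))
        offset += len(pages)
    return planes


def convert(
    inputs,
    output,
    options: ConvertOptions | None = None,
    data: np.ndarray | None = None,
) -> ngff.MultiscaleDoc:
    """Convert TIFF planes (or a raw array via ``data=``) to an OME-Zarr image.

    Level 0 holds the assembled data bit-exactly; further levels follow
    ``options.n_resolutions`` ("auto" asks :func:`pyramid.choose_levels`).
    Chunks are written by a pool of ``options.workers`` threads; since a
    chunk is written by exactly one task the store is byte-identical for
    any worker count.
    """
    options = options or ConvertOptions()
    out = Path(output)
    if out.exists() and any(out.iterdir()):
        raise ConflictError(f"output {output} exists and is not empty")
    if data is None:
        planes = read_tiff_planes(
            inputs, options.dimension_order_pattern, options.pages_as
        )
        data = assemble_5d(planes)
    else:
        data = np.asarray(data)
    if data.ndim != 5:
        raise ShapeMismatchError(f"expected 5-D (t,c,z,y,x) data, got rank {data.ndim}")

    chunks = options.resolved_chunks(data.shape)
    axes = pyramid.default_axes(5)
    factors = (1, 1, 2, 2, 2)
    if options.n_resolutions == "auto":
        n_levels = pyramid.choose_levels(data.shape, factors)
    else:
        n_levels = int(options.n_resolutions)

    spec = ArraySpec(
        shape=data.shape,
        chunk_shape=chunks,
        dtype_code=image_mod.dtype_code_for(data.dtype),
        fill_value=0,
        compressor=options.compressor,
    )
    chunkstore.init_group(out, "")
    arr = chunkstore.init_array(out, "0", spec)
    plan = chunkstore.chunk_plan(spec.shape, spec.chunk_shape, [(0, s) for s in spec.shape])

    def _write(entry):
        lo = [o for o, _ in entry.out_slab]
        hi = [h for _, h in entry.out_slab]
        arr.write_region(
            entry.out_slab, data[tuple(slice(a, b) for a, b in zip(lo, hi))]
        )

    if options.workers == 1:
        for entry in plan:
            _write(entry)
    else:
        with ThreadPoolExecutor(max_workers=options.workers) as pool:
            list(pool.map(_write, plan))

    doc = pyramid.build_pyramid(
        out,
        "",
        n_levels,
        pyramid.DownsampleSpec(factors=factors, method=options.method),
        axes=axes,
    )
    return doc
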