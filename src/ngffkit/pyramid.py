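"""Multiresolution pyramid generation.

Levels are computed level-from-previous-level with per-axis integer
factors; output extent per axis is ``ceil(input / factor)``, so edge
windows may be partial. Three reduction methods:

* ``mean`` — window average; partial edge windows average their actual
  members only, so border statistics are not diluted by padding. For
  integer stores the result is rounded half-to-even before casting
  (bias-free); ``keep_float`` returns float64.
* ``nearest`` — the window-origin element; exact subsampling.
* ``mode`` — most frequent value per window, ties broken toward the
  smallest value. The only safe choice for label images: it never
  invents a value absent from the input.

``build_pyramid`` streams chunk-by-chunk, so peak memory is a few
chunks, not the full image. Windows stay aligned because output chunks
are processed on window boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import chunkstore, ngff
from .chunkstore import Array, ArraySpec, init_array, open_array
from .errors import ConflictError, FactorError

__all__ = ["DownsampleSpec", "downsample_block", "build_pyramid", "choose_levels"]


@dataclass(frozen=True)
class DownsampleSpec:
    """How one pyramid level is reduced to the next."""

    factors: tuple[int, ...]
    method: str = "mean"  # mean | nearest | mode
    cast_policy: str = "round_half_even_to_dtype"  # or keep_float (mean only)

    def __post_init__(self):
        object.__setattr__(self, "factors", tuple(int(f) for f in self.factors))
        if any(f < 1 for f in self.factors):
            raise FactorError(f"factors must be >= 1, got {self.factors}")
        if self.method not in ("mean", "nearest", "mode"):
            raise FactorError(f"unknown method {self.method!r}")
        if self.cast_policy not in ("round_half_even_to_dtype", "keep_float"):
            raise FactorError(f"unknown cast policy {self.cast_policy!r}")


def _window_sums(block: np.ndarray, factors: Sequence[int]):
    """Per-window sum and member count, honouring partial edge windows."""
    sums = block.astype(np.float64)
    counts = np.ones(block.shape, dtype=np.float64)
    for ax, f in enumerate(factors):
        if f == 1:
            continue
        n = sums.shape[ax]
        starts = np.arange(0, n, f)
        sums = np.add.reduceat(sums, starts, axis=ax)
        counts = np.add.reduceat(counts, starts, axis=ax)
    return sums, counts


def _mode_reduce(block: np.ndarray, factors: Sequence[int]) -> np.ndarray:
    out_shape = tuple(-(-n // f) for n, f in zip(block.shape, factors))
    out = np.empty(out_shape, dtype=block.dtype)
    for idx in np.ndindex(*out_shape):
        window = block[
            tuple(slice(i * f, min((i + 1) * f, n)) for i, f, n in zip(idx, factors, block.shape))
        ]
        values, counts = np.unique(window, return_counts=True)
        out[idx] = values[np.argmax(counts)]  # np.unique sorts, so ties pick the smallest
    return out


def downsample_block(block: np.ndarray, spec: DownsampleSpec) -> np.ndarray:
    """Reduce one in-memory block by ``spec.factors``."""
    block = np.asarray(block)
    if block.ndim != len(spec.factors):
        raise FactorError(f"rank {block.ndim} block with {len(spec.factors)} factors")
    if block.size == 0:
        raise FactorError("empty block")
    if spec.method == "nearest":
        return block[tuple(slice(None, None, f) for f in spec.factors)].copy()
    if spec.method == "mode":
        return _mode_reduce(block, spec.factors)
    sums, counts = _window_sums(block, spec.factors)
    mean = sums / counts
    if spec.cast_policy == "keep_float" or block.dtype.kind == "f":
        return mean.astype(np.float64 if spec.cast_policy == "keep_float" else block.dtype)
    info = np.iinfo(block.dtype)
    return np.clip(np.rint(mean), info.min, info.max).astype(block.dtype)


def choose_levels(
    shape: Sequence[int],
    factors: Sequence[int],
    min_spatial: int = 256,
) -> int:
    """Smallest level count whose final level has every reduced extent
    ≤ ``min_spatial``; once nothing shrinks any further, stop."""
    extents = [int(s) for s, f in zip(shape, factors) if f > 1]
    if not extents:
        return 1
    n = 1
    while max(extents) > min_spatial:
        reduced = [-(-e // f) for e, f in zip(extents, [f for f in factors if f > 1])]
        if reduced == extents:  # all at 1: cannot shrink below a single sample
            break
        extents = reduced
        n += 1
    return n


def build_pyramid(
    root,
    image_path: str,
    n_levels: int,
    spec: DownsampleSpec,
    base_scale: Sequence[float] | None = None,
    axes: Sequence[ngff.AxisSpec] | None = None,
    write_doc: bool = True,
) -> ngff.MultiscaleDoc:
    """Compute levels 1..n−1 from the existing level-0 array and (optionally)
    write the multiscales document on the image group.

    Each level is derived from the previous one, chunk-streamed: for every
    output chunk the matching input region is read, reduced, and written,
    so memory stays bounded by a few chunks. The document is written last,
    in one shot, so readers never see a half-registered pyramid.
    """
    from pathlib import Path

    base = open_array(root, f"{image_path}/0" if image_path else "0")
    rank = len(base.spec.shape)
    if len(spec.factors) != rank:
        raise FactorError(f"{len(spec.factors)} factors for rank-{rank} image")
    if axes is None:
        axes = default_axes(rank)
    if base_scale is None:
        base_scale = (1.0,) * rank
    for a, f in zip(axes, spec.factors):
        if a.kind in ("time", "channel") and f != 1:
            raise FactorError(f"factor must be 1 on {a.kind} axis {a.name!r}")

    prev = base
    for lvl in range(1, n_levels):
        out_shape = tuple(-(-n // f) for n, f in zip(prev.spec.shape, spec.factors))
        out_chunks = tuple(min(c, s) for c, s in zip(base.spec.chunk_shape, out_shape))
        lvl_path = f"{image_path}/{lvl}" if image_path else str(lvl)
        lvl_dir = Path(root) / lvl_path
        if (lvl_dir / ".zarray").exists():
            existing = open_array(root, lvl_path)
            if existing.spec.shape != out_shape or existing.spec.dtype_code != base.spec.dtype_code:
                raise ConflictError(f"level {lvl} exists with conflicting metadata")
        out = init_array(
            root,
            lvl_path,
            ArraySpec(
                shape=out_shape,
                chunk_shape=out_chunks,
                dtype_code=base.spec.dtype_code,
                fill_value=base.spec.fill_value,
                dimension_separator=base.spec.dimension_separator,
                compressor=base.spec.compressor,
            ),
        )
        for entry in chunkstore.chunk_plan(out_shape, out_chunks, [(0, s) for s in out_shape]):
            region_in = [
                (lo * f, min(hi * f, n))
                for (lo, hi), f, n in zip(entry.out_slab, spec.factors, prev.spec.shape)
            ]
            block = prev.read_region(region_in)
            out.write_region(list(entry.out_slab), downsample_block(block, spec))
        prev = out

    doc = ngff.build_multiscales(
        axes, n_levels, base_scale, spec.factors, method=spec.method
    )
    if write_doc:
        group = Path(root) / image_path if image_path else Path(root)
        chunkstore.init_group(root, image_path)
        attrs = chunkstore.read_attributes(group)
        attrs["multiscales"] = [doc.to_json()]
        chunkstore.write_attributes(group, attrs)
    return doc


def default_axes(rank: int) -> tuple[ngff.AxisSpec, ...]:
    """Canonical axes for a given rank: trailing subset of (t, c, z, y, x)."""
    full = (
        ngff.AxisSpec("t", "time"),
        ngff.AxisSpec("c", "channel"),
        ngff.AxisSpec("z", "space"),
        ngff.AxisSpec("y", "space"),
        ngff.AxisSpec("x", "space"),
    )
    if not 2 <= rank <= 5:
        raise FactorError(f"rank {rank} outside 2-5")
    return full[5 - rank :]
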