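"""Shared plumbing for writing and reading whole multiscale images.

A "multiscale image" on disk is a group whose ``.zattrs`` carries a
``multiscales`` block and whose level arrays live at ``0``, ``1``, ...
This module offers the one-call write path the higher-level modules
(plates, converter, fixtures) build on.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from . import chunkstore, ngff, pyramid
from .chunkstore import ArraySpec, CompressorSpec
from .errors import NotFoundError

__all__ = ["write_multiscale_image", "read_level", "open_image"]

_DTYPE_TO_CODE = {
    np.dtype("uint8"): "|u1",
    np.dtype("uint16"): "<u2",
    np.dtype("uint32"): "<u4",
    np.dtype("int16"): "<i2",
    np.dtype("int32"): "<i4",
    np.dtype("float32"): "<f4",
    np.dtype("float64"): "<f8",
}


def dtype_code_for(dtype) -> str:
    code = _DTYPE_TO_CODE.get(np.dtype(dtype))
    if code is None:
        from .errors import UnsupportedDtypeError

        raise UnsupportedDtypeError(f"unsupported dtype {dtype!r}")
    return code


def write_multiscale_image(
    root,
    image_path: str,
    data: np.ndarray,
    *,
    axes: Sequence[ngff.AxisSpec] | None = None,
    chunk_shape: Sequence[int] | None = None,
    compressor: CompressorSpec | None = None,
    n_levels: int = 1,
    method: str = "mean",
    base_scale: Sequence[float] | None = None,
    fill_value=0,
    name: str | None = None,
    extra_attrs: dict | None = None,
) -> ngff.MultiscaleDoc:
    """Write ``data`` as level 0 and derive ``n_levels-1`` further levels.

    Default chunking caps each spatial axis at 256 samples and keeps
    non-spatial axes at 1, a middle-of-the-road tiling for plane and
    volume access alike.
    """
    rank = data.ndim
    if axes is None:
        axes = pyramid.default_axes(rank)
    if chunk_shape is None:
        chunk_shape = tuple(
            1 if a.kind in ("time", "channel") else min(int(s), 256)
            for a, s in zip(axes, data.shape)
        )
    spec = ArraySpec(
        shape=data.shape,
        chunk_shape=tuple(chunk_shape),
        dtype_code=dtype_code_for(data.dtype),
        fill_value=fill_value,
        compressor=compressor if compressor is not None else CompressorSpec(),
    )
    group = chunkstore.init_group(root, image_path)
    arr = chunkstore.init_array(root, f"{image_path}/0" if image_path else "0", spec)
    arr.write(data)
    factors = tuple(1 if a.kind in ("time", "channel") else 2 for a in axes)
    doc = pyramid.build_pyramid(
        root,
        image_path,
        n_levels,
        pyramid.DownsampleSpec(factors=factors, method=method),
        base_scale=base_scale,
        axes=axes,
        write_doc=False,
    )
    if name is not None:
        doc.name = name
    attrs = chunkstore.read_attributes(group)
    attrs["multiscales"] = [doc.to_json()]
    if extra_attrs:
        attrs.update(extra_attrs)
    chunkstore.write_attributes(group, attrs)
    return doc


def open_image(root, image_path: str = "") -> ngff.MultiscaleDoc:
    """Parse the multiscales document of an image group."""
    group = Path(root) / image_path if image_path else Path(root)
    attrs = chunkstore.read_attributes(group)
    ms = attrs.get("multiscales")
    if not ms:
        raise NotFoundError(f"no multiscales metadata at {image_path!r}")
    return ngff.parse_multiscales(ms[0])


def read_level(root, image_path: str, level: int = 0) -> np.ndarray:
    """Read one whole pyramid level of an image."""
    doc = open_image(root, image_path)
    if not 0 <= level < len(doc.levels):
        raise NotFoundError(f"level {level} out of range for {image_path!r}")
    lvl_path = doc.levels[level].path
    arr_path = f"{image_path}/{lvl_path}" if image_path else lvl_path
    return chunkstore.open_array(root, arr_path).read()
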