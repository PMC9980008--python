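"""Deterministic synthetic images, plates, and defect injection.

Everything the test-bench needs is generated here, bit-reproducibly,
with a counter-based PRNG fixed in this file (a splitmix64 finalizer
over ``seed ^ i*golden``) so determinism does not depend on any
library's generator staying stable across versions. The same SceneSpec
always produces the same bytes on every run and platform.

Patterns:

* ``gradient`` — a closed-form ramp over the (y, x) plane: flattened
  index scaled to the dtype's full range, identical on every (t, c, z).
* ``checker``  — 8-pixel checkerboard alternating with t, c, z parity.
* ``spots``    — non-overlapping bright spheres/disks at PRNG-chosen
  centers, co-generated with a ground-truth integer label image
  (labels 1..n) so segmentation-storage tests have known answers.

``inject_defect`` applies one minimal, targeted mutation per validator
issue code, so validator completeness can be checked code by code.
"""

from __future__ import annotations

import json
import hashlib
import shutil
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import chunkstore, hcs, image as image_mod, pyramid
from .chunkstore import ArraySpec, CompressorSpec
from .errors import CapacityError, NgffError
from .validate import ISSUE_CODES

__all__ = [
    "SceneSpec",
    "CounterRng",
    "synth_image",
    "synth_image_store",
    "synth_plate",
    "synth_multiscale_image",
    "inject_defect",
    "tree_hash",
]

_M64 = (1 << 64) - 1
_GOLDEN = 0x9E3779B97F4A7C15


def _splitmix64(x: int) -> int:
    x &= _M64
    x = (x ^ (x >> 30)) * 0xBF58476D1CE4E5B9 & _M64
    x = (x ^ (x >> 27)) * 0x94D049BB133111EB & _M64
    return x ^ (x >> 31)


def fnv1a64(text: str) -> int:
    h = 0xCBF29CE484222325
    for b in text.encode("utf-8"):
        h = ((h ^ b) * 0x100000001B3) & _M64
    return h


class CounterRng:
    """Counter-based generator: draw ``i`` is ``splitmix64(seed ^ i*golden)``.

    Stateless per draw, so any value can be recomputed from (seed, i).
    """

    def __init__(self, seed: int):
        self.seed = int(seed) & _M64
        self.counter = 0

    def next_u64(self) -> int:
        v = _splitmix64(self.seed ^ (self.counter * _GOLDEN & _M64))
        self.counter += 1
        return v

    def randint(self, lo: int, hi: int) -> int:
        """Uniform integer in [lo, hi)."""
        span = hi - lo
        return lo + self.next_u64() % span


@dataclass(frozen=True)
class SceneSpec:
    shape: tuple[int, int, int, int, int]  # (t, c, z, y, x)
    dtype_code: str = "<u2"
    pattern: str = "gradient"  # gradient | checker | spots
    n_spots: int = 10
    spot_radius: int = 3
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        if len(self.shape) != 5 or any(s < 1 for s in self.shape):
            raise NgffError(f"shape must be a positive 5-tuple, got {self.shape}")
        if self.pattern not in ("gradient", "checker", "spots"):
            raise NgffError(f"unknown pattern {self.pattern!r}")


def _dtype_peak(dtype: np.dtype):
    return 1.0 if dtype.kind == "f" else np.iinfo(dtype).max


def synth_image(spec: SceneSpec):
    """Render a scene; returns ``(array, labels_or_None, centers)``.

    ``labels`` (spots only) is an integer (z, y, x) volume with one
    distinct non-zero label per spot; ``centers`` lists the (z, y, x)
    spot centers in label order.
    """
    t, c, z, y, x = spec.shape
    dtype = np.dtype(spec.dtype_code)
    peak = _dtype_peak(dtype)

    if spec.pattern == "gradient":
        idx = np.arange(y * x).reshape(y, x)
        denom = max(y * x - 1, 1)
        if dtype.kind == "f":
            plane = (idx / denom).astype(dtype)
        else:
            plane = (idx * int(peak) // denom).astype(dtype)
        return np.broadcast_to(plane, spec.shape).copy(), None, []

    if spec.pattern == "checker":
        tt, cc, zz, yy, xx = np.meshgrid(
            np.arange(t), np.arange(c), np.arange(z), np.arange(y), np.arange(x), indexing="ij"
        )
        parity = (tt + cc + zz + yy // 8 + xx // 8) % 2
        return (parity * peak).astype(dtype), None, []

    # spots
    r = spec.spot_radius
    span_z = max(z - 2 * r, 1) if z > 1 else 1
    span_y = max(y - 2 * r, 1)
    span_x = max(x - 2 * r, 1)
    diam = 2 * r + 1
    capacity = (max(z // diam, 1)) * max(y // diam, 1) * max(x // diam, 1)
    if spec.n_spots > capacity:
        raise CapacityError(
            f"{spec.n_spots} spots of radius {r} cannot fit a {z}x{y}x{x} volume "
            f"(capacity ~{capacity})"
        )
    rng = CounterRng(spec.seed)
    centers: list[tuple[int, int, int]] = []
    attempts = 0
    while len(centers) < spec.n_spots:
        attempts += 1
        if attempts > 1000 * spec.n_spots:
            raise CapacityError(
                f"could not place {spec.n_spots} non-overlapping spots after {attempts} attempts"
            )
        cz = rng.randint(min(r, z - 1) if z > 1 else 0, (min(r, z - 1) if z > 1 else 0) + span_z)
        cy = rng.randint(r if y > diam else 0, (r if y > diam else 0) + span_y)
        cx = rng.randint(r if x > diam else 0, (r if x > diam else 0) + span_x)
        if all(
            max(abs(cz - oz), abs(cy - oy), abs(cx - ox)) > diam for oz, oy, ox in centers
        ):
            centers.append((cz, cy, cx))
    zz, yy, xx = np.meshgrid(np.arange(z), np.arange(y), np.arange(x), indexing="ij")
    labels = np.zeros((z, y, x), dtype=np.int32)
    for k, (cz, cy, cx) in enumerate(centers, start=1):
        if z > 1:
            mask = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        else:
            mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        labels[mask] = k
    plane = (labels > 0) * peak
    data = np.broadcast_to(plane.astype(dtype), spec.shape).copy()
    return data, labels, centers


def synth_image_store(
    root,
    spec: SceneSpec | None = None,
    n_levels: int = 2,
    with_labels: bool = True,
    compressor: CompressorSpec | None = None,
) -> Path:
    """A pristine, validating image store (optionally with a label image)."""
    spec = spec or SceneSpec(shape=(1, 1, 4, 32, 32), pattern="spots", n_spots=4, seed=11)
    data, labels, _ = synth_image(spec)
    image_mod.write_multiscale_image(
        Path(root),
        "",
        data,
        n_levels=n_levels,
        compressor=compressor if compressor is not None else CompressorSpec("zlib", level=5),
    )
    if with_labels and labels is not None:
        colors = {int(v): (255, 0, 0, 255) for v in np.unique(labels) if v}
        hcs.attach_labels(root, "", "spots", labels, colors=colors, n_levels=1)
    return Path(root)


def synth_plate(
    root,
    rows: int = 2,
    cols: int = 2,
    fields: int = 1,
    scene: SceneSpec | None = None,
    seed: int = 0,
    n_levels: int = 1,
) -> hcs.PlateDoc:
    """A pristine plate whose field images differ but are reproducible:
    each field is rendered with seed ``seed ^ fnv1a64(well/field)``."""
    scene = scene or SceneSpec(shape=(1, 1, 1, 64, 64), pattern="gradient")
    row_names = hcs.default_row_names(rows)
    col_names = hcs.default_column_names(cols)
    template = hcs.ImageTemplate(
        shape=scene.shape,
        dtype_code=scene.dtype_code,
        n_levels=n_levels,
        compressor=CompressorSpec("zlib", level=5),
    )
    doc = hcs.create_plate(
        root, row_names, col_names, fields_per_well=fields, image_template=template
    )
    for w in doc.wells:
        for f in range(fields):
            fseed = (seed ^ fnv1a64(f"{w.path}/{f}")) & ((1 << 63) - 1)
            fspec = SceneSpec(
                shape=scene.shape,
                dtype_code=scene.dtype_code,
                pattern=scene.pattern,
                n_spots=scene.n_spots,
                spot_radius=scene.spot_radius,
                seed=fseed,
            )
            data, _, _ = synth_image(fspec)
            hcs.write_field(root, w.path, f, data)
    return doc


def synth_multiscale_image(root, rank: int, extent: int = 16, n_levels: int = 2) -> Path:
    """A minimal multiscale image of the given rank, for validator probing.

    Ranks 2-5 are written through the normal (self-validating) pipeline.
    Other ranks cannot be expressed by the writers, so their metadata is
    emitted directly — axes ``(t, c, z, y, x, u4, u5, ...)`` with extra
    trailing space axes and consistently sized transform vectors — which
    is exactly what probing the validator's rank rules requires.
    """
    root = Path(root)
    if 2 <= rank <= 5:
        shape = (1, 1, 4, extent, extent)[5 - rank :]
        data5, _, _ = synth_image(SceneSpec(shape=(1, 1, shape[-3] if rank >= 3 else 1, extent, extent)))
        image_mod.write_multiscale_image(root, "", data5.reshape(shape), n_levels=n_levels)
        return root
    chunkstore.init_group(root, "")
    kinds = ["time", "channel"] + ["space"] * (rank - 2)
    names = ["t", "c", "z", "y", "x"] + [f"u{k}" for k in range(3, rank - 1)]
    axes = [{"name": n, "type": k} for n, k in zip(names[:rank], kinds)]
    datasets = [
        {
            "path": str(i),
            "coordinateTransformations": [{"type": "scale", "scale": [float(2**i)] * rank}],
        }
        for i in range(n_levels)
    ]
    attrs = chunkstore.read_attributes(root)
    attrs["multiscales"] = [{"version": "0.4", "axes": axes, "datasets": datasets}]
    chunkstore.write_attributes(root, attrs)
    return root


def tree_hash(root) -> str:
    """SHA-256 over every file path and its bytes, in sorted order."""
    h = hashlib.sha256()
    root = Path(root)
    for path in sorted(p for p in root.rglob("*") if p.is_file()):
        h.update(str(path.relative_to(root)).encode())
        h.update(b"\0")
        h.update(path.read_bytes())
        h.update(b"\0")
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Defect injection


def _edit_multiscales(root: Path, edit) -> None:
    attrs = chunkstore.read_attributes(root)
    edit(attrs["multiscales"][0])
    chunkstore.write_attributes(root, attrs)


def _first_chunk_file(level_dir: Path) -> Path:
    files = sorted(
        p for p in level_dir.rglob("*") if p.is_file() and not p.name.startswith(".")
    )
    if not files:
        raise NgffError(f"no chunk files under {level_dir}")
    return files[0]


def _edit_zarray(level_dir: Path, edit) -> None:
    meta = json.loads((level_dir / ".zarray").read_text())
    edit(meta)
    (level_dir / ".zarray").write_text(json.dumps(meta, indent=1) + "\n")


def inject_defect(root, kind: str) -> Path:
    """Minimally corrupt a pristine store so ``validate`` reports ``kind``.

    Image-profile kinds expect a store from :func:`synth_image_store`
    (two levels, spots labels); ``WELL_*`` kinds expect a plate. A kind
    that does not apply to the store raises ``NgffError("inapplicable")``.
    """
    root = Path(root)
    if kind not in ISSUE_CODES:
        raise NgffError(f"unknown issue code {kind!r}")
    attrs = chunkstore.read_attributes(root)
    is_plate = "plate" in attrs
    if kind.startswith("WELL_") != is_plate:
        raise NgffError(f"inapplicable: {kind} needs a {'plate' if kind.startswith('WELL_') else 'image'} store")
    img = root  # image-profile mutations target the root image

    if kind == "MISSING_GROUP_META":
        (root / ".zgroup").unlink()
    elif kind == "MISSING_ARRAY_META":
        (img / "0" / ".zarray").unlink()
    elif kind == "BAD_JSON":
        (img / ".zattrs").write_text("{ this is not json", encoding="utf-8")
    elif kind == "BAD_VERSION":
        _edit_multiscales(img, lambda ms: ms.__setitem__("version", "0.3"))
    elif kind == "AXIS_COUNT":

        def grow(ms):
            ms["axes"] = ms["axes"] + [{"name": "q", "type": "space"}]
            for ds in ms["datasets"]:
                for tr in ds["coordinateTransformations"]:
                    tr[tr["type"]] = tr[tr["type"]] + [1.0]

        _edit_multiscales(img, grow)
    elif kind == "AXIS_ORDER":

        def swap(ms):
            ms["axes"][0], ms["axes"][1] = ms["axes"][1], ms["axes"][0]

        _edit_multiscales(img, swap)
    elif kind == "TRANSFORM_LENGTH":

        def truncate(ms):
            tr = ms["datasets"][0]["coordinateTransformations"][0]
            tr["scale"] = tr["scale"][:-1]

        _edit_multiscales(img, truncate)
    elif kind == "MISSING_SCALE":

        def drop(ms):
            n = len(ms["axes"])
            ms["datasets"][0]["coordinateTransformations"] = [
                {"type": "translation", "translation": [0.0] * n}
            ]

        _edit_multiscales(img, drop)
    elif kind == "LEVEL_PATH_MISSING":
        shutil.rmtree(img / "1")
    elif kind == "NONDECREASING_LEVELS":
        base = json.loads((img / "0" / ".zarray").read_text())["shape"]
        _edit_zarray(img / "1", lambda meta: meta.__setitem__("shape", base))
    elif kind == "DTYPE_INCONSISTENT":
        # same-width edit keeps the chunk payload decodable
        _edit_zarray(img / "1", lambda meta: meta.__setitem__("dtype", "<i2"))
    elif kind == "CHUNK_UNDECODABLE":
        chunk = _first_chunk_file(img / "0")
        chunk.write_bytes(chunk.read_bytes()[: max(1, chunk.stat().st_size // 2)])
    elif kind == "LABEL_DTYPE":
        ldir = img / "labels" / "spots"
        arr = chunkstore.open_array(root, "labels/spots/0")
        data = arr.read().astype(np.float32)
        spec = arr.spec
        shutil.rmtree(ldir / "0")
        chunkstore.init_array(
            root,
            "labels/spots/0",
            ArraySpec(
                shape=spec.shape,
                chunk_shape=spec.chunk_shape,
                dtype_code="<f4",
                fill_value=spec.fill_value,
                compressor=spec.compressor,
            ),
        ).write(data)
    elif kind == "LABEL_SOURCE_MISSING":
        ldir = img / "labels" / "spots"
        lattrs = chunkstore.read_attributes(ldir)
        lattrs["image-label"]["source"]["image"] = "../../../nowhere"
        chunkstore.write_attributes(ldir, lattrs)
    elif kind == "UNKNOWN_UNIT":
        _edit_multiscales(img, lambda ms: ms["axes"][-1].__setitem__("unit", "furlong"))
    elif kind == "WELL_PATH_MISMATCH":

        def rename(plate):
            plate["wells"][0]["path"] = plate["wells"][0]["path"] + "_moved"

        pattrs = chunkstore.read_attributes(root)
        rename(pattrs["plate"])
        chunkstore.write_attributes(root, pattrs)
    elif kind == "WELL_INDEX_RANGE":
        pattrs = chunkstore.read_attributes(root)
        pattrs["plate"]["wells"][0]["rowIndex"] = 99
        chunkstore.write_attributes(root, pattrs)
    return root
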