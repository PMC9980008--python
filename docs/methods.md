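# Methods

## Storage dialect

ngffkit writes the Zarr v2 dialect: per-array `.zarray`, per-group
`.zgroup` (`{"zarr_format": 2}`), user attributes in `.zattrs`, all
UTF-8 JSON. The dialect is deliberately narrow so that every branch is
exercised by tests:

- **Dtypes** — exactly `|u1 <u2 <u4 <i2 <i4 <f4 <f8`. Anything else is
  rejected with an explicit error rather than silently reinterpreted.
  Values written from a wider dtype are accepted only when the cast is
  value-exact.
- **Layout** — C order only; `filters` always null; rank 1–5.
- **Chunk grid** — `dimension_separator` defaults to `/` (chunk keys
  become nested directories, matching common converter output); `.` is
  accepted on read and write. Edge chunks are stored padded to the full
  chunk shape with the fill value and cropped on read; this keeps every
  chunk file the same decoded size at the cost of a little padding,
  which the codec largely removes.
- **Missing chunks** — always legal; they read as `fill_value` (0 when
  the metadata says null). Sparse stores are a feature, not an error.
- **Codecs** — `none`, `zlib`, `gzip`, `blosc` (zstd/lz4/zlib inner
  codec, byte/bit/no shuffle). zlib and gzip use the standard library;
  Blosc uses numcodecs with threading disabled so encoded bytes are
  deterministic. gzip frames are written with `mtime=0` for the same
  reason: rewriting identical data must leave chunk files byte-identical.
  Blosc's C decoder does not reliably reject truncated buffers, so the
  frame header's `nbytes`/`cbytes` fields are checked against the actual
  buffer before decoding; any mismatch is a corrupt-chunk error naming
  the chunk key.

Chunk files are the atomic write unit. A sub-region write touches only
the chunks its region intersects (read-modify-write on partially
covered ones), so concurrent writers on disjoint chunks commute and the
converter's thread pool cannot affect output bytes.

## Metadata model

Multiscales documents follow NGFF v0.4 field names exactly (`version`,
`axes` with `name`/`type`/`unit`, `datasets` with `path` and
`coordinateTransformations`, optional top-level
`coordinateTransformations` and `type`). Design choices where the
format leaves room:

- **Canonical axis order is enforced** — time, then channel, then 2–3
  contiguous space axes (t, c, z, y, x). Documents in any other order
  are rejected, not reordered: silent reordering would corrupt data
  whose arrays were written against the declared order.
- **Transforms** — each dataset's first transform must be a scale (>0
  elementwise, length = axis count); at most one translation, after it.
  `effective_scale` is the elementwise product of global and per-level
  scale vectors; translations never affect the step.
- **Units are advisory** — an unrecognized unit is a warning, never an
  error, because the vocabulary keeps growing.
- **Unknown keys round-trip** — extra metadata keys are preserved
  verbatim in an extras bag for forward compatibility.
- **Rendering hints** (`omero`-style blocks) are carried opaquely and
  never required.

## Pyramids

No single downsampling kernel suits all data, so the method is explicit
and recorded in the document's `type` field:

- `mean` (default for intensity) — window average with float64
  accumulation. Partial edge windows average their actual members only,
  so border statistics are not diluted; with even divisibility the
  global mean is conserved exactly. Integer stores round half-to-even
  before casting (bias-free); `keep_float` returns float64.
- `nearest` — the window-origin sample; exact subsampling.
- `mode` (default for labels) — most frequent value per window, ties
  broken toward the smallest value; coarse levels can never contain a
  label absent from level 0.

Levels are computed each from the previous level rather than always
from level 0 — cheaper, and the small extra error is acceptable for
visualization-oriented levels. Processing is chunk-streamed: for each
output chunk only the matching input region is materialized, and output
chunks sit on window boundaries so windows never straddle two tasks.
`choose_levels` adds levels until every reducible extent is ≤ 256
samples (and stops once nothing shrinks), a size at which a whole level
fits comfortably in one read.

Default downsample factors are 2 on every space axis (including z) and
1 on time/channel; per-axis overrides cover thick-slab data where z
should be left alone.

## Plates and labels

Rows default to `A, B, C, …`, columns to `1, 2, 3, …` (microtiter
convention); arbitrary unique names are accepted. Well paths are always
`<row name>/<column name>`, and the validator enforces that algebra.
Every field image is laid out at plate-creation time (metadata plus
sparse level arrays), so an unwritten field is a valid image that reads
as fill value. `field_count` records the per-well field capacity.

The montage packs each well's F fields row-major into a
`ceil(F/ceil(√F)) × ceil(√F)` grid of tiles and the wells onto the
plate grid, giving output extent `rows × tile_h` by `columns × tile_w`.
The packing is a documented convention of this package — upstream
tools each choose their own — and is recorded here rather than inferred.

Labels are stored under the image they segment
(`<image>/labels/<name>`), keeping provenance local; the `labels` group
attribute lists names in insertion order, and each label image carries
`image-label` metadata (unique `label-value` colors, a `source.image`
pointer defaulting to `../../`). Label data must be integer; attachment
validates the spatial shape against the source's level 0 and
downsamples with `mode` only.

## Validation

The validator re-implements, offline and file-based, what a format
checker needs: JSON schema conformance plus the structural rules
schemas cannot express. The 17-code catalog is this package's own
enumeration of the metadata invariants; each code has a pristine
fixture that does not trigger it and an injected defect that triggers
exactly it (`synth.inject_defect`).

- Schema texts live in `src/ngffkit/schemas/` and are authored in-repo
  (filenames say "synthetic"); they are checked by a small interpreter
  for the JSON-Schema subset they use, so validation needs no network
  and no extra dependency.
- Checks that depend on a broken document are skipped rather than
  cascaded: unparseable attributes yield only `BAD_JSON`; a rank
  violation yields only `AXIS_COUNT`. One defect, one code.
- `NONDECREASING_LEVELS` flags a level whose per-axis shape grows, or
  whose space extents are all unchanged (>1) from the previous level;
  equality is allowed on non-space axes and at extent 1, where ceil
  division legitimately plateaus.
- Chunk decodability is sampled (first 3 chunk files per level, sorted)
  to bound validation cost on large stores.
- Exit status: 0 clean, 1 errors, 2 unreadable root.

`summarize` computes raw bytes as `∏ shape × dtype width` per level
from metadata alone — a metadata-only store still reports its full raw
size (terabytes = bytes / 10¹², also rounded to the nearest integer) —
and stored bytes by stat-ing chunk files.

## Conversion

The converter assembles 2-D planes into (t, c, z, y, x): multi-page
TIFFs map pages to z (or t on request); directory inputs require an
explicit `{t}/{c}/{z}` filename template — no heuristic order guessing,
because silent misordering is the worst failure mode. Missing planes
fill with the fill value plus a warning; duplicates and ragged planes
are errors. Chunk shape, level count ("auto" = `choose_levels`), codec
(default Blosc+Zstd, falling back to zlib if Blosc is unavailable), and
worker count are configurable; the only named chunk profile is `dandi`,
(1, 1, 128, 128, 128). Level 0 is bit-exact; output bytes are
independent of worker count.

## Synthetic data

Fixtures are generated, never stored. Determinism rests on a
counter-based PRNG fixed in `synth.py` (a splitmix64 finalizer over
`seed ^ i·golden`), so identical specs give identical bytes on every
platform and library version. Patterns: a closed-form `gradient` ramp
(flattened (y,x) index scaled to the dtype range), an 8-px `checker`
with t/c/z parity, and `spots` — non-overlapping constant-intensity
spheres/disks co-generated with a ground-truth label volume (labels
1..n) so label-attachment and montage tests have known answers.
Plate fields derive per-field seeds as `seed ^ fnv1a64(well/field)`.

These scenes exercise layout, arithmetic, and metadata, not microscopy
physics: there is no PSF, noise, or bleaching, intensities are
piecewise-constant, and spots never touch. Passing tests therefore
demonstrate container correctness (bit-exact storage, valid metadata,
geometric bookkeeping) — they say nothing about segmentation or
restoration quality on real images.

Default test problem sizes are desk-scale on purpose — arrays up to a
few hundred pixels per side, plates up to 8×12 — large enough to cross
every chunk boundary and small enough that the whole suite runs in
seconds.

## Known limitations

- Zarr v2 dialect only: no v3 sharding, consolidated metadata, or
  remote stores; local filesystems only (the layout itself is
  transport-agnostic).
- No affine or cross-image transforms; no label measurement tables.
- The converter reads TIFF planes and in-memory arrays, not proprietary
  vendor formats.
- Montage packing is a convention, not a reproduction of any particular
  tool's mosaic.
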