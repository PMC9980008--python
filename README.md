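# ngffkit

A self-contained Python implementation of the OME-Zarr bioimaging
container (OME-NGFF v0.4): chunked multiscale image storage with JSON
metadata, high-content-screening plate layout, label images, store
validation, and TIFF conversion — library first, with a thin `ngff`
command line on top.

## Who this is for

Microscopy facilities and image-analysis developers who need to write,
inspect, or validate OME-Zarr data without pulling in a full viewer
stack, and who want every byte of the on-disk format to be testable.
Stores written by ngffkit are plain Zarr v2 directory hierarchies and
are readable by any conforming Zarr implementation (the test suite
cross-checks against `zarr`), and vice versa.

## The model

An image is stored as a directory of **chunks** — fixed-shape N-D
blocks, each one compressed file (`none`, `zlib`, `gzip`, or
Blosc) — plus a `.zarray` JSON descriptor. Only the chunks intersecting
a requested sub-region are ever touched; a missing chunk file reads as
the fill value, so sparse stores are legal. Arrays have up to 5
dimensions in the canonical axis order *(t, c, z, y, x)*: at most one
time and one channel axis, then 2–3 contiguous trailing space axes.

A **multiscale image** is a group of such arrays at paths `0, 1, …`,
highest resolution first, declared by a `multiscales` metadata block:
named axes and, per level, a scale (and optional translation) transform
mapping array indices to physical coordinates. Level *i* of a factor-*f*
pyramid has per-axis extent `ceil(prev / f)` and scale
`base × f^i`. Downsampling kernels: windowed `mean` (partial edge
windows average their actual members; integer output rounds
half-to-even), `nearest` (window origin), and `mode` (most frequent,
ties to the smallest value — the label-safe choice, since it never
invents a value).

An **HCS plate** is a hierarchy of groups: plate → well
(`<row>/<column>`) → field of view, each field a full multiscale image.
Segmentations live beside their source image under
`<image>/labels/<name>` as integer multiscale images with color and
source metadata.

The **validator** checks every JSON document against in-repo schema
texts plus structural rules (level shapes non-increasing, consistent
dtypes, decodable chunks, plate path algebra, label dtype/source) and
reports *all* issues at once under a 17-code catalog; `summarize`
reports shapes, chunk counts, raw bytes (`∏ shape × dtype width`,
summed over levels) and stored bytes.

## Worked example

```sh
$ ngff synth image --out embryo.zarr --shape 1,2,8,256,256 --pattern spots --seed 7 --levels 3
wrote synthetic image at embryo.zarr
$ ngff validate embryo.zarr
0 error(s), 0 warning(s)
$ ngff info embryo.zarr
image .  axes=t,c,z,y,x  dtype=<u2
  level 0: shape=[1, 2, 8, 256, 256] chunks=[1, 1, 8, 256, 256] n_chunks=2 raw=2,097,152 B
  level 1: shape=[1, 2, 4, 128, 128] chunks=[1, 1, 4, 128, 128] n_chunks=2 raw=262,144 B
  level 2: shape=[1, 2, 2, 64, 64] chunks=[1, 1, 2, 64, 64] n_chunks=2 raw=32,768 B
image labels/spots  axes=z,y,x  dtype=<i4
  level 0: shape=[8, 256, 256] chunks=[8, 256, 256] n_chunks=1 raw=2,097,152 B
total raw 4,489,216 B (0.0000 TB, rounds to 0 TB); stored 7,931 B
```

The synthetic two-channel volume carries 10 bright spots and a matching
ground-truth label image. `info` shows the three pyramid levels halving
each spatial extent, the per-level chunking, and the raw-vs-stored size
gap (the sparse spot field compresses well under zlib). A plate works
the same way:

```sh
$ ngff synth plate --out screen.zarr --rows 2 --cols 3 --shape 1,1,1,64,64 --pattern spots --seed 3
wrote synthetic plate at screen.zarr
$ ngff montage screen.zarr --out plate.tiff
montage 128x192 -> plate.tiff
$ ngff validate screen.zarr
0 error(s), 0 warning(s)
```

The montage concatenates one low-resolution plane per field on the
plate grid: 2 rows × 64 px tall, 3 columns × 64 px wide → 128 × 192.
Converting an existing TIFF stack:

```sh
ngff convert stack.tif out.zarr --profile dandi --resolutions auto --workers 4
```

writes a (1,1,128,128,128)-chunked, Blosc+Zstd-compressed multiscale
image whose level 0 equals the source planes bit-exactly, byte-identical
for any worker count.

Library use mirrors the CLI: `ngffkit.write_multiscale_image`,
`ngffkit.validate`, `ngffkit.create_plate`, `ngffkit.convert`, and so
on — see the module docstrings.

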