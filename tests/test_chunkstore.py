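"""Chunk store: planning arithmetic, codecs, region I/O, interoperability."""

import gzip
import hashlib
import json
import zlib

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ngffkit as nk
from ngffkit.chunkstore import SUPPORTED_DTYPES, chunk_plan, decode_chunk, encode_chunk
from ngffkit.errors import (
    BoundsError,
    ConflictError,
    CorruptChunkError,
    DtypeError,
    EmptyRegionError,
    ShapeMismatchError,
    UnsupportedDtypeError,
)

CODECS = [
    nk.CompressorSpec("none"),
    nk.CompressorSpec("zlib", level=5),
    nk.CompressorSpec("gzip", level=4),
    nk.CompressorSpec("blosc", blosc_cname="zstd", blosc_clevel=5),
]


def brute_force_plan(shape, chunks, region):
    """Element-by-element oracle: which chunk does each element belong to,
    and does the plan's slab bookkeeping cover each exactly once."""
    owners = {}
    for idx in np.ndindex(*[hi - lo for lo, hi in region]):
        absolute = tuple(i + lo for i, (lo, _) in zip(idx, region))
        owners[idx] = tuple(a // c for a, c in zip(absolute, chunks))
    return owners


# ---------------------------------------------------------------------------
# chunk_plan


def test_plan_covers_5x5_grid_with_nine_chunks():
    plan = chunk_plan([5, 5], [2, 2], [(0, 5), (0, 5)], separator=".")
    assert len(plan) == 9
    assert [e.chunk_key for e in plan] == [
        "0.0", "0.1", "0.2", "1.0", "1.1", "1.2", "2.0", "2.1", "2.2",
    ]
    oracle = brute_force_plan((5, 5), (2, 2), ((0, 5), (0, 5)))
    covered = {}
    for e in plan:
        for idx in np.ndindex(*[hi - lo for lo, hi in e.out_slab]):
            pos = tuple(i + lo for i, (lo, _) in zip(idx, e.out_slab))
            assert pos not in covered, "element covered twice"
            covered[pos] = e.grid_index
    assert covered == oracle


def test_plan_single_chunk_for_colocated_volume():
    # a 128x128x64 region matching the chunk shape is one atomic object
    plan = chunk_plan([128, 128, 64], [128, 128, 64], [(0, 128), (0, 128), (0, 64)])
    assert len(plan) == 1
    assert plan[0].chunk_key == "0/0/0"


def test_plan_offset_within_single_chunk():
    (entry,) = chunk_plan([4], [4], [(1, 3)])
    assert entry.chunk_slab == ((1, 3),)
    assert entry.out_slab == ((0, 2),)


def test_plan_rejects_bad_regions():
    with pytest.raises(BoundsError):
        chunk_plan([4, 4], [2, 2], [(0, 5), (0, 4)])
    with pytest.raises(EmptyRegionError):
        chunk_plan([4, 4], [2, 2], [(2, 2), (0, 4)])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.data())
def test_plan_tiles_every_element_exactly_once(data):
    rank = data.draw(st.integers(1, 4))
    shape = tuple(data.draw(st.integers(1, 9)) for _ in range(rank))
    chunks = tuple(data.draw(st.integers(1, 9)) for _ in range(rank))
    region = tuple(
        (lambda lo, hi: (lo, hi))(*sorted(data.draw(
            st.tuples(st.integers(0, s - 1), st.integers(1, s)).filter(lambda p: p[0] < p[1])
        )))
        for s in shape
    )
    plan = chunk_plan(shape, chunks, region)
    counts = np.zeros([hi - lo for lo, hi in region], dtype=int)
    for e in plan:
        counts[tuple(slice(lo, hi) for lo, hi in e.out_slab)] += 1
        for (clo, chi), (olo, ohi) in zip(e.chunk_slab, e.out_slab):
            assert chi - clo == ohi - olo > 0
    assert np.all(counts == 1)
    assert len({e.chunk_key for e in plan}) == len(plan)


# ---------------------------------------------------------------------------
# codecs


def test_encode_none_is_raw_little_endian_bytes():
    spec = nk.ArraySpec(shape=(2, 2), chunk_shape=(2, 2), dtype_code="<u2",
                        compressor=nk.CompressorSpec("none"))
    raw = encode_chunk(np.array([[1, 2], [3, 4]], dtype="<u2"), spec)
    assert raw == b"\x01\x00\x02\x00\x03\x00\x04\x00"


@pytest.mark.parametrize("codec", CODECS, ids=lambda c: c.codec_id)
@pytest.mark.parametrize("dtype_code", SUPPORTED_DTYPES)
def test_codec_roundtrip_random_blocks(codec, dtype_code, rng):
    spec = nk.ArraySpec(shape=(4, 5), chunk_shape=(4, 5), dtype_code=dtype_code,
                        compressor=codec)
    dt = np.dtype(dtype_code)
    if dt.kind == "f":
        block = rng.standard_normal((4, 5)).astype(dt)
    else:
        info = np.iinfo(dt)
        block = rng.integers(info.min, info.max, size=(4, 5), endpoint=True).astype(dt)
    assert np.array_equal(decode_chunk(encode_chunk(block, spec), spec), block)


def test_zlib_compresses_constant_chunk():
    spec = nk.ArraySpec(shape=(64, 64, 64), chunk_shape=(64, 64, 64), dtype_code="<u2",
                        compressor=nk.CompressorSpec("zlib"))
    block = np.zeros((64, 64, 64), dtype="<u2")
    assert len(encode_chunk(block, spec)) < block.nbytes


def test_zlib_bytes_from_independent_implementation_decode():
    spec = nk.ArraySpec(shape=(3, 3), chunk_shape=(3, 3), dtype_code="<i4",
                        compressor=nk.CompressorSpec("zlib"))
    block = np.arange(9, dtype="<i4").reshape(3, 3)
    foreign = zlib.compressobj(6).compress(block.tobytes()) + zlib.compressobj(6).flush()
    # a second, independently configured zlib stream decodes to the same block
    foreign = zlib.compress(block.tobytes(), 1)
    assert np.array_equal(decode_chunk(foreign, spec), block)


def test_gzip_chunks_decode_with_stdlib_gzip():
    spec = nk.ArraySpec(shape=(4,), chunk_shape=(4,), dtype_code="<u2",
                        compressor=nk.CompressorSpec("gzip"))
    block = np.array([9, 8, 7, 6], dtype="<u2")
    assert gzip.decompress(encode_chunk(block, spec)) == block.tobytes()


def test_truncated_chunk_raises_corrupt(tmp_path):
    for codec in CODECS:
        spec = nk.ArraySpec(shape=(4, 4), chunk_shape=(4, 4), dtype_code="<u2",
                            compressor=codec)
        data = encode_chunk(np.arange(16, dtype="<u2").reshape(4, 4), spec)
        with pytest.raises(CorruptChunkError):
            decode_chunk(data[:-3], spec)


def test_unsupported_dtype_rejected():
    with pytest.raises(UnsupportedDtypeError):
        nk.ArraySpec(shape=(4,), chunk_shape=(4,), dtype_code="<c8")


# ---------------------------------------------------------------------------
# array metadata


def test_zarray_metadata_fields(tmp_path):
    spec = nk.ArraySpec(shape=(4, 4), chunk_shape=(2, 2), dtype_code="<u2")
    nk.init_array(tmp_path, "a", spec)
    meta = json.loads((tmp_path / "a" / ".zarray").read_text())
    assert meta["zarr_format"] == 2
    assert meta["shape"] == [4, 4]
    assert meta["chunks"] == [2, 2]
    assert meta["order"] == "C"
    assert meta["filters"] is None
    assert (tmp_path / ".zgroup").exists()


def test_reopen_recovers_spec_exactly(tmp_path):
    spec = nk.ArraySpec(
        shape=(3, 5, 7), chunk_shape=(2, 2, 2), dtype_code="<f4", fill_value=1.5,
        dimension_separator=".", compressor=nk.CompressorSpec("blosc", blosc_shuffle="bit"),
    )
    nk.init_array(tmp_path, "x", spec)
    assert nk.open_array(tmp_path, "x").spec == spec


def test_reinit_identical_is_noop_and_conflict_detected(tmp_path):
    spec = nk.ArraySpec(shape=(4, 4), chunk_shape=(2, 2), dtype_code="<u2")
    nk.init_array(tmp_path, "a", spec).write(np.ones((4, 4), dtype="<u2"))
    before = nk.tree_hash(tmp_path)
    nk.init_array(tmp_path, "a", spec)
    assert nk.tree_hash(tmp_path) == before
    with pytest.raises(ConflictError):
        nk.init_array(tmp_path, "a", nk.ArraySpec(shape=(4, 4), chunk_shape=(4, 4), dtype_code="<u2"))


# ---------------------------------------------------------------------------
# region I/O


def test_fresh_array_reads_fill_value(tmp_path):
    arr = nk.init_array(tmp_path, "a", nk.ArraySpec(shape=(6, 6), chunk_shape=(4, 4),
                                                    dtype_code="<u2", fill_value=255))
    assert np.all(arr.read_region([(1, 5), (0, 6)]) == 255)


def test_null_fill_value_reads_zero(tmp_path):
    arr = nk.init_array(tmp_path, "a", nk.ArraySpec(shape=(4,), chunk_shape=(2,),
                                                    dtype_code="<i2", fill_value=None))
    assert np.all(arr.read() == 0)


def test_read_mixes_written_and_missing_chunks(tmp_path):
    spec = nk.ArraySpec(shape=(4, 8), chunk_shape=(4, 4), dtype_code="<u2", fill_value=255)
    arr = nk.init_array(tmp_path, "a", spec)
    arr.write_region([(0, 4), (0, 4)], np.full((4, 4), 7, dtype="<u2"))
    got = arr.read_region([(0, 4), (2, 6)])
    mirror = np.full((4, 8), 255, dtype="<u2")
    mirror[:, :4] = 7
    assert np.array_equal(got, mirror[:, 2:6])


def test_write_rewrites_chunk_byte_identically(tmp_path):
    spec = nk.ArraySpec(shape=(4, 4), chunk_shape=(4, 4), dtype_code="<u2",
                        compressor=nk.CompressorSpec("zlib"))
    arr = nk.init_array(tmp_path, "a", spec)
    block = np.arange(8, dtype="<u2").reshape(2, 4)
    arr.write_region([(0, 2), (0, 4)], block)
    h1 = hashlib.sha256((tmp_path / "a" / "0" / "0").read_bytes()).hexdigest()
    arr.write_region([(0, 2), (0, 4)], block)
    h2 = hashlib.sha256((tmp_path / "a" / "0" / "0").read_bytes()).hexdigest()
    assert h1 == h2


def test_locality_only_intersecting_chunks_opened(tmp_path):
    spec = nk.ArraySpec(shape=(8, 8), chunk_shape=(2, 2), dtype_code="<u2")
    arr = nk.init_array(tmp_path, "a", spec)
    arr.write(np.arange(64, dtype="<u2").reshape(8, 8))
    arr.io_counters["chunks_read"] = 0
    arr.read_region([(0, 2), (0, 2)])  # exactly one chunk
    assert arr.io_counters["chunks_read"] == 1
    arr.io_counters["chunks_read"] = 0
    arr.read_region([(1, 4), (0, 3)])
    assert arr.io_counters["chunks_read"] == len(
        chunk_plan((8, 8), (2, 2), [(1, 4), (0, 3)])
    )


def test_write_errors(tmp_path):
    arr = nk.init_array(tmp_path, "a", nk.ArraySpec(shape=(4, 4), chunk_shape=(2, 2),
                                                    dtype_code="<u2"))
    with pytest.raises(ShapeMismatchError):
        arr.write_region([(0, 2), (0, 2)], np.zeros((3, 2), dtype="<u2"))
    with pytest.raises(DtypeError):
        arr.write_region([(0, 2), (0, 2)], np.full((2, 2), 1.5))
    # value-exact coercion from a wider dtype is allowed
    arr.write_region([(0, 2), (0, 2)], np.full((2, 2), 9, dtype=np.int64))
    assert np.all(arr.read_region([(0, 2), (0, 2)]) == 9)


def test_corrupt_chunk_error_names_key(tmp_path):
    spec = nk.ArraySpec(shape=(4, 4), chunk_shape=(2, 2), dtype_code="<u2",
                        compressor=nk.CompressorSpec("zlib"))
    arr = nk.init_array(tmp_path, "a", spec)
    arr.write(np.ones((4, 4), dtype="<u2"))
    victim = tmp_path / "a" / "1" / "0"
    victim.write_bytes(victim.read_bytes()[:2])
    with pytest.raises(CorruptChunkError) as err:
        arr.read()
    assert err.value.key == "1/0"


@pytest.mark.parametrize("dtype_code", SUPPORTED_DTYPES)
@pytest.mark.parametrize("codec", CODECS, ids=lambda c: c.codec_id)
def test_whole_array_roundtrip_every_dtype_and_codec(tmp_path, rng, dtype_code, codec):
    dt = np.dtype(dtype_code)
    if dt.kind == "f":
        data = rng.standard_normal((5, 6)).astype(dt)
    else:
        info = np.iinfo(dt)
        data = rng.integers(info.min, info.max, size=(5, 6), endpoint=True).astype(dt)
    arr = nk.init_array(tmp_path, dtype_code.strip("<|"),
                        nk.ArraySpec(shape=(5, 6), chunk_shape=(2, 4),
                                     dtype_code=dtype_code, compressor=codec))
    arr.write(data)
    assert np.array_equal(nk.open_array(tmp_path, dtype_code.strip("<|")).read(), data)


def test_randomized_read_write_matches_in_memory_mirror(tmp_path, rng):
    """200 random (shape, chunks, region, values) cases vs. a plain ndarray."""
    for case in range(200):
        rank = int(rng.integers(1, 4))
        shape = tuple(int(s) for s in rng.integers(1, 10, size=rank))
        chunks = tuple(int(c) for c in rng.integers(1, 10, size=rank))
        spec = nk.ArraySpec(shape=shape, chunk_shape=chunks, dtype_code="<i4",
                            dimension_separator="/" if case % 2 else ".")
        root = tmp_path / f"case{case}"
        arr = nk.init_array(root, "", spec)
        mirror = np.zeros(shape, dtype="<i4")
        for _ in range(3):
            lo = [int(rng.integers(0, s)) for s in shape]
            hi = [int(rng.integers(l + 1, s + 1)) for l, s in zip(lo, shape)]
            region = list(zip(lo, hi))
            block = rng.integers(-1000, 1000, size=[h - l for l, h in region]).astype("<i4")
            arr.write_region(region, block)
            mirror[tuple(slice(l, h) for l, h in region)] = block
        assert np.array_equal(arr.read(), mirror)
        lo = [int(rng.integers(0, s)) for s in shape]
        hi = [int(rng.integers(l + 1, s + 1)) for l, s in zip(lo, shape)]
        sub = tuple(slice(l, h) for l, h in zip(lo, hi))
        assert np.array_equal(arr.read_region(list(zip(lo, hi))), mirror[sub])


# ---------------------------------------------------------------------------
# cross-implementation interoperability (zarr as independent oracle)


@pytest.mark.parametrize("codec", CODECS, ids=lambda c: c.codec_id)
def test_zarr_reads_our_stores(tmp_path, rng, codec):
    zarr = pytest.importorskip("zarr")
    data = rng.integers(0, 60000, size=(9, 7), endpoint=True).astype("<u2")
    arr = nk.init_array(tmp_path / "ours", "", nk.ArraySpec(
        shape=(9, 7), chunk_shape=(4, 3), dtype_code="<u2", compressor=codec))
    arr.write(data)
    theirs = zarr.open_array(str(tmp_path / "ours"), mode="r")
    assert np.array_equal(theirs[:], data)


def test_we_read_zarr_written_stores(tmp_path):
    zarr = pytest.importorskip("zarr")
    numcodecs = pytest.importorskip("numcodecs")
    for name, codec in [("zlib", numcodecs.Zlib(level=5)),
                        ("blosc", numcodecs.Blosc(cname="lz4", clevel=3, shuffle=1)),
                        ("raw", None)]:
        p = tmp_path / name
        za = zarr.create_array(store=str(p), shape=(6, 7), chunks=(3, 4), dtype="uint16",
                               zarr_format=2, fill_value=0, compressors=codec)
        expect = np.arange(42, dtype=np.uint16).reshape(6, 7)
        za[:] = expect
        assert np.array_equal(nk.open_array(p, "").read(), expect)
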