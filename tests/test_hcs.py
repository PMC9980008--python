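"""Plate/well/field hierarchy, montage geometry, label attachment."""

import numpy as np
import pytest

import ngffkit as nk
from ngffkit import hcs
from ngffkit.errors import (
    DtypeError,
    DuplicateWellError,
    NotFoundError,
    ShapeMismatchError,
)

TEMPLATE = hcs.ImageTemplate(shape=(1, 1, 1, 64, 64), dtype_code="<u2")


def test_full_plate_enumerates_cartesian_wells(tmp_path):
    doc = nk.create_plate(tmp_path, ["A", "B"], ["1", "2", "3"], image_template=TEMPLATE)
    assert [w.path for w in doc.wells] == ["A/1", "A/2", "A/3", "B/1", "B/2", "B/3"]
    for w in doc.wells:
        assert (tmp_path / w.path / ".zattrs").exists()
        assert doc.rows[w.row_index] + "/" + doc.columns[w.column_index] == w.path


def test_plate_doc_roundtrips_from_disk(tmp_path):
    nk.create_plate(tmp_path, ["A", "B"], ["1", "2"], wells=[("A", "1"), ("B", "2")],
                    fields_per_well=2, image_template=TEMPLATE)
    doc = nk.open_plate(tmp_path)
    assert doc.rows == ("A", "B") and doc.columns == ("1", "2")
    assert [w.path for w in doc.wells] == ["A/1", "B/2"]
    assert doc.field_count == 2


def test_well_doc_lists_field_paths(tmp_path):
    nk.create_plate(tmp_path, ["A"], ["1"], fields_per_well=2, image_template=TEMPLATE)
    well = hcs._well_doc(tmp_path, "A/1")
    assert [img["path"] for img in well.images] == ["0", "1"]


def test_duplicate_well_rejected(tmp_path):
    with pytest.raises(DuplicateWellError):
        nk.create_plate(tmp_path, ["A"], ["1"], wells=[("A", "1"), ("A", "1")],
                        image_template=TEMPLATE)


def test_recreate_identical_plate_is_noop(tmp_path):
    nk.create_plate(tmp_path, ["A"], ["1", "2"], image_template=TEMPLATE)
    before = nk.tree_hash(tmp_path)
    nk.create_plate(tmp_path, ["A"], ["1", "2"], image_template=TEMPLATE)
    assert nk.tree_hash(tmp_path) == before


def test_write_then_read_field_roundtrip(tmp_path, rng):
    nk.create_plate(tmp_path, ["A"], ["1"], image_template=TEMPLATE)
    data = rng.integers(0, 60000, size=(1, 1, 1, 64, 64)).astype("<u2")
    nk.write_field(tmp_path, "A/1", 0, data)
    assert np.array_equal(nk.read_field(tmp_path, "A/1", 0), data)


def test_unwritten_field_reads_fill_value(tmp_path):
    nk.create_plate(tmp_path, ["A"], ["1"], fields_per_well=2, image_template=TEMPLATE)
    assert np.all(nk.read_field(tmp_path, "A/1", 1) == 0)


def test_unknown_well_or_field_raises(tmp_path):
    nk.create_plate(tmp_path, ["A"], ["1"], image_template=TEMPLATE)
    with pytest.raises(NotFoundError):
        nk.write_field(tmp_path, "B/9", 0, np.zeros((1, 1, 1, 64, 64), dtype="<u2"))
    with pytest.raises(NotFoundError):
        nk.read_field(tmp_path, "A/1", 5)


def test_fields_are_sibling_directories_with_private_chunks(tmp_path):
    nk.create_plate(tmp_path, ["A"], ["1"], fields_per_well=2, image_template=TEMPLATE)
    nk.write_field(tmp_path, "A/1", 0, np.ones((1, 1, 1, 64, 64), dtype="<u2"))
    nk.write_field(tmp_path, "A/1", 1, np.full((1, 1, 1, 64, 64), 2, dtype="<u2"))
    f0 = {p.relative_to(tmp_path / "A/1/0") for p in (tmp_path / "A/1/0").rglob("*") if p.is_file()}
    f1 = {p.relative_to(tmp_path / "A/1/1") for p in (tmp_path / "A/1/1").rglob("*") if p.is_file()}
    assert f0 and f1
    assert not ((tmp_path / "A/1/0").samefile(tmp_path / "A/1/1"))
    assert np.all(nk.read_field(tmp_path, "A/1", 0) == 1)
    assert np.all(nk.read_field(tmp_path, "A/1", 1) == 2)


# ---------------------------------------------------------------------------
# montage


def test_montage_geometry_2x3_plate(tmp_path):
    nk.synth_plate(tmp_path, 2, 3, 1, nk.SceneSpec(shape=(1, 1, 1, 64, 64)), seed=0)
    mosaic = nk.render_plate_montage(tmp_path)
    assert mosaic.shape == (128, 192)


def test_montage_missing_well_is_fill_value(tmp_path):
    template = hcs.ImageTemplate(shape=(1, 1, 1, 16, 16), dtype_code="<u2")
    nk.create_plate(tmp_path, ["A", "B"], ["1"], wells=[("A", "1")], image_template=template)
    nk.write_field(tmp_path, "A/1", 0, np.full((1, 1, 1, 16, 16), 9, dtype="<u2"))
    mosaic = nk.render_plate_montage(tmp_path)
    assert mosaic.shape == (32, 16)
    assert np.all(mosaic[:16] == 9)
    assert np.all(mosaic[16:] == 0)  # the absent B/1 tile


def test_montage_single_well_single_field_is_identity(tmp_path, rng):
    template = hcs.ImageTemplate(shape=(1, 1, 1, 16, 16), dtype_code="<u2")
    nk.create_plate(tmp_path, ["A"], ["1"], image_template=template)
    data = rng.integers(0, 100, size=(1, 1, 1, 16, 16)).astype("<u2")
    nk.write_field(tmp_path, "A/1", 0, data)
    assert np.array_equal(nk.render_plate_montage(tmp_path), data[0, 0, 0])


def test_montage_fields_pack_near_square(tmp_path):
    template = hcs.ImageTemplate(shape=(1, 1, 1, 8, 8), dtype_code="<u2")
    nk.create_plate(tmp_path, ["A"], ["1"], fields_per_well=3, image_template=template)
    for f, v in enumerate((1, 2, 3)):
        nk.write_field(tmp_path, "A/1", f, np.full((1, 1, 1, 8, 8), v, dtype="<u2"))
    mosaic = nk.render_plate_montage(tmp_path)
    # 3 fields -> 2 cols x 2 rows of 8x8 tiles
    assert mosaic.shape == (16, 16)
    assert np.all(mosaic[:8, :8] == 1)
    assert np.all(mosaic[:8, 8:] == 2)
    assert np.all(mosaic[8:, :8] == 3)
    assert np.all(mosaic[8:, 8:] == 0)


def test_montage_dimension_formula_randomized(tmp_path, rng):
    import math

    for trial in range(4):
        rows = int(rng.integers(1, 5))
        cols = int(rng.integers(1, 5))
        fields = int(rng.integers(1, 5))
        side = int(rng.choice([8, 16]))
        root = tmp_path / f"p{trial}"
        nk.synth_plate(root, rows, cols, fields,
                       nk.SceneSpec(shape=(1, 1, 1, side, side)), seed=trial)
        mosaic = nk.render_plate_montage(root)
        gc = math.ceil(math.sqrt(fields))
        gr = math.ceil(fields / gc)
        assert mosaic.shape == (rows * gr * side, cols * gc * side)


# ---------------------------------------------------------------------------
# labels


def test_attach_two_labels_listed_in_insertion_order(tmp_path):
    data, labels, _ = nk.synth_image(nk.SceneSpec(shape=(1, 1, 4, 32, 32), pattern="spots",
                                                  n_spots=3, seed=5))
    nk.write_multiscale_image(tmp_path, "", data, n_levels=1)
    nk.attach_labels(tmp_path, "", "nuclei", labels)
    nk.attach_labels(tmp_path, "", "cells", labels)
    attrs = nk.read_attributes(tmp_path / "labels")
    assert attrs["labels"] == ["nuclei", "cells"]


def test_label_pyramid_values_subset_of_level0(tmp_path):
    data, labels, _ = nk.synth_image(nk.SceneSpec(shape=(1, 1, 4, 32, 32), pattern="spots",
                                                  n_spots=3, seed=5))
    nk.write_multiscale_image(tmp_path, "", data, n_levels=1)
    nk.attach_labels(tmp_path, "", "spots", labels, n_levels=2)
    lvl1 = nk.read_level(tmp_path, "labels/spots", 1)
    assert set(np.unique(lvl1)) <= set(np.unique(labels))


def test_label_colors_roundtrip(tmp_path):
    data, labels, _ = nk.synth_image(nk.SceneSpec(shape=(1, 1, 4, 32, 32), pattern="spots",
                                                  n_spots=2, seed=5))
    nk.write_multiscale_image(tmp_path, "", data, n_levels=1)
    nk.attach_labels(tmp_path, "", "spots", labels, colors={1: (255, 0, 0, 255)})
    attrs = nk.read_attributes(tmp_path / "labels" / "spots")
    assert attrs["image-label"]["colors"] == [{"label-value": 1, "rgba": [255, 0, 0, 255]}]
    assert attrs["image-label"]["source"] == {"image": "../../"}


def test_float_label_data_rejected(tmp_path):
    data, labels, _ = nk.synth_image(nk.SceneSpec(shape=(1, 1, 4, 32, 32), pattern="spots",
                                                  n_spots=2, seed=5))
    nk.write_multiscale_image(tmp_path, "", data, n_levels=1)
    with pytest.raises(DtypeError):
        nk.attach_labels(tmp_path, "", "bad", labels.astype(np.float32))
    with pytest.raises(ShapeMismatchError):
        nk.attach_labels(tmp_path, "", "bad", labels[:, :16, :])
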