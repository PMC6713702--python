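"""Annotation CSV dialects, patchification and the train/test split."""

import numpy as np
import pytest

from organoidquant import (
    AnnotationRecord,
    Box,
    patchify_for_annotation,
    read_annotation_csv,
    train_test_split,
    write_annotation_csv,
)


def rec(filename, box, size=300):
    return AnnotationRecord(filename, size, size, "organoid", box)


class TestReadAnnotationCsv:
    def test_direct_parse(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text(
            "filename,width,height,class,xmin,ymin,xmax,ymax\n"
            "img1.png,300,300,organoid,10,20,50,80\n"
        )
        records = read_annotation_csv(p)
        assert len(records) == 1
        assert records[0].box == Box(10, 20, 50, 80)
        assert records[0].class_label == "organoid"

    def test_column_order_is_insensitive(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text(
            "xmin,ymin,xmax,ymax,filename,width,height,class\n"
            "10,20,50,80,img1.png,300,300,organoid\n"
        )
        assert read_annotation_csv(p)[0].box == Box(10, 20, 50, 80)

    def test_degenerate_row_rejected_with_row_number(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text(
            "filename,width,height,class,xmin,ymin,xmax,ymax\n"
            "img1.png,300,300,organoid,10,20,50,80\n"
            "img1.png,300,300,organoid,50,20,50,80\n"
        )
        with pytest.raises(ValueError, match="row 3"):
            read_annotation_csv(p)

    def test_out_of_frame_row_rejected(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text(
            "filename,width,height,class,xmin,ymin,xmax,ymax\n"
            "img1.png,300,300,organoid,10,20,500,80\n"
        )
        with pytest.raises(ValueError, match="row 2"):
            read_annotation_csv(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("filename,width,height,class,xmin,ymin,xmax\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_annotation_csv(p)

    def test_xywh_dialect_converted_to_corners(self, tmp_path):
        # the raw crowdsourcing export carries box width/height, not corners
        p = tmp_path / "raw.csv"
        p.write_text(
            "filename,width,height,class,xmin,ymin,box_width,box_height\n"
            "img1.png,300,300,organoid,10,20,40,60\n"
        )
        records = read_annotation_csv(p, dialect="xywh")
        assert records[0].box == Box(10, 20, 50, 80)

    def test_unexpected_patch_size_warns_when_strict(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text(
            "filename,width,height,class,xmin,ymin,xmax,ymax\n"
            "img1.png,512,512,organoid,10,20,50,80\n"
        )
        with pytest.warns(UserWarning, match="patch sizes"):
            read_annotation_csv(p, strict_sizes=True)


class TestWriteAnnotationCsv:
    def test_empty_records_header_only(self, tmp_path):
        p = tmp_path / "out.csv"
        write_annotation_csv([], p)
        assert p.read_text().splitlines() == [
            "filename,width,height,class,xmin,ymin,xmax,ymax"
        ]

    def test_round_trip_identity_on_random_records(self, tmp_path, rng):
        records = []
        for i in range(100):
            x, y = int(rng.integers(0, 250)), int(rng.integers(0, 250))
            w, h = int(rng.integers(1, 50)), int(rng.integers(1, 50))
            records.append(
                rec(f"img{int(rng.integers(0, 10))}.png", Box(x, y, x + w, y + h))
            )
        p = tmp_path / "out.csv"
        write_annotation_csv(records, p)
        assert read_annotation_csv(p) == records  # order preserved too


class TestPatchify:
    def test_grid_counts_at_both_published_sizes(self, rng):
        img = rng.integers(0, 255, (1125, 1500), dtype=np.uint8)
        assert len(patchify_for_annotation(img, [300])) == 15  # 5 x 3
        assert len(patchify_for_annotation(img, [450])) == 6  # 3 x 2
        assert len(patchify_for_annotation(img, [300, 450])) == 21

    def test_too_small_image_skips_size_with_warning(self, rng):
        img = rng.integers(0, 255, (299, 299), dtype=np.uint8)
        with pytest.warns(UserWarning, match="skipped"):
            out = patchify_for_annotation(img, [300])
        assert out == []

    def test_patches_are_exact_source_crops(self, rng):
        img = rng.integers(0, 255, (600, 900), dtype=np.uint8)
        patches = dict(
            (name, patch)
            for patch, name in patchify_for_annotation(img, [300], "src")
        )
        np.testing.assert_array_equal(
            patches["src_s300_x1_y1.png"], img[300:600, 300:600]
        )
        assert all(p.shape == (300, 300) for p in patches.values())


class TestTrainTestSplit:
    def _records(self, n_files=10, boxes_per_file=3):
        out = []
        for i in range(n_files):
            for j in range(boxes_per_file):
                out.append(
                    rec(f"img{i:02d}.png", Box(10 * j, 0, 10 * j + 8, 8))
                )
        return out

    def test_ten_files_at_ten_percent_gives_one_test_file(self):
        train, test = train_test_split(self._records(10), 0.1, seed=0)
        assert len({r.filename for r in test}) == 1
        assert len({r.filename for r in train}) == 9

    def test_partition_by_filename(self):
        records = self._records(7)
        train, test = train_test_split(records, 0.3, seed=1)
        assert sorted(train + test, key=lambda r: (r.filename, r.box.as_tuple())) == \
            sorted(records, key=lambda r: (r.filename, r.box.as_tuple()))
        assert {r.filename for r in train} & {r.filename for r in test} == set()

    def test_same_seed_reproduces_split(self):
        records = self._records(20)
        s1 = train_test_split(records, 0.2, seed=9)
        s2 = train_test_split(records, 0.2, seed=9)
        assert s1 == s2

    def test_single_filename_rejected(self):
        records = [rec("only.png", Box(0, 0, 10, 10))]
        with pytest.raises(ValueError, match="2 distinct"):
            train_test_split(records, 0.5)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            train_test_split(self._records(), 1.0)
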