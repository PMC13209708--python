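"""Compound table I/O, pIC50 conversion, and split assignment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sunqsar.data import (
    CompoundRecord,
    CompoundTableError,
    Dataset,
    MODELING_DESCRIPTORS,
    from_pic50,
    random_split,
    read_compound_table,
    to_pic50,
    write_compound_table,
)


class TestReadCompoundTable:
    def test_packaged_fixture(self, sunscreens):
        assert len(sunscreens) == 16
        ocr = next(r for r in sunscreens if r.id == "OCR")
        assert ocr.descriptors["nRot"] == 10
        assert ocr.descriptors["Flex"] == 0.667
        assert ocr.descriptors["logD"] == 4.52
        assert all(r.complete for r in sunscreens)

    def test_header_only(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("id,nRot,Flex,Fsp3,logD,caco2,PPB\n")
        assert len(read_compound_table(p)) == 0

    def test_unicode_minus_normalized(self, tmp_path):
        p = tmp_path / "u.csv"
        p.write_text(
            "id,nRot,Flex,Fsp3,logD,caco2,PPB\n"
            "a,1,0.1,0.2,1.5,−4.94,50\n"
            "b,2,0.2,0.3,−0.5,-5.1,60\n"
            "c,3,0.3,0.4,2.0,-4.8,70\n",
            encoding="utf-8")
        ds = read_compound_table(p)
        assert ds.records[0].descriptors["caco2"] == -4.94
        assert ds.records[1].descriptors["logD"] == -0.5

    def test_missing_id_column(self, tmp_path):
        p = tmp_path / "noid.csv"
        p.write_text("name,nRot\na,1\n")
        with pytest.raises(CompoundTableError, match="id"):
            read_compound_table(p)

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("id,nRot\na,1\nb,oops\n")
        with pytest.raises(CompoundTableError, match=r"row 2.*'nRot'"):
            read_compound_table(p)

    def test_incomplete_row_flagged_unassigned(self, tmp_path):
        p = tmp_path / "inc.csv"
        p.write_text("id,nRot,Flex,Fsp3,logD,caco2,PPB,split\n"
                     "a,1,0.1,0.2,1.5,-4.9,50,train\n"
                     "b,2,,0.3,1.0,-5.0,60,train\n")
        ds = read_compound_table(p)
        assert ds.records[0].complete and ds.records[0].split == "train"
        assert not ds.records[1].complete
        assert ds.records[1].split == "unassigned"

    def test_round_trip_full_precision(self, tmp_path, rng):
        recs = [CompoundRecord(id=f"c{i}",
                               descriptors={n: float(v) for n, v in
                                            zip(MODELING_DESCRIPTORS,
                                                rng.standard_normal(6))},
                               pic50=float(rng.standard_normal()))
                for i in range(7)]
        ds = Dataset(recs)
        p = tmp_path / "rt.csv"
        write_compound_table(ds, p)
        back = read_compound_table(p)
        for a, b in zip(ds.records, back.records):
            assert a.descriptors == b.descriptors  # bit-exact
            assert a.pic50 == b.pic50


class TestPic50:
    @pytest.mark.parametrize("nm,expected,tol", [
        (1.0, 9.0, 1e-12),
        (1000.0, 6.0, 1e-12),
        (53.7, 7.27, 0.005),
    ])
    def test_values(self, nm, expected, tol):
        assert to_pic50(nm) == pytest.approx(expected, abs=tol)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            to_pic50(bad)

    @given(st.floats(min_value=1e-6, max_value=1e9),
           st.floats(min_value=1.000001, max_value=100))
    @settings(max_examples=50, derandomize=True)
    def test_strictly_decreasing_and_invertible(self, nm, factor):
        assert to_pic50(nm * factor) < to_pic50(nm)
        assert from_pic50(to_pic50(nm)) == pytest.approx(nm, rel=1e-9)


class TestRecordInvariants:
    def test_pic50_derived_from_ic50(self):
        r = CompoundRecord(id="x", ic50_nM=53.7)
        assert r.pic50 == pytest.approx(9 - math.log10(53.7), abs=1e-12)

    def test_inconsistent_activity_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            CompoundRecord(id="x", ic50_nM=100.0, pic50=8.5)

    def test_flex_consistency_checked(self):
        with pytest.raises(ValueError, match="Flex"):
            CompoundRecord(id="x", descriptors={"nRot": 6, "nRig": 12,
                                                "Flex": 0.9})
        CompoundRecord(id="ok", descriptors={"nRot": 6, "nRig": 12,
                                             "Flex": 0.5})


class TestRandomSplit:
    def _dataset(self, n):
        return Dataset([CompoundRecord(id=f"c{i}") for i in range(n)])

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_reference_counts_100_21(self, seed):
        ds = random_split(self._dataset(121),
                          {"train": 100 / 121, "test": 21 / 121}, seed=seed)
        labels = [r.split for r in ds.records]
        assert labels.count("train") == 100
        assert labels.count("test") == 21

    def test_all_train(self):
        ds = random_split(self._dataset(4), {"train": 1.0}, seed=0)
        assert all(r.split == "train" for r in ds.records)

    def test_different_seeds_differ_same_counts(self):
        a = random_split(self._dataset(8), {"train": 0.75, "test": 0.25}, seed=1)
        b = random_split(self._dataset(8), {"train": 0.75, "test": 0.25}, seed=2)
        for ds in (a, b):
            labels = [r.split for r in ds.records]
            assert labels.count("train") == 6 and labels.count("test") == 2
        assert [r.split for r in a.records] != [r.split for r in b.records]

    def test_deterministic_under_seed(self):
        a = random_split(self._dataset(30), {"train": 0.7, "test": 0.3}, seed=5)
        b = random_split(self._dataset(30), {"train": 0.7, "test": 0.3}, seed=5)
        assert [r.split for r in a.records] == [r.split for r in b.records]

    def test_counts_independent_of_input_order(self):
        base = self._dataset(23)
        shuffled = Dataset(list(reversed(base.records)))
        f = {"train": 0.6, "test": 0.2, "validation": 0.2}
        c1 = [r.split for r in random_split(base, f, seed=3).records]
        c2 = [r.split for r in random_split(shuffled, f, seed=3).records]
        for lbl in ("train", "test", "validation"):
            assert c1.count(lbl) == c2.count(lbl)

    def test_empty_dataset_rejected(self):
        with pytest.raises(CompoundTableError):
            random_split(self._dataset(0), {"train": 1.0}, seed=0)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            random_split(self._dataset(5), {"train": 0.5, "test": 0.3}, seed=0)
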