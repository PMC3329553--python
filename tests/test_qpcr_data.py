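import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import refstab as rs
from refstab.qpcr_data import CqDataError, LONG_COLUMNS


def make_table(rows):
    return rs.CqTable(pd.DataFrame(rows, columns=LONG_COLUMNS))


class TestReaders:
    def test_long_csv_parses_all_rows(self, long_cq_csv):
        table = rs.read_cq_table(long_cq_csv)
        assert len(table) == 3
        assert sorted(table.data["cq"]) == [20.1, 20.2, 20.3]

    def test_wide_matrix_melts_to_long(self, tmp_path):
        path = tmp_path / "wide.csv"
        path.write_text("gene,s1,s2\ng1,20,21\ng2,22,23\n")
        table = rs.read_cq_table(path, dialect="wide")
        assert len(table) == 4
        assert set(table.genes) == {"g1", "g2"}
        assert set(table.samples) == {"s1", "s2"}
        assert (table.data["plate"] == "1").all()

    def test_undetermined_cell_becomes_marker_not_zero(self, tmp_path):
        path = tmp_path / "cq.csv"
        path.write_text("sample,gene,cq\ns1,g1,Undetermined\ns2,g1,20\n")
        table = rs.read_cq_table(path)
        undet = table.data.loc[table.data["sample"] == "s1", "cq"].iloc[0]
        assert np.isnan(undet) and undet != 0

    def test_duplicate_key_names_offender(self, tmp_path):
        path = tmp_path / "cq.csv"
        path.write_text(
            "sample,gene,plate,bio_rep,tech_rep,cq\ns1,g1,1,1,1,20\ns1,g1,1,1,1,21\n"
        )
        with pytest.raises(CqDataError, match="s1.*g1"):
            rs.read_cq_table(path)

    def test_garbage_cq_reports_row(self, tmp_path):
        path = tmp_path / "cq.csv"
        path.write_text("sample,gene,cq\ns1,g1,20\ns2,g1,oops\n")
        with pytest.raises(CqDataError, match="row 3"):
            rs.read_cq_table(path)

    def test_round_trip_preserves_records(self, tmp_path):
        rows = [
            ("s1", "g1", "p1", 1, 1, 20.125),
            ("s1", "g1", "p1", 1, 2, np.nan),
            ("s2", "g2", "p2", 2, 1, 33.333333333333336),
        ]
        table = make_table(rows)
        path = tmp_path / "out.csv"
        rs.write_cq_table(table, path)
        back = rs.read_cq_table(path)
        pd.testing.assert_frame_equal(
            back.data.sort_values(LONG_COLUMNS[:5]).reset_index(drop=True),
            table.data.sort_values(LONG_COLUMNS[:5]).reset_index(drop=True),
        )

    def test_cq_bounds_enforced(self):
        with pytest.raises(CqDataError, match="out of"):
            make_table([("s1", "g1", "1", 1, 1, 46.0)])


class TestAggregateTechnical:
    def test_identical_replicates(self):
        table = make_table(
            [("s1", "g1", "1", 1, r, 20.0) for r in (1, 2, 3)]
        )
        agg = rs.aggregate_technical(table)
        row = agg.iloc[0]
        assert row["cq_mean"] == 20.0 and row["cq_sd"] == 0.0
        assert row["n_tech"] == 3 and not row["flagged"]

    def test_two_replicates_sd_and_flag(self):
        table = make_table(
            [("s1", "g1", "1", 1, 1, 20.0), ("s1", "g1", "1", 1, 2, 21.0)]
        )
        agg = rs.aggregate_technical(table, sd_threshold=0.5)
        row = agg.iloc[0]
        assert row["cq_mean"] == 20.5
        assert row["cq_sd"] == pytest.approx(0.7071, abs=1e-4)
        assert row["flagged"]

    def test_all_undetermined_aggregates_undetermined(self):
        table = make_table(
            [("s1", "g1", "1", 1, r, np.nan) for r in (1, 2, 3)]
        )
        agg = rs.aggregate_technical(table)
        assert np.isnan(agg.iloc[0]["cq_mean"]) and agg.iloc[0]["n_tech"] == 3

    def test_undetermined_excluded_from_mean_but_counted(self):
        table = make_table(
            [("s1", "g1", "1", 1, 1, 20.0), ("s1", "g1", "1", 1, 2, np.nan)]
        )
        row = rs.aggregate_technical(table).iloc[0]
        assert row["cq_mean"] == 20.0 and row["n_tech"] == 2
        assert row["cq_sd"] == 0.0 and not row["flagged"]

    @given(perm=st.permutations([20.0, 20.4, 21.1]))
    @settings(max_examples=10, deadline=None)
    def test_mean_invariant_to_replicate_order(self, perm):
        table = make_table(
            [("s1", "g1", "1", 1, r + 1, cq) for r, cq in enumerate(perm)]
        )
        row = rs.aggregate_technical(table).iloc[0]
        assert row["cq_mean"] == pytest.approx(np.mean([20.0, 20.4, 21.1]))
        assert row["cq_sd"] == pytest.approx(np.std([20.0, 20.4, 21.1], ddof=1))


class TestInterplateCalibrate:
    def two_plate_table(self):
        # calibrator 'cal' measured for g on both plates: Cq 20 vs 21
        return make_table(
            [
                ("cal", "g", "p1", 1, 1, 20.0),
                ("a", "g", "p1", 1, 1, 25.0),
                ("cal", "g", "p2", 1, 1, 21.0),
                ("b", "g", "p2", 1, 1, 25.0),
            ]
        )

    def test_single_plate_is_identity(self):
        table = make_table(
            [("cal", "g", "p1", 1, 1, 20.0), ("a", "g", "p1", 1, 1, 25.0)]
        )
        out = rs.interplate_calibrate(table, "cal")
        pd.testing.assert_frame_equal(out.data, table.data)

    def test_two_plates_center_on_mean(self):
        out = rs.interplate_calibrate(self.two_plate_table(), "cal").data
        cq = out.set_index(["sample", "plate"])["cq"]
        # across-plate calibrator mean 20.5: plate-1 shifts +0.5, plate-2 -0.5
        assert cq[("a", "p1")] == 25.5
        assert cq[("b", "p2")] == 24.5
        assert cq[("cal", "p1")] == 20.5 and cq[("cal", "p2")] == 20.5

    def test_equal_calibrator_no_change(self):
        table = make_table(
            [
                ("cal", "g", "p1", 1, 1, 20.0),
                ("cal", "g", "p2", 1, 1, 20.0),
                ("a", "g", "p2", 1, 1, 24.0),
            ]
        )
        out = rs.interplate_calibrate(table, "cal")
        pd.testing.assert_frame_equal(out.data, table.data)

    def test_missing_calibrator_plate_errors(self):
        table = make_table(
            [
                ("cal", "g", "p1", 1, 1, 20.0),
                ("a", "g", "p2", 1, 1, 25.0),
            ]
        )
        with pytest.raises(CqDataError, match=r"\('g', 'p2'\)"):
            rs.interplate_calibrate(table, "cal")

    def test_within_plate_gene_differences_unchanged(self):
        # an additive plate effect (same +1 cycle for every gene on plate 2)
        # is removed without touching between-gene differences within a plate
        table = make_table(
            [
                ("cal", "g1", "p1", 1, 1, 20.0),
                ("cal", "g2", "p1", 1, 1, 18.0),
                ("a", "g1", "p1", 1, 1, 25.0),
                ("a", "g2", "p1", 1, 1, 23.5),
                ("cal", "g1", "p2", 1, 1, 21.0),
                ("cal", "g2", "p2", 1, 1, 19.0),
                ("a2", "g1", "p2", 1, 1, 24.0),
                ("a2", "g2", "p2", 1, 1, 22.0),
            ]
        )
        out = rs.interplate_calibrate(table, "cal").data
        before = table.data.set_index(["plate", "sample", "gene"])["cq"]
        after = out.set_index(["plate", "sample", "gene"])["cq"]
        for plate, sample in (("p1", "a"), ("p2", "a2"), ("p1", "cal"), ("p2", "cal")):
            assert (
                before[plate][sample]["g1"] - before[plate][sample]["g2"]
            ) == pytest.approx(after[plate][sample]["g1"] - after[plate][sample]["g2"])


def test_sample_meta_validation():
    with pytest.raises(CqDataError, match="duplicate"):
        rs.SampleMeta(pd.DataFrame({"sample": ["s1", "s1"], "group": ["a", "b"]}))
    meta = rs.SampleMeta(pd.DataFrame({"sample": ["s1"], "group": ["leaf"]}))
    with pytest.raises(CqDataError, match="without metadata"):
        meta.require_samples(["s1", "s2"])
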