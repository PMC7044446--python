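import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_table
from oracles import recount_coverage_filter

from methdiff.meth_io import (
    CpGParseError,
    CpGTable,
    CpGValidationError,
    FeatureSet,
    combine_technical_replicates,
    estimate_nonconversion,
    filter_by_coverage,
    read_cpg_table,
    write_cpg_table,
)


class TestReadCpGTable:
    def test_direct_parse(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("chr1\t100\t101\t30\t27\n")
        t = read_cpg_table(p, "s1", "UN")
        assert len(t) == 1
        row = t.data.iloc[0]
        assert (row["chrom"], row["pos"], row["coverage"], row["meth_calls"]) == (
            "chr1", 100, 30, 27,
        )
        assert t.rates.iloc[0] == pytest.approx(0.9)

    def test_meth_exceeds_coverage(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("chr1\t100\t101\t10\t11\n")
        with pytest.raises(CpGValidationError, match="line 1"):
            read_cpg_table(p, "s1", "UN")

    def test_malformed_line_number(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("chr1\t100\t101\t30\t27\nchr1\tx\t101\t30\t27\n")
        with pytest.raises(CpGParseError, match="line 2"):
            read_cpg_table(p, "s1", "UN")

    def test_wrong_field_count(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("chr1\t100\t101\t30\n")
        with pytest.raises(CpGParseError, match="5 tab-separated"):
            read_cpg_table(p, "s1", "UN")

    def test_bad_interval_width(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("chr1\t100\t103\t30\t27\n")
        with pytest.raises(CpGParseError, match="end != start"):
            read_cpg_table(p, "s1", "UN")

    def test_identical_positions_align(self, tmp_path):
        content = "chr1\t100\t101\t30\t27\nchr1\t200\t201\t12\t0\n"
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        pa.write_text(content)
        pb.write_text(content)
        ta = read_cpg_table(pa, "a", "UN")
        tb = read_cpg_table(pb, "b", "RA")
        pd.testing.assert_frame_equal(ta.data, tb.data)

    def test_roundtrip_identity(self, tmp_path, rng):
        pos = np.sort(rng.choice(10_000, size=50, replace=False))
        cov = rng.integers(0, 40, size=50)
        meth = rng.binomial(cov, 0.7)
        t = make_table(list(zip(["chr1"] * 50, pos, cov, meth)))
        path = tmp_path / "rt.tsv"
        write_cpg_table(t, path)
        t2 = read_cpg_table(path, t.sample_id, t.condition)
        pd.testing.assert_frame_equal(t.data, t2.data)


class TestCpGTableInvariants:
    def test_sorted_and_unique(self):
        t = make_table([("chr2", 5, 10, 1), ("chr1", 9, 10, 2), ("chr1", 3, 10, 3)])
        assert list(t.data["pos"]) == [3, 9, 5]
        assert list(t.data["chrom"]) == ["chr1", "chr1", "chr2"]

    def test_duplicate_positions_rejected(self):
        with pytest.raises(CpGValidationError, match="duplicate"):
            make_table([("chr1", 5, 10, 1), ("chr1", 5, 12, 2)])

    def test_meth_gt_cov_rejected(self):
        with pytest.raises(CpGValidationError):
            make_table([("chr1", 5, 10, 11)])

    def test_rate_nan_at_zero_coverage(self):
        t = make_table([("chr1", 5, 0, 0)])
        assert np.isnan(t.rates.iloc[0])


class TestCombineReplicates:
    def test_additivity(self):
        t1 = make_table([("chr1", 10, 10, 5)])
        t2 = make_table([("chr1", 10, 20, 15)])
        c = combine_technical_replicates([t1, t2])
        assert c.data.iloc[0]["coverage"] == 30
        assert c.data.iloc[0]["meth_calls"] == 20

    def test_position_in_one_replicate_only(self):
        t1 = make_table([("chr1", 10, 10, 5)])
        t2 = make_table([("chr1", 99, 7, 7)])
        c = combine_technical_replicates([t1, t2])
        assert len(c) == 2
        row = c.data[c.data["pos"] == 99].iloc[0]
        assert (row["coverage"], row["meth_calls"]) == (7, 7)

    def test_three_empty_replicates(self):
        empties = [make_table([]) for _ in range(3)]
        assert len(combine_technical_replicates(empties)) == 0

    def test_mixed_sample_ids_rejected(self):
        t1 = make_table([("chr1", 10, 10, 5)], sample_id="a")
        t2 = make_table([("chr1", 10, 10, 5)], sample_id="b")
        with pytest.raises(ValueError, match="mixed sample_ids"):
            combine_technical_replicates([t1, t2])

    @settings(max_examples=25, deadline=None)
    @given(st.permutations([0, 1, 2]))
    def test_order_invariance(self, perm):
        reps = [
            make_table([("chr1", 10, 10, 5), ("chr1", 20, 8, 0)]),
            make_table([("chr1", 10, 3, 1)]),
            make_table([("chr2", 7, 9, 9)]),
        ]
        base = combine_technical_replicates(reps).data
        shuffled = combine_technical_replicates([reps[i] for i in perm]).data
        pd.testing.assert_frame_equal(base, shuffled)

    def test_associativity(self):
        reps = [
            make_table([("chr1", 10, 10, 5)]),
            make_table([("chr1", 10, 6, 2)]),
            make_table([("chr1", 10, 4, 4)]),
        ]
        left = combine_technical_replicates(
            [combine_technical_replicates(reps[:2]), reps[2]]
        ).data
        flat = combine_technical_replicates(reps).data
        pd.testing.assert_frame_equal(left, flat)


class TestFilterByCoverage:
    def test_kept_at_threshold(self):
        tabs = [
            make_table([("chr1", 5, c, 1)], sample_id=f"s{i}")
            for i, c in enumerate((10, 12, 11))
        ]
        out = filter_by_coverage(tabs, 10)
        assert all(len(t) == 1 for t in out)

    def test_dropped_when_one_sample_low(self):
        tabs = [
            make_table([("chr1", 5, c, 1)], sample_id=f"s{i}")
            for i, c in enumerate((9, 30, 30))
        ]
        out = filter_by_coverage(tabs, 10)
        assert all(len(t) == 0 for t in out)

    def test_min_cov_zero_forbidden(self):
        with pytest.raises(ValueError):
            filter_by_coverage([make_table([("chr1", 5, 10, 1)])], 0)

    def test_min_cov_one_identity_on_shared(self):
        t1 = make_table([("chr1", 5, 3, 1), ("chr1", 9, 2, 0)])
        t2 = make_table([("chr1", 5, 8, 4), ("chr1", 9, 1, 1)])
        out = filter_by_coverage([t1, t2], 1)
        assert list(out[0].data["pos"]) == [5, 9]

    def test_shared_position_index(self, rng):
        tabs = []
        for i in range(3):
            pos = np.sort(rng.choice(200, size=60, replace=False))
            cov = rng.integers(0, 25, size=60)
            tabs.append(
                make_table(
                    list(zip(["chr1"] * 60, pos, cov, np.zeros(60, int))),
                    sample_id=f"s{i}",
                )
            )
        out = filter_by_coverage(tabs, 10)
        ref = out[0].data[["chrom", "pos"]]
        for t in out[1:]:
            pd.testing.assert_frame_equal(t.data[["chrom", "pos"]], ref)

    def test_matches_bruteforce_recount(self, rng):
        for _ in range(30):
            tabs, dicts = [], []
            for i in range(rng.integers(1, 4)):
                n = int(rng.integers(1, 30))
                pos = np.sort(rng.choice(100, size=n, replace=False))
                cov = rng.integers(0, 20, size=n)
                recs = list(zip(["chr1"] * n, pos, cov, np.zeros(n, int)))
                tabs.append(make_table(recs, sample_id=f"s{i}"))
                dicts.append({("chr1", int(p)): (int(c), 0) for _, p, c, _ in recs})
            out = filter_by_coverage(tabs, 10)
            got = list(zip(out[0].data["chrom"], out[0].data["pos"]))
            assert got == recount_coverage_filter(dicts, 10)


class TestNonconversion:
    def test_arithmetic(self):
        t = make_table([("chrM", 10, 100, 1), ("chrM", 60, 100, 3), ("chr1", 5, 50, 50)])
        assert estimate_nonconversion(t) == pytest.approx(0.02)

    def test_zero_meth(self):
        t = make_table([("chrM", 10, 100, 0)])
        assert estimate_nonconversion(t) == 0.0

    def test_missing_contig(self):
        t = make_table([("chr1", 10, 100, 1)])
        with pytest.raises(ValueError, match="no control data"):
            estimate_nonconversion(t)


class TestFeatureSet:
    def test_merged_collapses_overlaps(self):
        fs = FeatureSet(
            "f",
            pd.DataFrame(
                [("chr1", 0, 10), ("chr1", 5, 20), ("chr1", 30, 40)],
                columns=["chrom", "start", "end"],
            ),
        )
        m = fs.merged()
        assert m.values.tolist() == [["chr1", 0, 20], ["chr1", 30, 40]]
        assert fs.covered_bp() == 30

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            FeatureSet("f", pd.DataFrame([("chr1", 10, 10)], columns=["chrom", "start", "end"]))
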