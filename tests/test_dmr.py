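import numpy as np
import pandas as pd
import pytest

from conftest import make_counts
from oracles import fisher_two_sided_exact

from methdiff.dmr import (
    build_windows,
    call_dmrs,
    filter_dmrs,
    merge_windows,
    retest_regions,
)
from methdiff.dmr import test_windows as run_window_test


def _null_counts(positions, cov=30, meth=15, chrom="chr1"):
    return make_counts([(chrom, p, cov, meth) for p in positions])


class TestBuildWindows:
    def test_five_cpgs_three_windows(self):
        pos = [0, 100, 200, 300, 400]
        w = build_windows(_null_counts(pos), _null_counts(pos))
        assert len(w) == 3
        assert list(w["idx"]) == [0, 1, 2]

    def test_wide_triple_skipped(self):
        pos = [0, 1200, 2500]
        w = build_windows(_null_counts(pos), _null_counts(pos))
        assert len(w) == 0

    def test_two_cpgs_no_window(self):
        pos = [0, 100]
        w = build_windows(_null_counts(pos), _null_counts(pos))
        assert len(w) == 0

    def test_span_uses_end_exclusive(self):
        # span = last pos + 1 - first pos; exactly 2000 passes, 2001 fails
        ok = [0, 100, 1999]
        w = build_windows(_null_counts(ok), _null_counts(ok))
        assert len(w) == 1
        too_wide = [0, 100, 2000]
        w = build_windows(_null_counts(too_wide), _null_counts(too_wide))
        assert len(w) == 0

    def test_mean_counts_stored(self):
        a = make_counts([("chr1", 0, 30, 27), ("chr1", 50, 32, 27), ("chr1", 90, 28, 24)])
        b = make_counts([("chr1", 0, 30, 3), ("chr1", 50, 30, 3), ("chr1", 90, 30, 3)])
        w = build_windows(a, b)
        assert w["mean_cov_a"].iloc[0] == pytest.approx(30.0)
        assert w["mean_meth_a"].iloc[0] == pytest.approx(26.0)
        assert w["mean_meth_b"].iloc[0] == pytest.approx(3.0)

    def test_windows_do_not_span_chromosomes(self):
        a = make_counts(
            [("chr1", 0, 30, 15), ("chr1", 50, 30, 15), ("chr2", 10, 30, 15),
             ("chr2", 60, 30, 15), ("chr2", 110, 30, 15)]
        )
        w = build_windows(a, a)
        assert set(w["chrom"]) == {"chr2"}


class TestTestWindows:
    def test_strong_window_significant(self, block_counts):
        a, b = block_counts
        w = build_windows(a, b)
        sig = run_window_test(w)
        assert len(sig) == len(w)
        # rounded table [[27,3],[3,27]] checked against the exact oracle
        assert sig["p_value"].iloc[0] == pytest.approx(
            fisher_two_sided_exact(27, 3, 3, 27), abs=1e-9
        )
        assert fisher_two_sided_exact(27, 3, 3, 27) < 0.05
        assert (sig["direction"] == "hypo").all()

    def test_identical_windows_not_significant(self):
        pos = [0, 100, 200]
        sig = run_window_test(build_windows(_null_counts(pos), _null_counts(pos)))
        assert len(sig) == 0

    def test_alpha_one_keeps_all(self):
        pos = [0, 100, 200, 300]
        w = build_windows(_null_counts(pos), _null_counts(pos))
        assert len(run_window_test(w, alpha=1.0)) == len(w)


class TestMergeWindows:
    def _sig(self, rows):
        cols = ["chrom", "idx", "start", "end", "direction", "window_cpgs"]
        df = pd.DataFrame(rows, columns=cols)
        df["p_value"] = 0.01
        return df

    def test_consecutive_merge(self):
        sig = self._sig(
            [("chr1", 0, 0, 201, "hyper", 3), ("chr1", 1, 100, 301, "hyper", 3),
             ("chr1", 2, 200, 401, "hyper", 3)]
        )
        reg = merge_windows(sig)
        assert len(reg) == 1
        r = reg.iloc[0]
        assert (r["first_idx"], r["last_idx"], r["n_windows"]) == (0, 4, 3)
        assert (r["start"], r["end"]) == (0, 401)

    def test_gap_breaks_region(self):
        sig = self._sig(
            [("chr1", 0, 0, 201, "hyper", 3), ("chr1", 2, 200, 401, "hyper", 3)]
        )
        assert len(merge_windows(sig)) == 2

    def test_direction_change_breaks_region(self):
        sig = self._sig(
            [("chr1", 0, 0, 201, "hyper", 3), ("chr1", 1, 100, 301, "hypo", 3)]
        )
        reg = merge_windows(sig)
        assert len(reg) == 2
        assert set(reg["direction"]) == {"hyper", "hypo"}

    def test_chromosomes_kept_apart(self):
        sig = self._sig(
            [("chr1", 0, 0, 201, "hyper", 3), ("chr2", 1, 100, 301, "hyper", 3)]
        )
        assert len(merge_windows(sig)) == 2


class TestRetestRegions:
    def test_strong_region_kept(self, block_counts):
        a, b = block_counts
        reg = merge_windows(run_window_test(build_windows(a, b)))
        out = retest_regions(reg, a, b)
        assert len(out) == 1
        # summed counts: 5+ CpGs at (30,27) vs (30,3) -> enumerated oracle
        n = out.iloc[0]["n_cpgs"]
        expected = fisher_two_sided_exact(27 * n, 3 * n, 3 * n, 27 * n)
        assert out.iloc[0]["p_value"] == pytest.approx(expected, rel=1e-6)
        assert out.iloc[0]["p_value"] < 1e-10

    def test_equal_rates_dropped(self):
        pos = [0, 100, 200, 300, 400]
        a = _null_counts(pos)
        reg = pd.DataFrame(
            [("chr1", 0, 4, 0, 401, 3, "hyper")],
            columns=["chrom", "first_idx", "last_idx", "start", "end",
                     "n_windows", "direction"],
        )
        assert len(retest_regions(reg, a, a)) == 0

    def test_alpha_one_keeps_with_p_recorded(self):
        pos = [0, 100, 200, 300, 400]
        a = _null_counts(pos)
        reg = pd.DataFrame(
            [("chr1", 0, 4, 0, 401, 3, "hyper")],
            columns=["chrom", "first_idx", "last_idx", "start", "end",
                     "n_windows", "direction"],
        )
        out = retest_regions(reg, a, a, alpha=1.0)
        assert len(out) == 1
        assert out.iloc[0]["p_value"] == pytest.approx(1.0)


class TestFilterDmrs:
    def _region(self, start, end, n_cpgs, n_windows):
        return pd.DataFrame(
            [("chr1", 0, n_cpgs - 1, start, end, n_windows, "hyper", 1e-6, 0.5, n_cpgs)],
            columns=["chrom", "first_idx", "last_idx", "start", "end", "n_windows",
                     "direction", "p_value", "mean_delta", "n_cpgs"],
        )

    def test_dense_region_kept(self):
        out = filter_dmrs(self._region(0, 601, 7, 5))
        assert len(out) == 1
        assert out.iloc[0]["density"] == pytest.approx(7 / 0.601)

    def test_sparse_region_dropped(self):
        # 5 CpGs over 1900 bp -> 2.63 CpGs/kb < 3
        assert len(filter_dmrs(self._region(0, 1900, 5, 3))) == 0

    def test_too_few_windows_dropped(self):
        assert len(filter_dmrs(self._region(0, 500, 5, 2))) == 0


class TestCallDmrs:
    def test_null_input_no_dmrs(self, rng):
        pos = np.sort(rng.choice(50_000, size=300, replace=False))
        cov = rng.integers(20, 40, size=300)
        a = make_counts(list(zip(["chr1"] * 300, pos, cov, rng.binomial(cov, 0.8))))
        b = make_counts(list(zip(["chr1"] * 300, pos, cov.copy(), a["meth_calls"])))
        assert len(call_dmrs(a, b)) == 0

    def test_single_planted_block(self, block_counts):
        a, b = block_counts
        dmrs = call_dmrs(a, b)
        assert len(dmrs) == 1
        d = dmrs.iloc[0]
        assert d["n_cpgs"] == 7
        assert d["n_windows"] == 5
        assert d["direction"] == "hypo"
        assert d["start"] == 0 and d["end"] == 601

    def test_two_blocks_separated(self):
        pos1 = list(range(0, 700, 100))
        pos2 = list(range(5000, 5700, 100))
        a = make_counts([("chr1", p, 30, 27) for p in pos1 + pos2])
        b = make_counts([("chr1", p, 30, 3) for p in pos1 + pos2])
        dmrs = call_dmrs(a, b)
        assert len(dmrs) == 2

    def test_chromosome_order_invariance(self, block_counts):
        a, b = block_counts
        a2 = a.copy()
        a2["chrom"] = "chr9"
        b2 = b.copy()
        b2["chrom"] = "chr9"
        both_a = pd.concat([a2, a], ignore_index=True)
        both_b = pd.concat([b2, b], ignore_index=True)
        both_a = both_a.sort_values(["chrom", "pos"]).reset_index(drop=True)
        both_b = both_b.sort_values(["chrom", "pos"]).reset_index(drop=True)
        dmrs = call_dmrs(both_a, both_b)
        assert set(dmrs["chrom"]) == {"chr1", "chr9"}
        per_chrom = dmrs.groupby("chrom")[["start", "end", "p_value"]].first()
        assert per_chrom.loc["chr1"].equals(per_chrom.loc["chr9"])

    def test_alpha_monotonicity(self, rng):
        pos = np.sort(rng.choice(30_000, size=400, replace=False))
        cov = rng.integers(15, 45, size=400)
        rates = np.full(400, 0.5)
        rates[100:120] = 0.75  # weak block
        a = make_counts(list(zip(["chr1"] * 400, pos, cov, rng.binomial(cov, 0.5))))
        b = make_counts(list(zip(["chr1"] * 400, pos, cov, rng.binomial(cov, rates))))
        counts = [len(call_dmrs(a, b, alpha=al)) for al in (0.05, 0.01, 0.001)]
        assert counts == sorted(counts, reverse=True)

    def test_emitted_dmrs_satisfy_invariants(self, rng):
        pos = np.sort(rng.choice(100_000, size=600, replace=False))
        cov = rng.integers(12, 50, size=600)
        rates_a = rng.uniform(0.1, 0.9, size=600)
        rates_b = rates_a.copy()
        rates_b[200:215] = np.clip(rates_a[200:215] + 0.4, 0, 1)
        a = make_counts(list(zip(["chr1"] * 600, pos, cov, rng.binomial(cov, rates_a))))
        b = make_counts(list(zip(["chr1"] * 600, pos, cov, rng.binomial(cov, rates_b))))
        dmrs = call_dmrs(a, b)
        assert len(dmrs) >= 1
        assert (dmrs["n_cpgs"] >= 5).all()
        assert (dmrs["n_windows"] >= 3).all()
        assert (dmrs["density"] >= 3).all()
        assert (dmrs["p_value"] <= 0.05).all()
        assert dmrs["direction"].isin(["hyper", "hypo"]).all()
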