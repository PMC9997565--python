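from itertools import product

import numpy as np
import pytest
from scipy import stats

from sexlinkscan.core_io import DepthMatrix, GenomeIndex, Specimen, Window, make_windows
from sexlinkscan.covscan import (
    chromosome_enrichment,
    detect_outlier_windows,
    hodges_lehmann_ci,
    normalize_depth,
    signed_rank_exact_p,
    wilcoxon_signed_rank_p,
    window_coverage_stats,
)
from sexlinkscan.covscan import test_windows as run_window_tests

PANEL = [Specimen(f"m{i}", "male") for i in range(3)] + [
    Specimen(f"f{i}", "female") for i in range(3)
]


def _matrix(male, female):
    """Depth matrix from per-sex per-site depth vectors (same value per individual)."""
    male, female = np.asarray(male), np.asarray(female)
    arr = np.column_stack([male] * 3 + [female] * 3)
    return DepthMatrix({"c": arr}, PANEL)


class TestNormalization:
    def test_constant_depth_normalizes_to_one(self):
        tr = normalize_depth(_matrix([10] * 100, [10] * 100))
        assert np.allclose(tr.norm_m["c"], 1.0) and np.allclose(tr.norm_f["c"], 1.0)
        assert np.allclose(tr.log2("male", "c"), 0.0)

    def test_per_sex_normalization_cancels_global_difference(self):
        tr = normalize_depth(_matrix([10] * 100, [20] * 100))
        assert np.allclose(tr.norm_m["c"], 1.0) and np.allclose(tr.norm_f["c"], 1.0)

    def test_half_coverage_window_norm(self):
        male = [10] * 900 + [5] * 100
        tr = normalize_depth(_matrix(male, [10] * 1000))
        assert np.allclose(tr.norm_m["c"][900:], 0.5)
        assert np.allclose(tr.log2("male", "c")[900:], -1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(20, size=(500, 6))
        d1 = DepthMatrix({"c": base}, PANEL)
        scaled = base.copy()
        scaled[:, :3] *= 3  # male columns
        d2 = DepthMatrix({"c": scaled}, PANEL)
        t1, t2 = normalize_depth(d1), normalize_depth(d2)
        assert np.allclose(t1.norm_m["c"], t2.norm_m["c"])
        assert np.allclose(t1.norm_f["c"], t2.norm_f["c"])

    def test_all_zero_sex_rejected(self):
        with pytest.raises(ValueError):
            normalize_depth(_matrix([0] * 100, [10] * 100))


class TestWindowStats:
    def test_equal_norms_give_unit_ratio_zero_diff(self):
        tr = normalize_depth(_matrix([10] * 100, [10] * 100))
        ws = window_coverage_stats(tr, [Window("c", 0, 100)])
        assert ws.ratio[0] == pytest.approx(1.0) and ws["diff"][0] == 0.0

    def test_half_norm_window(self):
        male = [10] * 900 + [5] * 100
        tr = normalize_depth(_matrix(male, [10] * 1000))
        ws = window_coverage_stats(tr, [Window("c", 900, 1000)], epsilon=0.0)
        assert ws.ratio[0] == pytest.approx(0.5)
        assert ws["diff"][0] == pytest.approx(-0.5)

    def test_matches_brute_force_median(self):
        rng = np.random.default_rng(2)
        d = DepthMatrix({"c": rng.poisson(15, size=(200, 6))}, PANEL)
        tr = normalize_depth(d)
        eps = 0.01
        ws = window_coverage_stats(tr, [Window("c", 50, 150)], epsilon=eps)
        nm, nf = tr.norm_m["c"][50:150], tr.norm_f["c"][50:150]
        vals = [(m + eps) / (f + eps) for m, f in zip(nm, nf) if not (m == 0 and f == 0)]
        assert ws.ratio[0] == pytest.approx(np.median(vals))
        assert ws["diff"][0] == pytest.approx(np.median(nm - nf))

    def test_empty_window_gets_nan_and_is_never_flagged(self):
        male = [0] * 50 + [10] * 950
        female = [0] * 50 + [10] * 950
        tr = normalize_depth(_matrix(male, female))
        windows = [Window("c", 0, 50), Window("c", 50, 1000)]
        ws = detect_outlier_windows(window_coverage_stats(tr, windows))
        assert np.isnan(ws.ratio[0]) and not ws.outlier[0]


class TestOutlierDetection:
    def _frame(self, ratios, diffs):
        import pandas as pd

        df = pd.DataFrame({
            "chromosome": "c", "start": 0, "end": 1, "n_sites": 1,
            "ratio": ratios, "diff": diffs,
        })
        df["outlier"] = False
        return df

    def test_constant_distribution_has_no_outliers(self):
        ws = detect_outlier_windows(self._frame([1.0] * 500, [0.0] * 500))
        assert not ws.outlier.any()

    def test_planted_half_coverage_windows_flagged(self):
        rng = np.random.default_rng(3)
        ratios = list(1 + rng.normal(0, 0.005, 1000)) + [0.5] * 10
        diffs = list(rng.normal(0, 0.005, 1000)) + [-0.5] * 10
        ws = detect_outlier_windows(self._frame(ratios, diffs))
        assert ws.outlier[1000:].all()
        assert ws.outlier[:1000].sum() == 0

    def test_extreme_ratio_with_small_diff_not_flagged(self):
        ratios = [1.0] * 999 + [0.2]
        diffs = [0.0] * 999 + [-0.1]
        ws = detect_outlier_windows(self._frame(ratios, diffs))
        assert not ws.outlier.iloc[-1]


def _brute_force_p(d):
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array([np.where(s, ranks, 0).sum() for s in product([0, 1], repeat=len(d))])
    return min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))


class TestWilcoxonSignedRank:
    def test_five_equal_negative_pairs(self):
        assert signed_rank_exact_p(np.array([-1.0] * 5)) == pytest.approx(0.0625)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_equals_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        d = rng.normal(0.4, 1, n)
        # include ties half the time
        if seed % 2:
            d = np.round(d, 0) + 0.5
        d = d[d != 0]
        assert signed_rank_exact_p(d) == pytest.approx(_brute_force_p(d))

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(7)
        d = rng.normal(0.3, 1, 14)
        assert wilcoxon_signed_rank_p(d) == pytest.approx(
            stats.wilcoxon(d, method="exact").pvalue)

    def test_large_n_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(8)
        d = rng.normal(0.1, 1, 200)
        p = wilcoxon_signed_rank_p(d)
        ref = stats.wilcoxon(d, method="approx", correction=False).pvalue
        assert p == pytest.approx(ref, rel=1e-6)


class TestHodgesLehmann:
    # reference values from R wilcox.test(conf.int=TRUE) on the same data
    def test_exact_branch_matches_r(self):
        d = np.array([0.8047, -0.54, 1.2505, 1.4406, -1.451, -0.8022, 0.6278,
                      0.1838, 0.4832, -0.353, 1.3794, 1.2778, 0.566, 1.6272, 0.9675])
        est, lo, hi = hodges_lehmann_ci(d)
        assert est == pytest.approx(0.54965, abs=1e-6)
        assert lo == pytest.approx(-0.02840, abs=1e-6)
        assert hi == pytest.approx(1.05520, abs=1e-6)

    def test_large_n_branch_matches_r(self):
        rng = np.random.default_rng(42)
        rng.normal(0.5, 1, 15)  # advance stream to match the frozen data draw
        d = rng.normal(0.2, 1, 60).round(4)
        est, lo, hi = hodges_lehmann_ci(d)
        assert est == pytest.approx(0.21687842, abs=1e-3)
        assert lo == pytest.approx(0.02313119, abs=1e-3)
        assert hi == pytest.approx(0.42157793, abs=1e-3)


class TestTestWindows:
    def test_zero_difference_window_not_tested(self):
        tr = normalize_depth(_matrix([10] * 100, [10] * 100))
        ws = window_coverage_stats(tr, [Window("c", 0, 100)])
        ws["outlier"] = True
        out = run_window_tests(ws, tr)
        assert np.isnan(out.p_value[0]) and not out.significant[0]

    def test_flagged_window_with_shift_is_significant(self):
        male = [10] * 900 + [5] * 100
        tr = normalize_depth(_matrix(male, [10] * 1000))
        windows = [Window("c", 0, 900), Window("c", 900, 1000)]
        ws = window_coverage_stats(tr, windows)
        ws.loc[1, "outlier"] = True
        out = run_window_tests(ws, tr)
        assert out.significant[1] and out.p_value[1] < 1e-6
        assert out.ci_high[1] < 0  # CI excludes zero shift
        assert np.isnan(out.p_value[0])  # unflagged windows never tested


class TestChromosomeEnrichment:
    def _ws(self, sig_by_chrom, per_chrom):
        import pandas as pd

        rows = []
        for chrom, n_sig in sig_by_chrom.items():
            for i in range(per_chrom):
                rows.append({"chromosome": chrom, "start": i, "end": i + 1,
                             "significant": i < n_sig})
        return pd.DataFrame(rows)

    def test_no_significant_windows_gives_unit_p(self):
        g = GenomeIndex([("c1", 1_000_000), ("c2", 1_000_000)])
        out = chromosome_enrichment(self._ws({"c1": 0, "c2": 0}, 50), g)
        assert (out.p_raw == 1.0).all()

    def test_fisher_example_3113(self):
        # [[3,1],[1,3]] one-sided: p = 17/70
        g = GenomeIndex([("c1", 1_000_000), ("c2", 1_000_000)])
        out = chromosome_enrichment(self._ws({"c1": 3, "c2": 1}, 4), g)
        assert out[out.chromosome == "c1"].p_raw.iloc[0] == pytest.approx(17 / 70)

    def test_concentrated_signal_attains_hypergeometric_minimum(self):
        chroms = {f"c{i}": (10 if i == 0 else 0) for i in range(20)}
        g = GenomeIndex([(c, 1_000_000) for c in chroms])
        out = chromosome_enrichment(self._ws(chroms, 10), g)
        # brute-force hypergeometric sum for the focal chromosome
        p_expected = stats.hypergeom.sf(9, 200, 10, 10)  # P(X >= 10)
        row = out[out.chromosome == "c0"]
        assert row.p_raw.iloc[0] == pytest.approx(p_expected)
        assert row.p_bonferroni.iloc[0] == out.p_bonferroni.min()
        assert row.sig_per_mb.iloc[0] == pytest.approx(10.0)
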