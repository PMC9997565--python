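import numpy as np
import pytest

from sexlinkscan.core_io import Specimen
from sexlinkscan.kmersex import (
    KmerCalls,
    KmerCatalog,
    build_kmer_catalog,
    categorize_kmers,
    heterogamety_test,
    kmer_intersections,
    regression_outliers,
)
from sexlinkscan.ssrcall import reverse_complement

PANEL = [Specimen(f"m{i}", "male") for i in range(3)] + [
    Specimen(f"f{i}", "female") for i in range(3)
]


def brute_force_scan(seq, k=37, prefix="AG"):
    """All prefix-anchored k-mers of a sequence and its reverse complement."""
    out = {}
    for s in (seq, reverse_complement(seq)):
        for i in range(len(s) - k + 1):
            w = s[i:i + k]
            if w.startswith(prefix) and "N" not in w:
                out[w] = out.get(w, 0) + 1
    return out


class TestCatalogConstruction:
    READ = "AG" + ("ACGTTGCA" * 5)[:35]  # one 37-mer window

    def test_shared_read_in_five_specimens(self):
        reads = {s.id: [self.READ] for s in PANEL[:5]}
        cat = build_kmer_catalog(reads, PANEL, min_specimens=5)
        expected = brute_force_scan(self.READ)
        assert set(cat.kmers) == set(expected)
        assert (cat.n_specimens_present == 5).all()

    def test_four_specimens_insufficient(self):
        reads = {s.id: [self.READ] for s in PANEL[:4]}
        cat = build_kmer_catalog(reads, PANEL, min_specimens=5)
        assert cat.n_kmers == 0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_on_random_sequence(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        reads = {s.id: [seq] for s in PANEL}
        cat = build_kmer_catalog(reads, PANEL, min_specimens=5)
        expected = brute_force_scan(seq)
        assert dict(zip(cat.kmers, cat.counts[:, 0])) == expected

    def test_strand_closure(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=1500))
        fwd = build_kmer_catalog({s.id: [seq] for s in PANEL}, PANEL)
        rev = build_kmer_catalog(
            {s.id: [reverse_complement(seq)] for s in PANEL}, PANEL)
        assert dict(zip(fwd.kmers, map(tuple, fwd.counts))) == \
            dict(zip(rev.kmers, map(tuple, rev.counts)))

    def test_n_containing_windows_skipped(self):
        seq = "AG" + "N" + "A" * 40
        cat = build_kmer_catalog({s.id: [seq] for s in PANEL}, PANEL)
        assert all("N" not in k for k in cat.kmers)

    def test_invalid_parameters_rejected(self):
        reads = {s.id: ["ACGT" * 20] for s in PANEL}
        with pytest.raises(ValueError):
            build_kmer_catalog(reads, PANEL, k=2)
        with pytest.raises(ValueError):
            build_kmer_catalog(reads, PANEL, k=3, prefix="ACGT")


def _catalog(sum_m, sum_f):
    """Catalog whose per-sex sums are as given (one male and one female carry all)."""
    n = len(sum_m)
    counts = np.zeros((n, 6), dtype=np.int64)
    counts[:, 0] = sum_m
    counts[:, 3] = sum_f
    kmers = [f"AG{'A' * 33}{'ACGT'[i % 4]}{'ACGT'[(i // 4) % 4]}" for i in range(n)]
    return KmerCatalog(37, "AG", kmers, counts, PANEL)


class TestRegressionOutliers:
    def test_far_point_is_sole_outlier(self):
        rng = np.random.default_rng(0)
        x = np.arange(10, 30)
        y = 2 * x + rng.normal(0, 0.3, len(x))
        cat = _catalog(np.append(x, 20), np.append(y, 200.0).astype(int))
        calls = regression_outliers(cat)
        assert calls.outlier[-1]
        assert not calls.outlier[:-1].any()

    def test_collinear_points_have_no_outliers(self):
        x = np.arange(10, 25)
        cat = _catalog(x, 3 * x)
        calls = regression_outliers(cat)
        assert not calls.outlier.any()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_studentized_residual_equals_leave_one_out_refit(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(10, 100, 25)
        y = 1.5 * x + rng.normal(0, 5, 25)
        cat = _catalog(x.astype(int), y.astype(int))
        calls = regression_outliers(cat)
        xi = cat.sum_m.astype(float)
        yi = cat.sum_f.astype(float)
        for i in range(len(xi)):
            keep = np.ones(len(xi), bool)
            keep[i] = False
            X = np.column_stack([np.ones(keep.sum()), xi[keep]])
            beta, *_ = np.linalg.lstsq(X, yi[keep], rcond=None)
            resid = yi[keep] - X @ beta
            s2 = (resid**2).sum() / (keep.sum() - 2)
            pred = beta[0] + beta[1] * xi[i]
            xbar = xi[keep].mean()
            sxx = ((xi[keep] - xbar) ** 2).sum()
            se = np.sqrt(s2 * (1 + 1 / keep.sum() + (xi[i] - xbar) ** 2 / sxx))
            expected = (yi[i] - pred) / se
            assert calls.studentized_residual[i] == pytest.approx(expected, rel=1e-8)

    def test_zero_male_variance_rejected(self):
        cat = _catalog(np.full(12, 5), np.arange(12))
        with pytest.raises(ValueError):
            regression_outliers(cat)


class TestCategorization:
    def _calls(self, sum_m, sum_f, outlier=None):
        cat = _catalog(np.asarray(sum_m), np.asarray(sum_f))
        n = cat.n_kmers
        out = np.ones(n, bool) if outlier is None else np.asarray(outlier)
        return KmerCalls(cat, np.zeros(n), out)

    def test_definitions(self):
        calls = categorize_kmers(self._calls([40, 0, 2, 9, 10], [0, 40, 9, 2, 10]))
        assert calls.category.tolist() == ["Y", "W", "X", "Z", "none"]

    def test_x_ratio_threshold_strict(self):
        # ratio 4.5 > 4 -> X; ratio exactly 4 -> none
        calls = categorize_kmers(self._calls([2, 2], [9, 8]))
        assert calls.category.tolist() == ["X", "none"]

    def test_stricter_z_threshold(self):
        calls = categorize_kmers(self._calls([9], [2]), z_ratio_threshold=12.0)
        assert calls.category.tolist() == ["none"]

    def test_non_outliers_stay_none(self):
        calls = categorize_kmers(self._calls([40, 40], [0, 0], outlier=[True, False]))
        assert calls.category.tolist() == ["Y", "none"]

    def test_category_partition(self):
        rng = np.random.default_rng(1)
        calls = categorize_kmers(self._calls(
            rng.integers(0, 50, 100), rng.integers(0, 50, 100)))
        assert set(calls.category) <= {"Y", "W", "X", "Z", "none"}
        # Y/W exclusivity with zero-count definitions
        for cat_name, m, f in zip(calls.category, calls.catalog.sum_m, calls.catalog.sum_f):
            if cat_name == "Y":
                assert f == 0 and m > 0
            if cat_name == "W":
                assert m == 0 and f > 0


class TestHeterogametyTest:
    def _calls(self, cov_y, cov_w):
        n = len(cov_y) + len(cov_w)
        cat = _catalog(
            np.concatenate([cov_y, np.zeros(len(cov_w))]).astype(int),
            np.concatenate([np.zeros(len(cov_y)), cov_w]).astype(int),
        )
        calls = KmerCalls(cat, np.zeros(n), np.ones(n, bool))
        calls.category = np.array(["Y"] * len(cov_y) + ["W"] * len(cov_w), dtype=object)
        return calls

    def test_exact_rank_sum_example(self):
        out = heterogamety_test(self._calls([10, 11, 12], [1, 2]))
        assert out["p_value"] == pytest.approx(0.2)
        assert out["verdict"] == "undetermined"

    def test_no_sex_specific_kmers_rejected(self):
        calls = KmerCalls(_catalog(np.arange(12), np.arange(12)),
                          np.zeros(12), np.zeros(12, bool))
        with pytest.raises(ValueError):
            heterogamety_test(calls)

    def test_one_sided_verdict_needs_twenty(self):
        assert heterogamety_test(self._calls(np.full(25, 30), []))["verdict"] == "XY"
        assert heterogamety_test(self._calls(np.full(5, 30), []))["verdict"] == "undetermined"
        assert heterogamety_test(self._calls([], np.full(25, 30)))["verdict"] == "ZW"

    def test_dominant_y_coverage_gives_xy(self):
        rng = np.random.default_rng(2)
        out = heterogamety_test(self._calls(
            rng.poisson(40, 30) + 1, rng.poisson(5, 25) + 1))
        assert out["verdict"] == "XY" and out["p_value"] < 0.05


class TestIntersections:
    def _calls_with_sets(self, y_kmers):
        n = max(len(y_kmers), 10) + 2
        cat = KmerCatalog(37, "AG", [f"AG{i:035d}" for i in range(n)],
                          np.ones((n, 6), dtype=np.int64), PANEL)
        calls = KmerCalls(cat, np.zeros(n), np.ones(n, bool))
        cats = np.full(n, "none", dtype=object)
        for km in y_kmers:
            cats[cat.kmers.index(km)] = "Y"
        calls.category = cats
        return calls

    def test_disjoint_and_identical_sets(self):
        a = self._calls_with_sets([f"AG{i:035d}" for i in range(7)])
        b = self._calls_with_sets([f"AG{i:035d}" for i in range(7)])
        c = self._calls_with_sets([f"AG{i:035d}" for i in range(7, 10)])
        out = kmer_intersections({"p1": a, "p2": b})
        assert out["pairwise"]["Y"][("p1", "p2")] == 7
        out2 = kmer_intersections({"p1": a, "p3": c})
        assert out2["pairwise"]["Y"][("p1", "p3")] == 0

    def test_exclusive_intersections_match_set_algebra(self):
        k = [f"AG{i:035d}" for i in range(10)]
        sets = {"p1": set(k[:6]), "p2": set(k[3:8]), "p3": set(k[5:10])}
        calls = {p: self._calls_with_sets(sorted(s)) for p, s in sets.items()}
        out = kmer_intersections(calls)
        for combo, size in out["exclusive"]["Y"].items():
            expected = set.intersection(*(sets[p] for p in combo))
            for other in sets:
                if other not in combo:
                    expected -= sets[other]
            assert size == len(expected)
        # union of exclusive cells covers every k-mer exactly once
        assert sum(out["exclusive"]["Y"].values()) == len(set().union(*sets.values()))

    def test_single_population_rejected(self):
        with pytest.raises(ValueError):
            kmer_intersections({"p1": self._calls_with_sets([])})


def test_planted_insertion_drives_xy_verdict(y_insertion_sim):
    cat = build_kmer_catalog(y_insertion_sim.reads, y_insertion_sim.specimens)
    calls = categorize_kmers(regression_outliers(cat))
    out = heterogamety_test(calls)
    assert out["verdict"] == "XY"
    ins = y_insertion_sim.truth.insertions[0]["sequence"]
    truth_kmers = set(brute_force_scan(ins))
    y_set = calls.kmers_in_category("Y")
    # called Y-mers overwhelmingly originate from the planted insertion
    assert len(y_set & truth_kmers) / len(y_set) > 0.95
    assert len(y_set & truth_kmers) / len(truth_kmers) > 0.5
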