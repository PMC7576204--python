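"""Layer scores, screening, correlation and distribution differences,
cross-checked against independent brute-force oracles."""

import bisect

import numpy as np
import pytest

from deephl import analysis
from deephl.analysis import (MaskRule, dist_diff, highlight_mask, intersect,
                             make_histogram, rank_layers, score_fc, score_it,
                             trajectory_score)
from deephl.errors import ValidationError
from deephl.features import FeatureSeriesSet

# -- brute-force oracles (pure python loops, independent of the implementation)


def oracle_var(a):
    m = sum(a) / len(a)
    return sum((v - m) ** 2 for v in a) / len(a)


def oracle_hist(values, lo, hi, bins=200):
    if hi <= lo:
        lo, hi = lo - 0.5, lo + 0.5
    edges = list(np.linspace(lo, hi, bins + 1))
    counts = [0] * bins
    for v in values:
        idx = bisect.bisect_right(edges, v) - 1
        if idx == bins:  # right edge closed
            idx = bins - 1
        counts[idx] += 1
    total = sum(counts)
    return [c / total for c in counts]


def oracle_intersect(f1, f2):
    return sum(min(a, b) for a, b in zip(f1, f2))


def oracle_sfc(A_A, A_B):
    pool = list(A_A) + list(A_B)
    mean_len = sum(len(a) for a in pool) / len(pool)
    return (sum(oracle_var(a) for a in pool) / (len(pool) * mean_len)) ** 0.5


def oracle_sit(A_A, A_B):
    pa = [v for a in A_A for v in a]
    pb = [v for a in A_B for v in a]
    lo, hi = min(pa + pb), max(pa + pb)
    return 1.0 - oracle_intersect(oracle_hist(pa, lo, hi), oracle_hist(pb, lo, hi))


def oracle_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sx = (sum((v - mx) ** 2 for v in x) / n) ** 0.5
    sy = (sum((v - my) ** 2 for v in y) / n) ** 0.5
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    return cov / (sx * sy)


def oracle_dist_diff(A_A, F_A, A_B, F_B, c=1.2):
    def extract(atts, feats):
        out = []
        for a, f in zip(atts, feats):
            thr = c / len(a)
            out.extend(fv for av, fv in zip(a, f) if av > thr)
        return out
    va, vb = extract(A_A, F_A), extract(A_B, F_B)
    if not va or not vb:
        return float("nan")
    lo, hi = min(va + vb), max(va + vb)
    return 1.0 - oracle_intersect(oracle_hist(va, lo, hi), oracle_hist(vb, lo, hi))


def random_attention_sets(rng, n_max=10, len_max=50):
    def one_set():
        out = []
        for _ in range(rng.integers(1, n_max + 1)):
            n = int(rng.integers(4, len_max + 1))
            a = rng.random(n) ** 3 + 1e-6
            out.append(a / a.sum())
        return out
    return one_set(), one_set()


# -- closed-form spot checks


class TestClosedForm:
    def test_identical_histograms_intersect_fully(self, rng):
        h = make_histogram(rng.random(100), (0, 1))
        assert intersect(h, h) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_supports_intersect_zero(self):
        h1 = make_histogram(np.linspace(0.0, 0.4, 50), (0, 1))
        h2 = make_histogram(np.linspace(0.6, 1.0, 50), (0, 1))
        assert intersect(h1, h2) == 0.0

    def test_two_bin_example(self):
        h1 = analysis.Histogram(np.array([0.5, 0.5]), np.array([0.0, 0.5, 1.0]))
        h2 = analysis.Histogram(np.array([0.25, 0.75]), np.array([0.0, 0.5, 1.0]))
        assert intersect(h1, h2) == pytest.approx(0.75, abs=1e-12)

    def test_mismatched_bins_rejected(self):
        h1 = analysis.Histogram(np.array([1.0]), np.array([0.0, 1.0]))
        h2 = analysis.Histogram(np.array([1.0]), np.array([0.0, 2.0]))
        with pytest.raises(ValidationError):
            intersect(h1, h2)

    def test_uniform_attention_scores_zero(self):
        u = [np.full(10, 0.1)]
        assert trajectory_score(u[0]) == 0.0
        assert score_fc(u, [np.full(8, 0.125)]) == 0.0

    def test_one_hot_length4_variance(self):
        a = np.array([1.0, 0.0, 0.0, 0.0])
        assert trajectory_score(a) == pytest.approx(3 / 16, abs=1e-12)
        assert score_fc([a], []) == pytest.approx(np.sqrt((3 / 16) / 4), abs=1e-12)

    def test_identical_class_distributions_give_zero(self, rng):
        a = rng.random(30)
        a /= a.sum()
        assert score_it([a], [a.copy()]) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_attention_ranges_give_one(self):
        lo = [np.full(10, 0.1) + np.linspace(0, 1e-3, 10)]
        hi = [np.concatenate([np.full(5, 0.19), np.full(5, 0.01)])]
        assert score_it(lo, hi) == pytest.approx(1.0, abs=1e-3)

    def test_uniform_attention_yields_no_attended_steps(self):
        a = np.full(25, 1 / 25)
        assert not highlight_mask(a, MaskRule()).any()  # 1/T < 1.2/T

    def test_variance_permutation_invariant(self, rng):
        a = rng.random(20)
        a /= a.sum()
        assert trajectory_score(a) == pytest.approx(
            trajectory_score(rng.permutation(a)), abs=1e-15)


# -- random-instance equivalence against the oracles


class TestOracleEquivalence:
    N = 100

    def test_intersect_and_scores_match_oracles(self):
        rng = np.random.default_rng(77)
        for _ in range(self.N):
            A_A, A_B = random_attention_sets(rng)
            assert score_fc(A_A, A_B) == pytest.approx(oracle_sfc(A_A, A_B), abs=1e-12)
            assert score_it(A_A, A_B) == pytest.approx(oracle_sit(A_A, A_B), abs=1e-12)
            for a in A_A:
                assert trajectory_score(a) == pytest.approx(oracle_var(list(a)), abs=1e-12)

    def test_dist_diff_matches_oracle(self):
        rng = np.random.default_rng(88)
        for _ in range(self.N):
            A_A, A_B = random_attention_sets(rng)
            F_A = [rng.standard_normal(len(a)) for a in A_A]
            F_B = [rng.standard_normal(len(a)) + 0.5 for a in A_B]
            got = dist_diff(A_A, F_A, A_B, F_B)
            want = oracle_dist_diff(A_A, F_A, A_B, F_B)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_pearson_matches_two_pass_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(self.N):
            n = int(rng.integers(5, 50))
            x, y = rng.standard_normal(n), rng.standard_normal(n)
            assert analysis._pearson(x, y) == pytest.approx(
                oracle_pearson(list(x), list(y)), abs=1e-12)


# -- ranking and correlation behavior


def make_series_set(atts, labels, transform):
    series = {tid: {"f": transform(a)} for tid, a in atts.items()}
    return FeatureSeriesSet(series=series, labels=labels, channel_names=("f",),
                            dt={tid: 1.0 for tid in atts})


class TestRankLayers:
    def test_peaked_separated_layer_beats_uniform(self, rng):
        n, T = 6, 30
        uniform = ([np.full(T, 1 / T)] * n, [np.full(T, 1 / T)] * n)
        peaked_a, peaked_b = [], []
        for _ in range(n):
            a = np.full(T, 0.2 / T)
            a[:3] += (1 - a.sum()) / 3  # class A attends to the start
            peaked_a.append(a)
            b = np.full(T, 0.2 / T)
            b[-3:] += (1 - b.sum()) / 3  # class B to the end
            peaked_b.append(b)
        table = rank_layers({"dull": uniform, "sharp": (peaked_a, peaked_b)})
        assert table.iloc[0]["layer"] == "sharp"
        assert table.iloc[0]["s"] > table.iloc[1]["s"]

    def test_scores_invariant_to_trajectory_order(self, rng):
        A_A, A_B = random_attention_sets(rng)
        t1 = rank_layers({"l": (A_A, A_B)})
        t2 = rank_layers({"l": (A_A[::-1], A_B[::-1])})
        assert t1.iloc[0]["s"] == pytest.approx(t2.iloc[0]["s"], abs=1e-15)

    def test_single_layer_rank(self, rng):
        A_A, A_B = random_attention_sets(rng)
        table = rank_layers({"only": (A_A, A_B)})
        assert len(table) == 1 and table.iloc[0]["layer"] == "only"


class TestCorrelate:
    def test_affine_feature_perfect_correlation(self, rng):
        atts = {f"t{i}": rng.random(20) for i in range(4)}
        labels = {f"t{i}": "A" if i < 2 else "B" for i in range(4)}
        fs = make_series_set(atts, labels, lambda a: 3.0 * a + 1.0)
        table = analysis.correlate(atts, fs, derivations=("raw",))
        assert table.iloc[0]["r"] == pytest.approx(1.0, abs=1e-9)
        fs_neg = make_series_set(atts, labels, lambda a: -a)
        table = analysis.correlate(atts, fs_neg, derivations=("raw",))
        assert table.iloc[0]["r"] == pytest.approx(-1.0, abs=1e-9)

    def test_zero_variance_feature_reported_nan(self, rng):
        atts = {"t0": rng.random(15), "t1": rng.random(15)}
        labels = {"t0": "A", "t1": "B"}
        fs = make_series_set(atts, labels, lambda a: np.zeros_like(a))
        table = analysis.correlate(atts, fs, derivations=("raw",))
        assert np.isnan(table.iloc[0]["r"])

    def test_misaligned_lengths_rejected(self, rng):
        atts = {"t0": rng.random(10), "t1": rng.random(10)}
        labels = {"t0": "A", "t1": "B"}
        fs = make_series_set({"t0": rng.random(9), "t1": rng.random(10)},
                             labels, lambda a: a)
        with pytest.raises(ValidationError):
            analysis.correlate(atts, fs)


class TestDistDiffEdges:
    def test_identical_extracted_distributions(self):
        a = np.array([0.5, 0.3, 0.1, 0.1])  # two attended steps (thr = 0.3)
        f = np.array([1.0, 2.0, 3.0, 4.0])
        assert dist_diff([a], [f], [a.copy()], [f.copy()]) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_extracted_distributions(self):
        a = np.array([0.9, 0.05, 0.05])
        assert dist_diff([a], [np.array([0.0, 9, 9])],
                         [a.copy()], [np.array([5.0, 9, 9])]) == pytest.approx(1.0)

    def test_uniform_attention_undefined(self):
        a = np.full(10, 0.1)
        f = np.arange(10.0)
        assert np.isnan(dist_diff([a], [f], [a.copy()], [f.copy()]))
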