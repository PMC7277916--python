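"""Rank statistics: Spearman with p-value, ROC AUC, percentiles, panel logic."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rnaconcord import (
    CountMatrix,
    Marker,
    UndefinedStatisticError,
    binarize_ihc,
    default_panel,
    marker_concordance,
    percentile_rank,
    roc_auc,
    simulate_cohort,
    SimulationConfig,
    spearman_with_p,
)


def _brute_force_permutation_p(x, y):
    """Two-sided exact p by explicit enumeration of rank permutations."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    hits = total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12:
            hits += 1
    return hits / total


def _brute_force_auc(values, status):
    """Pairwise counting: P(pos > neg) + P(pos == neg)/2."""
    pos = [v for v, s in zip(values, status) if s]
    neg = [v for v, s in zip(values, status) if not s]
    score = 0.0
    for p in pos:
        for n in neg:
            score += 1.0 if p > n else (0.5 if p == n else 0.0)
    return score / (len(pos) * len(neg))


class TestSpearman:
    def test_perfectly_monotone_gives_rho_one(self):
        rho, p, n = spearman_with_p([1, 2, 3], [10, 20, 30])
        assert rho == pytest.approx(1.0)
        # exact permutation p at n=3: 2 of 6 orderings reach |rho| = 1
        assert p == pytest.approx(2 / 6)
        assert n == 3
        _, p_t, _ = spearman_with_p([1, 2, 3], [10, 20, 30], exact=False)
        assert p_t == 0.0

    def test_known_small_example_with_exact_p(self):
        x, y = [1, 2, 3, 4], [2, 1, 4, 3]
        rho, p, _ = spearman_with_p(x, y, exact=True)
        assert rho == pytest.approx(0.6)
        assert p == pytest.approx(_brute_force_permutation_p(x, y))

    def test_default_p_matches_enumeration_for_n8(self):
        # at n <= 8 the default p is the exact permutation p; the oracle is
        # an independent brute-force enumeration in this module
        rng = np.random.default_rng(12)
        for _ in range(8):
            x = rng.integers(0, 4, size=8)
            y = rng.normal(size=8)
            if np.ptp(x) == 0:
                continue
            _, p_default, _ = spearman_with_p(x, y)
            assert abs(p_default - _brute_force_permutation_p(x, y)) <= 0.02

    def test_t_approximation_tracks_exact_p_for_untied_n8(self):
        # the large-n t approximation stays within a few percent of the
        # exact permutation null already at n=8 when ranks are untied
        rng = np.random.default_rng(12)
        for _ in range(8):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            _, p_t, _ = spearman_with_p(x, y, exact=False)
            _, p_exact, _ = spearman_with_p(x, y, exact=True)
            assert abs(p_t - p_exact) <= 0.05

    def test_matches_r_cor_test_on_tied_data(self):
        # frozen from R: cor.test(..., method="spearman", exact=FALSE)
        x = [0, 0, 1, 1, 2, 3, 3, 3, 2, 1, 0, 2]
        y = [1.2, 0.7, 2.3, 1.9, 3.1, 4.0, 3.5, 5.2, 2.2, 2.0, 1.1, 2.9]
        rho, p, _ = spearman_with_p(x, y)
        assert rho == pytest.approx(0.9500337376, abs=1e-9)
        assert p == pytest.approx(2.254862466e-06, rel=1e-6)

    def test_fixture_rin_vs_coverage_reproduces_reported_value(self, combined_cohort):
        rin = [r.rin if r.rin is not None else np.nan for r in combined_cohort]
        cov = [r.coverage_reads for r in combined_cohort]
        rho, p, n = spearman_with_p(rin, cov)
        assert n == 56
        assert rho == pytest.approx(0.304, abs=0.05)
        assert p == pytest.approx(0.022, abs=0.02)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 9, size=30).astype(float)
        y = rng.normal(size=30)
        rho0, p0, _ = spearman_with_p(x, y)
        rho1, p1, _ = spearman_with_p(np.exp(x), y**3)
        assert rho1 == pytest.approx(rho0, abs=1e-12)
        assert p1 == pytest.approx(p0, abs=1e-12)

    def test_missing_values_dropped_pairwise(self):
        rho, _, n = spearman_with_p([1, 2, np.nan, 4, 5], [1, np.nan, 3, 4, 6])
        assert n == 3
        assert rho == pytest.approx(1.0)

    def test_too_few_pairs_raises(self):
        with pytest.raises(UndefinedStatisticError):
            spearman_with_p([1, 2, np.nan], [1, np.nan, 3])

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedStatisticError):
            spearman_with_p([2, 2, 2, 2], [1, 2, 3, 4])


class TestBinarization:
    @pytest.mark.parametrize(
        "protein,score,expected",
        [
            ("ER", 2, False),  # strict inequality at the clinical cutoff
            ("ER", 3, True),
            ("PR", 2, False),
            ("PR", 8, True),
            ("HER2", 2, False),  # only "+++" counts as positive
            ("HER2", 3, True),
            ("PD-L1", 0, False),
            ("PD-L1", 1, True),
            ("PD-L1", 2, True),
        ],
    )
    def test_clinical_positivity_rules(self, protein, score, expected):
        marker = default_panel()[protein]
        assert marker.is_positive(score) is expected

    def test_invalid_score_rejected(self):
        with pytest.raises(ValueError):
            default_panel()["HER2"].is_positive(5)

    def test_unknown_operator_rejected(self):
        with pytest.raises(ValueError):
            binarize_ihc(1, {"lt": 2})


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([5, 6, 1, 2], [True, True, False, False]) == 1.0

    def test_interleaved_small_example(self):
        # pairs: (3>2), (3>0), (1<2), (1>0) -> 3 of 4
        assert roc_auc([3, 1, 2, 0], [True, True, False, False]) == 0.75

    def test_all_ties_give_half(self):
        assert roc_auc([4, 4, 4, 4], [True, False, True, False]) == 0.5

    def test_label_swap_complements(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=30)
        s = rng.random(30) < 0.4
        assert roc_auc(v, s) == pytest.approx(1.0 - roc_auc(v, ~s))

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            v = rng.integers(0, 10, size=30).astype(float)  # force ties
            s = rng.random(30) < 0.5
            if s.all() or not s.any():
                continue
            assert roc_auc(v, s) == pytest.approx(_brute_force_auc(v, s), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        v = rng.normal(size=50)
        s = rng.random(50) < 0.5
        assert roc_auc(v, s) == pytest.approx(roc_auc_score(s, v), abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(UndefinedStatisticError):
            roc_auc([1, 2, 3], [True, True, True])


class TestPercentileRank:
    def _matrix(self, arr):
        return CountMatrix(
            pd.DataFrame(
                np.asarray(arr),
                index=[f"g{i}" for i in range(len(arr))],
                columns=[f"s{j}" for j in range(len(arr[0]))],
            )
        )

    def test_strict_top_rank_formula(self):
        m = self._matrix([[10], [5], [2], [0]])
        pct = percentile_rank(m, "g0")
        assert pct["s0"] == pytest.approx(100 * (4 - 0.5) / 4)

    def test_full_tie_gives_fifty(self):
        m = self._matrix([[3, 3], [3, 3], [3, 3]])
        pct = percentile_rank(m, "g1")
        assert (pct == 50.0).all()

    def test_agrees_with_rankdata_midranks(self):
        rng = np.random.default_rng(4)
        arr = rng.integers(0, 20, size=(40, 5))
        m = self._matrix(arr)
        for gene in ("g0", "g17"):
            got = percentile_rank(m, gene).to_numpy()
            i = int(gene[1:])
            want = np.array(
                [100 * (stats.rankdata(arr[:, j])[i] - 0.5) / 40 for j in range(5)]
            )
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_invariant_to_sample_scaling(self):
        arr = np.array([[1, 2], [5, 9], [30, 41]])
        m1 = self._matrix(arr)
        m2 = self._matrix(arr * np.array([3, 7]))
        pd.testing.assert_series_equal(
            percentile_rank(m1, "g1"), percentile_rank(m2, "g1")
        )

    def test_absent_gene_raises(self, small_matrix):
        with pytest.raises(KeyError):
            percentile_rank(small_matrix, "NOPE")


@pytest.fixture(scope="module")
def synthetic():
    cohort, matrix, truth = simulate_cohort(
        SimulationConfig(seed=77, n_samples=30, n_genes=2000)
    )
    return cohort, matrix, truth


class TestMarkerConcordance:

    def test_per_marker_results_for_present_markers(self, synthetic):
        cohort, matrix, _ = synthetic
        res = marker_concordance(matrix, cohort)
        for protein in ("HER2", "ER", "PR"):
            entry = res[protein]
            assert entry.error is None
            assert -1 <= entry.rho <= 1
            assert entry.n == 30
            assert entry.n_pos + entry.n_neg == 30
            assert (entry.percentile_by_sample >= 0).all()
            assert (entry.percentile_by_sample <= 100).all()

    def test_absent_gene_reported_without_breaking_others(self, synthetic):
        cohort, matrix, _ = synthetic
        res = marker_concordance(matrix, cohort)
        # PD-L1's gene is not simulated in a BC cohort
        assert res["PD-L1"].error is not None
        assert res["HER2"].error is None

    def test_constant_expression_gives_undefined_result(self, synthetic):
        # identical columns give equal size factors, so the marker's
        # normalized expression is exactly constant across samples
        cohort, matrix, _ = synthetic
        counts = matrix.counts.copy()
        first = counts.iloc[:, 0]
        for c in counts.columns:
            counts[c] = first
        res = marker_concordance(CountMatrix(counts), cohort)
        assert res["HER2"].rho is None
        assert "variance" in res["HER2"].error

    def test_rank_statistics_identical_with_and_without_log(self, synthetic):
        # rho and AUC are rank-based, so the (strictly monotone) log
        # transform of normalized counts cannot change them
        from rnaconcord import log_normalize

        cohort, matrix, _ = synthetic
        norm = log_normalize(matrix)
        res_log = marker_concordance(matrix, cohort, log_counts=norm.log_counts)
        res_lin = marker_concordance(
            matrix, cohort, log_counts=norm.normalized_counts
        )
        for protein in ("HER2", "ER", "PR"):
            assert res_lin[protein].rho == pytest.approx(res_log[protein].rho, abs=1e-12)
            assert res_lin[protein].auc == pytest.approx(res_log[protein].auc, abs=1e-12)
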