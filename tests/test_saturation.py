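"""Downsampling: conservation, expectation, determinism, saturation logic."""

import warnings

import numpy as np
import pytest

from rnaconcord import (
    Marker,
    MarkerPanel,
    MarkerSim,
    SaturationConfig,
    SimulationConfig,
    marker_concordance,
    minimal_coverage,
    saturation_curve,
    simulate_cohort,
    subsample_counts,
    subsample_matrix,
)
from rnaconcord.saturation import LevelResult, SaturationCurve


class TestSubsampleCounts:
    def test_target_equal_to_total_is_identity(self):
        rng = np.random.default_rng(0)
        v = np.array([10, 0, 5, 85])
        out = subsample_counts(v, 100, rng)
        np.testing.assert_array_equal(out, v)

    def test_target_zero_gives_zero_vector(self):
        rng = np.random.default_rng(0)
        out = subsample_counts(np.array([10, 20]), 0, rng)
        np.testing.assert_array_equal(out, [0, 0])

    def test_total_conserved_exactly(self):
        rng = np.random.default_rng(1)
        v = rng.integers(0, 1000, size=200)
        for target in (17, 1000, int(v.sum()) // 2):
            assert subsample_counts(v, target, rng).sum() == target

    def test_mean_matches_hypergeometric_expectation(self):
        # 10,000 draws from (900, 100) at depth 100: E[gene 1] = 90,
        # Var = 100 * 0.9 * 0.1 * (900/999) -> SE of the mean ~ 0.0285
        rng = np.random.default_rng(2)
        v = np.array([900, 100])
        draws = np.array([subsample_counts(v, 100, rng)[0] for _ in range(10_000)])
        se = np.sqrt(100 * 0.9 * 0.1 * (900 / 999) / 10_000)
        assert abs(draws.mean() - 90.0) <= 3 * se

    def test_multinomial_fast_path_mean(self):
        # target below 1% of total exercises the approximate path
        rng = np.random.default_rng(3)
        v = np.array([90_000, 10_000])
        draws = np.array([subsample_counts(v, 100, rng)[1] for _ in range(5_000)])
        se = np.sqrt(100 * 0.1 * 0.9 / 5_000)
        assert abs(draws.mean() - 10.0) <= 4 * se

    def test_oversized_target_warns_and_returns_unchanged(self):
        rng = np.random.default_rng(4)
        v = np.array([5, 5])
        with pytest.warns(UserWarning, match="exceeds total"):
            out = subsample_counts(v, 100, rng)
        np.testing.assert_array_equal(out, v)

    def test_negative_target_rejected(self):
        with pytest.raises(ValueError):
            subsample_counts(np.array([1, 2]), -1, np.random.default_rng(0))


@pytest.fixture(scope="module")
def small_cohort():
    cfg = SimulationConfig(
        seed=55, cohort="BC", n_samples=12, n_genes=1500,
        coverage_range=(300_000, 300_000),  # equal depths: no subsample warnings
    )
    cohort, matrix, _ = simulate_cohort(cfg)
    return cohort, matrix


class TestSaturationCurve:
    def test_degenerate_grid_reproduces_direct_concordance(self, small_cohort):
        cohort, matrix = small_cohort
        full = int(matrix.column_totals().max())
        config = SaturationConfig(coverage_grid=(full,), replicates_per_level=1, seed=7)
        curves = saturation_curve(matrix, cohort, config=config)
        direct = marker_concordance(matrix, cohort, include_percentiles=False)
        for protein in ("HER2", "ER", "PR"):
            level = curves[protein].levels[0]
            assert level.rhos[0] == direct[protein].rho
            assert level.ps[0] == direct[protein].p

    def test_deterministic_for_fixed_seed(self, small_cohort):
        cohort, matrix = small_cohort
        config = SaturationConfig(
            coverage_grid=(5_000, 50_000), replicates_per_level=3, seed=11
        )
        c1 = saturation_curve(matrix, cohort, config=config)
        c2 = saturation_curve(matrix, cohort, config=config)
        for protein in c1:
            for l1, l2 in zip(c1[protein].levels, c2[protein].levels):
                np.testing.assert_array_equal(l1.rhos, l2.rhos)  # NaN-safe
                np.testing.assert_array_equal(l1.ps, l2.ps)

    def test_significant_fraction_nondecreasing_in_coverage(self, small_cohort):
        cohort, matrix = small_cohort
        config = SaturationConfig(
            coverage_grid=(1_000, 10_000, 100_000, 290_000),
            replicates_per_level=10,
            seed=13,
        )
        curves = saturation_curve(matrix, cohort, config=config)
        for curve in curves.values():
            if curve.gene == "CD274":
                continue
            fracs = [lv.frac_significant(0.05) for lv in curve.levels]
            # slack of two replicates out of ten = Monte Carlo noise on the
            # fraction estimates near the transition depth
            assert all(b >= a - 0.2 for a, b in zip(fracs, fracs[1:])), fracs
            assert fracs[-1] >= fracs[0]

    def test_subsample_matrix_preserves_layout(self, small_cohort):
        _, matrix = small_cohort
        rng = np.random.default_rng(17)
        sub = subsample_matrix(matrix, 1_000, rng)
        assert sub.genes == matrix.genes
        assert sub.samples == matrix.samples
        assert (sub.column_totals() == 1_000).all()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SaturationConfig(coverage_grid=(100, 50)).validate()
        with pytest.raises(ValueError):
            SaturationConfig(alpha=1.5).validate()
        with pytest.raises(ValueError):
            SaturationConfig(replicates_per_level=0).validate()


class TestMinimalCoverage:
    def _curve(self, ps_by_level):
        levels = [
            LevelResult(coverage=c, rhos=[0.5] * len(ps), ps=list(ps))
            for c, ps in ps_by_level
        ]
        return SaturationCurve("X", "GX", 0.05, levels)

    def test_all_significant_everywhere_gives_smallest_level(self):
        curve = self._curve([(100, [0.01, 0.02]), (1000, [0.01, 0.001])])
        assert minimal_coverage(curve, 0.05) == 100

    def test_no_significant_level_reports_not_reached(self):
        curve = self._curve([(100, [0.5]), (1000, [0.2])])
        assert minimal_coverage(curve, 0.05) is None

    def test_requires_all_higher_levels_significant_too(self):
        # significant at 100, a dropout at 1000, solid from 10000 on
        curve = self._curve(
            [(100, [0.01]), (1000, [0.2]), (10_000, [0.01]), (100_000, [0.01])]
        )
        assert minimal_coverage(curve, 0.05) == 10_000

    def test_undefined_p_counts_as_failure(self):
        curve = self._curve([(100, [float("nan")]), (1000, [0.01])])
        assert minimal_coverage(curve, 0.05) == 1000

    def test_abundant_marker_needs_no_more_reads_than_rare(self):
        # two otherwise identical markers, ~10x apart in baseline abundance
        markers = (
            MarkerSim("HER2", "ERBB2", 4, (13, 6, 1, 19), 0.02, 97.5, 1.1, 3),
            MarkerSim("ER", "ESR1", 4, (13, 6, 1, 19), 0.02, 80.0, 1.1, 3),
        )
        panel = MarkerPanel(
            (Marker("HER2", "ERBB2", 4, {"eq": 3}), Marker("ER", "ESR1", 4, {"gt": 2}))
        )
        grid = (2_000, 10_000, 50_000, 250_000, 1_200_000)
        wins = ties = 0
        n_runs = 5
        for seed in range(220, 220 + n_runs):
            cfg = SimulationConfig(
                seed=seed, cohort="BC", n_samples=30, n_genes=5000, markers=markers
            )
            cohort, matrix, _ = simulate_cohort(cfg)
            config = SaturationConfig(
                coverage_grid=grid, replicates_per_level=5, seed=seed
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                curves = saturation_curve(matrix, cohort, panel, config)
            mc_abundant = curves["HER2"].minimal_coverage()
            mc_rare = curves["ER"].minimal_coverage()
            assert mc_abundant is not None
            if mc_rare is None or mc_abundant < mc_rare:
                wins += 1
            elif mc_abundant == mc_rare:
                ties += 1
        assert wins + ties == n_runs
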