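"""Read-downsampling saturation analysis.

How many uniquely mapped reads per sample does each biomarker need before
its RNA-seq expression correlates significantly with IHC? The procedure:
subsample every sample's gene-level counts without replacement to a grid
of target depths (a multivariate hypergeometric draw over the read
population, so column totals hit the target exactly), renormalize,
recompute each marker's Spearman rho and p-value, and repeat per level.
The minimal coverage for a marker is the smallest grid depth at which
every replicate is significant at that depth and at every deeper one.

Abundant markers saturate early — a gene in the top decile of expression
keeps enough reads for a stable rank ordering at depths where a
mid-distribution gene has mostly zeros — which is the mechanistic link
between a marker's abundance percentile and its coverage requirement.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, CountMatrix
from .concordance import (
    ConcordanceResult,
    MarkerPanel,
    default_panel,
    marker_concordance,
)
from .normalize import NormalizationError, log_normalize

__all__ = [
    "SaturationConfig",
    "LevelResult",
    "SaturationCurve",
    "subsample_counts",
    "subsample_matrix",
    "saturation_curve",
    "minimal_coverage",
    "default_coverage_grid",
]


def default_coverage_grid(
    low: int = 500, high: int = 3_500_000, n_levels: int = 20
) -> tuple[int, ...]:
    """Log-spaced coverage grid over the simulated-depth range."""
    grid = np.unique(np.geomspace(low, high, n_levels).round().astype(int))
    return tuple(int(g) for g in grid)


@dataclass(frozen=True)
class SaturationConfig:
    coverage_grid: tuple[int, ...] = field(default_factory=default_coverage_grid)
    replicates_per_level: int = 10
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        grid = tuple(self.coverage_grid)
        if len(grid) == 0 or any(g <= 0 for g in grid):
            raise ValueError("coverage grid must be non-empty and positive")
        if list(grid) != sorted(grid):
            raise ValueError("coverage grid must be sorted ascending")
        if self.replicates_per_level < 1:
            raise ValueError("replicates_per_level must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_json(cls, path) -> "SaturationConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "coverage_grid" in raw:
            raw["coverage_grid"] = tuple(raw["coverage_grid"])
        return cls(**raw)


@dataclass
class LevelResult:
    """Replicate statistics for one marker at one coverage level."""

    coverage: int
    rhos: list[float]
    ps: list[float]

    @property
    def mean_rho(self) -> float:
        finite = [r for r in self.rhos if not np.isnan(r)]
        return float(np.mean(finite)) if finite else float("nan")

    def frac_significant(self, alpha: float) -> float:
        """Fraction of replicates with a defined p < alpha (undefined counts as failure)."""
        flags = [(not np.isnan(p)) and p < alpha for p in self.ps]
        return float(np.mean(flags))


@dataclass
class SaturationCurve:
    protein: str
    gene: str
    alpha: float
    levels: list[LevelResult]

    def minimal_coverage(self, alpha: float | None = None) -> int | None:
        return minimal_coverage(self, self.alpha if alpha is None else alpha)

    def to_dict(self) -> dict:
        return {
            "protein": self.protein,
            "gene": self.gene,
            "alpha": self.alpha,
            "levels": [
                {
                    "coverage": lv.coverage,
                    "rhos": [None if np.isnan(r) else float(r) for r in lv.rhos],
                    "ps": [None if np.isnan(p) else float(p) for p in lv.ps],
                    "mean_rho": None if np.isnan(lv.mean_rho) else lv.mean_rho,
                    "frac_significant": lv.frac_significant(self.alpha),
                }
                for lv in self.levels
            ],
            "minimal_coverage": self.minimal_coverage(),
        }


def subsample_counts(
    counts: np.ndarray, target: int, rng: np.random.Generator
) -> np.ndarray:
    """Subsample a per-gene count vector to ``target`` total reads.

    Draws a multivariate hypergeometric sample — reads are selected
    without replacement from the finite population the vector describes —
    so the output sums to ``target`` exactly and gene g's expected count
    is target * k_g / K. A multinomial approximation is used when the
    target is below 1% of the total (the two coincide in that regime).
    A target at or above the total returns the vector unchanged with a
    warning.
    """
    if target < 0:
        raise ValueError("target must be non-negative")
    counts = np.asarray(counts)
    total = int(counts.sum())
    if target >= total:
        if target > total:
            warnings.warn(
                f"subsample target {target} exceeds total {total}; returning counts unchanged",
                stacklevel=2,
            )
        return counts.astype(np.int64).copy()
    if target == 0:
        return np.zeros_like(counts, dtype=np.int64)
    if target < total / 100:
        p = counts / total
        return rng.multinomial(target, p).astype(np.int64)
    return rng.multivariate_hypergeometric(
        counts.astype(np.int64), target, method="marginals"
    ).astype(np.int64)


def subsample_matrix(
    matrix: CountMatrix, target: int, rng: np.random.Generator
) -> CountMatrix:
    """Subsample every sample column of a matrix to ``target`` reads."""
    arr = matrix.counts.to_numpy()
    out = np.column_stack(
        [subsample_counts(arr[:, j], target, rng) for j in range(arr.shape[1])]
    )
    return CountMatrix(
        pd.DataFrame(out, index=matrix.counts.index, columns=matrix.counts.columns)
    )


def _log_normalize_with_fallback(matrix: CountMatrix, pseudocount: float) -> pd.DataFrame:
    """Median-of-ratios log-normalization, falling back to library-size
    scaling when no reference-eligible gene survives subsampling.

    At heavy downsampling almost every gene has a zero somewhere, so the
    median-of-ratios reference set can be empty; since all samples are
    subsampled to a common depth, library-size factors are then all equal
    and the rank-based statistics downstream are unaffected.
    """
    try:
        return log_normalize(matrix, pseudocount=pseudocount).log_counts
    except NormalizationError:
        totals = matrix.column_totals().to_numpy(dtype=float)
        s = totals / np.exp(np.mean(np.log(totals)))
        return np.log2(matrix.counts / s + pseudocount)


def saturation_curve(
    matrix: CountMatrix,
    cohort: Cohort,
    panel: MarkerPanel | None = None,
    config: SaturationConfig | None = None,
    pseudocount: float = 1.0,
) -> dict[str, SaturationCurve]:
    """Full downsampling experiment: per marker, per level, per replicate.

    For each coverage level and replicate, every sample is subsampled to
    the level, the matrix is renormalized, and each marker's Spearman
    rho/p against its IHC scores is recomputed. Markers share the same
    subsampled matrices within a replicate. An undefined statistic (e.g.
    the marker count dropped to all zeros) is recorded as NaN and counts
    as non-significant. Deterministic for a fixed config.
    """
    if panel is None:
        panel = default_panel()
    if config is None:
        config = SaturationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    curves = {
        m.protein: SaturationCurve(m.protein, m.gene, config.alpha, [])
        for m in panel
    }
    for level in config.coverage_grid:
        per_marker: dict[str, LevelResult] = {
            m.protein: LevelResult(int(level), [], []) for m in panel
        }
        for _ in range(config.replicates_per_level):
            sub = subsample_matrix(matrix, int(level), rng)
            log_counts = _log_normalize_with_fallback(sub, pseudocount)
            result = marker_concordance(
                sub,
                cohort,
                panel,
                pseudocount=pseudocount,
                log_counts=log_counts,
                include_percentiles=False,
            )
            for m in panel:
                entry = result[m.protein]
                per_marker[m.protein].rhos.append(
                    float("nan") if entry.rho is None else entry.rho
                )
                per_marker[m.protein].ps.append(
                    float("nan") if entry.p is None else entry.p
                )
        for m in panel:
            curves[m.protein].levels.append(per_marker[m.protein])
    return curves


def minimal_coverage(curve: SaturationCurve, alpha: float) -> int | None:
    """Smallest grid level from which on every replicate is significant.

    Returns ``None`` ("not reached") when no such level exists.
    """
    ok = [lv.frac_significant(alpha) == 1.0 for lv in curve.levels]
    minimal = None
    for level, good in zip(reversed(curve.levels), reversed(ok)):
        if good:
            minimal = level.coverage
        else:
            break
    return minimal


def full_coverage_check(
    matrix: CountMatrix, cohort: Cohort, panel: MarkerPanel | None = None
) -> ConcordanceResult:
    """Direct concordance at full depth (the grid's degenerate endpoint)."""
    return marker_concordance(matrix, cohort, panel)
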