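"""Ordinal IHC vs expression concordance statistics.

Three rank-based statistics quantify how well RNA-seq expression of a
biomarker gene reproduces its IHC status:

* tie-corrected Spearman correlation between the ordinal IHC score and
  (log-normalized) expression across samples, with a two-sided p-value
  from the t approximation t = rho * sqrt((n-2)/(1-rho^2)) on n-2 degrees
  of freedom — the standard choice when ties are pervasive, as they are in
  ordinal IHC scores — and an exact permutation p-value for small n;
* the ROC area under the curve for classifying binary IHC status from
  expression, computed from the Mann-Whitney U statistic with ties
  counted 1/2: AUC = P(random positive > random negative) + P(tie)/2;
* the within-sample percentile rank of the marker's raw count among all
  genes, which explains how much sequencing depth a marker needs.

Positivity rules follow clinical convention: ER/PR positive at score > 2,
HER2 positive only at "+++" (score 3), PD-L1 positive at >= 1% of cells
stained (category >= 1).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, CountMatrix
from .normalize import log_normalize

__all__ = [
    "Marker",
    "MarkerPanel",
    "MarkerConcordance",
    "ConcordanceResult",
    "UndefinedStatisticError",
    "default_panel",
    "spearman_with_p",
    "binarize_ihc",
    "roc_auc",
    "percentile_rank",
    "marker_concordance",
]


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for this input (zero variance, one class, n < 3)."""


# ---------------------------------------------------------------------------
# marker panel

@dataclass(frozen=True)
class Marker:
    """One biomarker: protein name, measured gene, IHC scale and positivity rule.

    ``positivity`` is one of ``{"gt": c}`` (positive iff score > c),
    ``{"eq": c}`` (positive iff score == c) or ``{"ge": c}``
    (positive iff score >= c).
    """

    protein: str
    gene: str
    scale_size: int
    positivity: dict = field(default_factory=dict)

    def is_positive(self, score: int) -> bool:
        return binarize_ihc(score, self.positivity, scale_size=self.scale_size)


@dataclass(frozen=True)
class MarkerPanel:
    markers: tuple[Marker, ...]

    def __post_init__(self) -> None:
        genes = [m.gene for m in self.markers]
        if len(set(genes)) != len(genes):
            raise ValueError("marker gene symbols must be unique")

    def __iter__(self):
        return iter(self.markers)

    def __getitem__(self, protein: str) -> Marker:
        for m in self.markers:
            if m.protein == protein:
                return m
        raise KeyError(protein)


def default_panel() -> MarkerPanel:
    """The clinical four-marker panel: HER2, ER, PR (BC) and PD-L1 (LC)."""
    return MarkerPanel(
        (
            Marker("HER2", "ERBB2", 4, {"eq": 3}),
            Marker("ER", "ESR1", 9, {"gt": 2}),
            Marker("PR", "PGR", 9, {"gt": 2}),
            Marker("PD-L1", "CD274", 3, {"ge": 1}),
        )
    )


def binarize_ihc(score: int, rule: dict, scale_size: int | None = None) -> bool:
    """Map an ordinal IHC score to binary positive/negative status."""
    if scale_size is not None and not (0 <= score < scale_size):
        raise ValueError(f"score {score} outside 0..{scale_size - 1}")
    if len(rule) != 1:
        raise ValueError(f"positivity rule must have exactly one clause, got {rule!r}")
    (op, cutoff), = rule.items()
    if op == "gt":
        return score > cutoff
    if op == "ge":
        return score >= cutoff
    if op == "eq":
        return score == cutoff
    raise ValueError(f"unknown positivity operator {op!r}")


# ---------------------------------------------------------------------------
# rank statistics

def _clean_pairs(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)  # mid-ranks for ties
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_with_p(x, y, exact: bool | None = None) -> tuple[float, float, int]:
    """Tie-corrected Spearman rho with a two-sided p-value.

    Pairs with a missing value in either vector are dropped. rho is the
    Pearson correlation of mid-ranks. The p-value uses the t approximation
    on n-2 degrees of freedom — the convention for tied data — except at
    n <= 8, where all n! rank permutations are enumerable and the
    two-sided permutation p-value P(|rho_perm| >= |rho_obs|) is exact.
    ``exact`` forces one or the other (True is allowed only for n <= 8);
    the default ``None`` selects the exact p automatically for n <= 8.

    Returns ``(rho, p, n)`` with n the number of complete pairs.
    """
    x, y = _clean_pairs(x, y)
    n = len(x)
    if n < 3:
        raise UndefinedStatisticError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("zero variance in x or y")
    rho = _spearman_rho(x, y)
    if exact is None:
        exact = n <= 8
    if exact:
        if n > 8:
            raise ValueError("exact permutation p-value supported only for n <= 8")
        p = _exact_permutation_p(x, y, rho)
        return rho, p, n
    # t approximation, two-sided (the convention for tied data)
    if abs(rho) >= 1.0:
        return rho, 0.0, n
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(min(p, 1.0)), n


def _exact_permutation_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p over all permutations of y against fixed x."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    count = 0
    total = 0
    thresh = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        rho = np.corrcoef(rx, ry[list(perm)])[0, 1]
        total += 1
        if abs(rho) >= thresh:
            count += 1
    return count / total


def roc_auc(values, status) -> float:
    """ROC AUC from the Mann-Whitney U statistic, ties counted 1/2.

    ``status`` is boolean (True = positive). Equals the probability that a
    random positive sample's value exceeds a random negative's, counting
    ties as half.
    """
    values = np.asarray(values, dtype=float)
    status = np.asarray(status, dtype=bool)
    if values.shape != status.shape or values.ndim != 1:
        raise ValueError("values and status must be 1-D of equal length")
    n_pos = int(status.sum())
    n_neg = int((~status).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedStatisticError("AUC needs at least one positive and one negative")
    ranks = stats.rankdata(values)
    u = ranks[status].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def percentile_rank(matrix: CountMatrix, gene: str) -> pd.Series:
    """Per-sample percentile of ``gene``'s raw count among all genes.

    Mid-rank convention scaled to 0-100: with G genes, a strictly top-ranked
    gene sits at 100*(G-0.5)/G and a full tie puts every gene at 50.
    """
    if gene not in matrix.counts.index:
        raise KeyError(f"gene {gene!r} not in matrix")
    counts = matrix.counts.to_numpy(dtype=float)
    g_total = counts.shape[0]
    gene_pos = matrix.counts.index.get_loc(gene)
    v = counts[gene_pos, :]
    # mid-rank of v within its column: (# strictly below) + (# tied + 1)/2
    less = (counts < v).sum(axis=0)
    ties = (counts == v).sum(axis=0)
    midrank = less + (ties + 1) / 2.0
    pct = 100.0 * (midrank - 0.5) / g_total
    return pd.Series(pct, index=matrix.counts.columns, name=gene)


# ---------------------------------------------------------------------------
# panel-level concordance

@dataclass
class MarkerConcordance:
    protein: str
    gene: str
    rho: float | None = None
    p: float | None = None
    n: int | None = None
    auc: float | None = None
    n_pos: int | None = None
    n_neg: int | None = None
    percentile_by_sample: pd.Series | None = None
    error: str | None = None


@dataclass
class ConcordanceResult:
    markers: dict[str, MarkerConcordance]

    def __getitem__(self, protein: str) -> MarkerConcordance:
        return self.markers[protein]

    def __iter__(self):
        return iter(self.markers.values())

    def to_dict(self) -> dict:
        out = {}
        for m in self:
            out[m.protein] = {
                "gene": m.gene,
                "rho": m.rho,
                "p": m.p,
                "n": m.n,
                "auc": m.auc,
                "n_pos": m.n_pos,
                "n_neg": m.n_neg,
                "percentile_by_sample": (
                    None
                    if m.percentile_by_sample is None
                    else {k: float(v) for k, v in m.percentile_by_sample.items()}
                ),
                "error": m.error,
            }
        return out


def marker_concordance(
    matrix: CountMatrix,
    cohort: Cohort,
    panel: MarkerPanel | None = None,
    pseudocount: float = 1.0,
    log_counts: pd.DataFrame | None = None,
    include_percentiles: bool = True,
) -> ConcordanceResult:
    """Per-marker IHC-score vs expression concordance over a cohort.

    For every marker in the panel whose gene is present in the matrix,
    computes Spearman rho/p between the ordinal IHC score and the
    log-normalized expression across samples with a non-missing score,
    the ROC AUC for the binary positivity status (when both classes are
    present), and the within-sample raw-count percentile of the marker
    gene. A marker whose gene is absent or whose statistic is undefined is
    reported with an ``error`` message; the other markers are still
    computed.

    ``log_counts`` can carry a precomputed log-normalized matrix (as from
    :func:`rnaconcord.normalize.log_normalize`) to avoid recomputation.
    """
    if panel is None:
        panel = default_panel()
    if log_counts is None:
        log_counts = log_normalize(matrix, pseudocount=pseudocount).log_counts

    in_matrix = [sid for sid in cohort.sample_ids if sid in log_counts.columns]
    results: dict[str, MarkerConcordance] = {}
    for marker in panel:
        res = MarkerConcordance(protein=marker.protein, gene=marker.gene)
        results[marker.protein] = res
        if marker.gene not in log_counts.index:
            res.error = f"gene {marker.gene!r} absent from count matrix"
            continue
        scored = [
            sid for sid in in_matrix if cohort[sid].score(marker.protein) is not None
        ]
        if len(scored) < 3:
            res.error = f"fewer than 3 samples with a {marker.protein} score"
            continue
        scores = np.array([cohort[sid].score(marker.protein) for sid in scored], float)
        expr = log_counts.loc[marker.gene, scored].to_numpy(dtype=float)
        try:
            res.rho, res.p, res.n = spearman_with_p(scores, expr)
        except UndefinedStatisticError as exc:
            res.error = str(exc)
            continue
        status = np.array(
            [marker.is_positive(int(s)) for s in scores], dtype=bool
        )
        res.n_pos = int(status.sum())
        res.n_neg = int((~status).sum())
        try:
            res.auc = roc_auc(expr, status)
        except UndefinedStatisticError as exc:
            res.auc = None
            res.error = str(exc)
        if include_percentiles:
            res.percentile_by_sample = percentile_rank(
                matrix.subset_samples(scored), marker.gene
            )
    return ConcordanceResult(results)
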