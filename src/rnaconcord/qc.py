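"""Quality control: coverage gating, degradation correlations, clustering.

FFPE storage fragments RNA, so every cohort passes three checks before the
concordance analysis: a per-sample coverage gate (default 2.5 million
uniquely mapped reads), pairwise Spearman correlations between RIN,
days-in-paraffin and coverage (degraded blocks should show low RIN, and
the gate must not silently track degradation), and hierarchical clustering
of log-normalized expression, which should group samples by tissue of
origin when the data are usable. Replicate concordance — pairwise Spearman
correlation of log-expression across repeated sequencing of slices from
one FFPE block — quantifies protocol reproducibility.

Clustering uses the classic Ward criterion applied through the
Lance-Williams recurrence directly to the (unsquared) Euclidean distance
matrix, i.e. the behaviour of R's ``hclust(method = "ward.D")``; this
differs from Ward.D2 (scipy's ``ward``) in merge heights, rarely in
topology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .cohort import Cohort
from .concordance import UndefinedStatisticError, spearman_with_p

__all__ = [
    "CorrelationEntry",
    "QCReport",
    "ClusteringResult",
    "coverage_filter",
    "qc_correlations",
    "ward_cluster",
    "replicate_concordance",
    "DEFAULT_COVERAGE_THRESHOLD",
]

#: uniquely mapped reads required for a sample to enter the analysis.
DEFAULT_COVERAGE_THRESHOLD = 2_500_000


@dataclass
class CorrelationEntry:
    rho: float
    p: float
    n_used: int


@dataclass
class QCReport:
    """Coverage gate outcome plus the pairwise QC correlations.

    A correlation pair with fewer than 3 complete observations is recorded
    as ``None`` with the reason in ``undefined``, so reports stay
    computable for sheets that lack, e.g., the days-in-paraffin column.
    """

    coverage_threshold: int
    passed: list[str]
    failed: list[str]
    correlations: dict[str, CorrelationEntry | None] = field(default_factory=dict)
    undefined: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "coverage_threshold": self.coverage_threshold,
            "passed": self.passed,
            "failed": self.failed,
            "correlations": {
                k: (None if v is None else {"rho": v.rho, "p": v.p, "n_used": v.n_used})
                for k, v in self.correlations.items()
            },
            "undefined": self.undefined,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def coverage_filter(cohort: Cohort, threshold: int = DEFAULT_COVERAGE_THRESHOLD) -> list[str]:
    """Sample ids whose coverage meets the threshold (>=, inclusive)."""
    return [r.sample_id for r in cohort if r.coverage_reads >= threshold]


def qc_correlations(cohort: Cohort) -> QCReport:
    """Coverage gate plus Spearman correlations among RIN, days, coverage.

    Each pair is computed over pairwise-complete samples with the
    tie-corrected Spearman statistic and two-sided t-approximation
    p-value. Pairs with fewer than 3 complete observations are reported as
    undefined rather than failing the whole report.
    """
    passed = coverage_filter(cohort)
    failed = [sid for sid in cohort.sample_ids if sid not in set(passed)]
    rin = np.array([np.nan if r.rin is None else r.rin for r in cohort], float)
    days = np.array(
        [np.nan if r.days_in_paraffin is None else r.days_in_paraffin for r in cohort],
        float,
    )
    cov = np.array([r.coverage_reads for r in cohort], float)

    report = QCReport(
        coverage_threshold=DEFAULT_COVERAGE_THRESHOLD, passed=passed, failed=failed
    )
    for name, x, y in (
        ("rin_vs_days", rin, days),
        ("rin_vs_coverage", rin, cov),
        ("days_vs_coverage", days, cov),
    ):
        try:
            rho, p, n = spearman_with_p(x, y)
            report.correlations[name] = CorrelationEntry(rho, p, n)
        except UndefinedStatisticError as exc:
            report.correlations[name] = None
            report.undefined[name] = str(exc)
    return report


# ---------------------------------------------------------------------------
# Ward.D clustering

@dataclass
class ClusteringResult:
    """Agglomerative Ward.D clustering of samples.

    ``merges`` is an (n-1, 4) array in scipy linkage layout: each row is
    (cluster_a, cluster_b, merge_height, new_cluster_size), with leaves
    numbered 0..n-1 in input order and internal nodes n, n+1, ...
    """

    merges: np.ndarray
    leaf_order: list[int]
    sample_ids: list[str]
    labels: list[str] | None
    purity: float | None

    def members(self, node: int) -> list[int]:
        """Leaf indices under an internal node (or the leaf itself)."""
        n = len(self.sample_ids)
        if node < n:
            return [node]
        row = self.merges[node - n]
        return self.members(int(row[0])) + self.members(int(row[1]))

    def to_newick(self) -> str:
        """Newick serialization with branch lengths from merge heights."""
        n = len(self.sample_ids)
        heights = {i: 0.0 for i in range(n)}
        for k, row in enumerate(self.merges):
            heights[n + k] = float(row[2])

        def render(node: int, parent_height: float) -> str:
            length = parent_height - heights[node]
            if node < n:
                name = self.sample_ids[node].replace(" ", "_")
                return f"{name}:{length:.6g}"
            a, b = int(self.merges[node - n][0]), int(self.merges[node - n][1])
            h = heights[node]
            return f"({render(a, h)},{render(b, h)}):{length:.6g}"

        root = n + len(self.merges) - 1
        a, b = int(self.merges[-1][0]), int(self.merges[-1][1])
        h = heights[root]
        return f"({render(a, h)},{render(b, h)});"


def _nearest_neighbor_purity(dist: np.ndarray, labels: list[str]) -> float:
    """Fraction of samples whose nearest neighbor carries the same label."""
    d = dist.copy()
    np.fill_diagonal(d, np.inf)
    nn = np.argmin(d, axis=1)
    return float(np.mean([labels[i] == labels[j] for i, j in enumerate(nn)]))


def ward_cluster(log_matrix: pd.DataFrame, labels: list[str] | None = None) -> ClusteringResult:
    """Ward.D hierarchical clustering of samples on Euclidean distances.

    ``log_matrix`` is genes x samples (log-normalized counts); samples are
    clustered on their pairwise Euclidean distances with the Ward
    Lance-Williams update d(ij,k) = a_i d(i,k) + a_j d(j,k) + b d(i,j),
    a_i = (n_i + n_k)/(n_i + n_j + n_k), b = -n_k/(n_i + n_j + n_k),
    applied to unsquared distances. When ``labels`` (one tissue label per
    sample) are given, a threshold-free purity — nearest-neighbor label
    agreement on the original distances — is reported.
    """
    samples = list(log_matrix.columns)
    n = len(samples)
    if n < 2:
        raise ValueError("clustering needs at least 2 samples")
    if labels is not None and len(labels) != n:
        raise ValueError(f"{len(labels)} labels for {n} samples")
    X = log_matrix.to_numpy(dtype=float).T
    if np.isnan(X).any():
        raise ValueError("log matrix contains missing values")
    dist = squareform(pdist(X, metric="euclidean"))

    purity = None if labels is None else _nearest_neighbor_purity(dist, list(labels))

    # Lance-Williams agglomeration; O(n^3), fine for cohort-sized inputs.
    d = dist.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    active = list(range(n))
    cluster_id = {i: i for i in range(n)}  # row index -> linkage node id
    sizes = {i: 1 for i in range(n)}
    merges = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        sub = d[np.ix_(active, active)]
        flat = np.argmin(sub)
        ai, aj = divmod(flat, len(active))
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        height = d[i, j]
        ni, nj = sizes[i], sizes[j]
        merges[step] = (cluster_id[i], cluster_id[j], height, ni + nj)
        # update distances from the merged cluster (stored in row i) to others
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            s = ni + nj + nk
            d_new = (
                (ni + nk) / s * d[i, k] + (nj + nk) / s * d[j, k] - nk / s * height
            )
            d[i, k] = d[k, i] = d_new
        active.remove(j)
        sizes[i] = ni + nj
        cluster_id[i] = next_id
        next_id += 1

    leaf_order = _leaf_order(merges, n)
    return ClusteringResult(
        merges=merges,
        leaf_order=leaf_order,
        sample_ids=samples,
        labels=None if labels is None else list(labels),
        purity=purity,
    )


def _leaf_order(merges: np.ndarray, n: int) -> list[int]:
    def walk(node: int) -> list[int]:
        if node < n:
            return [node]
        row = merges[node - n]
        return walk(int(row[0])) + walk(int(row[1]))

    return walk(n + len(merges) - 1)


# ---------------------------------------------------------------------------
# replicate concordance

def replicate_concordance(log_matrix: pd.DataFrame, replicate_ids) -> pd.DataFrame:
    """Pairwise Spearman rho over genes between designated replicate columns.

    Returns a symmetric matrix with unit diagonal. Because rho is
    rank-based, the result is identical on normalized and raw counts for
    any per-sample positive scaling.
    """
    ids = list(replicate_ids)
    if len(ids) < 2:
        raise ValueError("replicate group must contain at least 2 columns")
    missing = [c for c in ids if c not in log_matrix.columns]
    if missing:
        raise KeyError(f"replicate columns not in matrix: {missing}")
    from scipy.stats import rankdata

    sub = log_matrix[ids].to_numpy(dtype=float)
    ranks = np.column_stack([rankdata(sub[:, j]) for j in range(sub.shape[1])])
    rho = np.corrcoef(ranks, rowvar=False)
    out = pd.DataFrame(rho, index=ids, columns=ids)
    np.fill_diagonal(out.values, 1.0)
    return out
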