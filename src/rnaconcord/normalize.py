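"""Median-of-ratios size-factor normalization and log transformation.

The estimator: a gene is *reference-eligible* when its count is positive in
every sample. For each such gene i, compute the geometric mean g_i of its
counts across samples; sample j's size factor s_j is the median over
eligible genes of k_ij / g_i. Counts are normalized as k_ij / s_j and
log-transformed as log2(k_ij / s_j + pseudocount).

Size factors are kept as raw medians, not rescaled to unit geometric mean;
every downstream statistic here is rank-based or uses ratios only, so the
overall scale is immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CountMatrix

__all__ = ["NormalizationResult", "NormalizationError", "size_factors", "log_normalize"]


class NormalizationError(ValueError):
    """No reference-eligible gene: every gene has a zero count somewhere."""


@dataclass
class NormalizationResult:
    size_factors: pd.Series
    normalized_counts: pd.DataFrame
    log_counts: pd.DataFrame
    pseudocount: float


def size_factors(matrix: CountMatrix) -> pd.Series:
    """Median-of-ratios size factor per sample.

    Raises :class:`NormalizationError` when no gene has all-positive
    counts; add a pseudocount or filter samples in that case, or fall back
    to library-size scaling if the downstream statistic is rank-based.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    eligible = (counts > 0).all(axis=1)
    if not eligible.any():
        raise NormalizationError(
            "no reference-eligible gene (positive counts in every sample); "
            "consider a pseudocount or gene/sample filtering"
        )
    ref = counts[eligible]
    log_geomeans = np.mean(np.log(ref), axis=1)
    ratios = np.log(ref) - log_geomeans[:, None]
    s = np.exp(np.median(ratios, axis=0))
    return pd.Series(s, index=matrix.counts.columns, name="size_factor")


def log_normalize(matrix: CountMatrix, pseudocount: float = 1.0) -> NormalizationResult:
    """Size-factor-normalize and log2-transform a count matrix."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    s = size_factors(matrix)
    normalized = matrix.counts / s
    log_counts = np.log2(normalized + pseudocount)
    return NormalizationResult(
        size_factors=s,
        normalized_counts=normalized,
        log_counts=log_counts,
        pseudocount=pseudocount,
    )
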