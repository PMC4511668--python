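"""Alpha, beta and gamma diversity of host/sample communities.

All three indices are bounded in [0, 1]:

* **alpha** — mean (and spread) across communities of the scaled
  Shannon-Wiener index ``H = -sum_i p_i ln p_i / ln R``, where ``R`` is either
  the number of taxa observed in that community (``richness_mode="observed"``)
  or a fixed global richness (``richness_mode="global"``);
* **gamma** — the scaled Shannon-Wiener index of the pooled community
  (column sums over all rows, renormalized);
* **beta** — the mean pairwise Bray-Curtis dissimilarity
  ``sum_k |p_ik - p_jk| / 2`` over all unordered pairs of communities.

Input matrices are row-per-community (host or sample) by column-per-taxon and
may hold either counts or relative abundances; rows are normalized internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

__all__ = [
    "DiversityRecord",
    "scaled_shannon",
    "alpha_diversity",
    "gamma_diversity",
    "beta_diversity",
    "pairwise_bray_curtis",
    "detect_stabilization",
]

_SUM_TOL = 1e-6


@dataclass(frozen=True)
class DiversityRecord:
    """Diversity snapshot of one host population at one generation."""

    generation: int
    alpha_mean: float
    alpha_sd: float
    beta: float
    gamma: float


def scaled_shannon(
    rel_abundances: np.ndarray,
    richness_mode: str = "observed",
    global_richness: int | None = None,
) -> float:
    """Scaled Shannon-Wiener index of a single community.

    Zero abundances are skipped (0 ln 0 := 0).  When the effective richness R
    is <= 1 the index is defined as 0 (a single-taxon community carries no
    diversity; the raw formula is 0/0 there).
    """
    p = np.asarray(rel_abundances, dtype=float)
    if p.ndim != 1:
        raise ValueError("rel_abundances must be one-dimensional")
    if (p < 0).any():
        raise ValueError("relative abundances must be non-negative")
    if abs(p.sum() - 1.0) > _SUM_TOL:
        raise ValueError(f"relative abundances must sum to 1, got {p.sum()!r}")
    if richness_mode == "observed":
        richness = int(np.count_nonzero(p))
    elif richness_mode == "global":
        if global_richness is None:
            raise ValueError("global richness_mode requires global_richness")
        richness = int(global_richness)
    else:
        raise ValueError(f"unknown richness_mode {richness_mode!r}")
    if richness <= 1:
        return 0.0
    nz = p[p > 0]
    entropy = -float(np.sum(nz * np.log(nz)))
    return float(min(1.0, max(0.0, entropy / np.log(richness))))


def _normalize_rows(matrix: np.ndarray) -> np.ndarray:
    mat = np.asarray(matrix, dtype=float)
    if mat.ndim != 2:
        raise ValueError("expected a 2-D community matrix")
    if mat.shape[0] < 1:
        raise ValueError("community matrix must have at least one row")
    if (mat < 0).any():
        raise ValueError("community matrix must be non-negative")
    totals = mat.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("every community (row) must have positive total abundance")
    return mat / totals


def alpha_diversity(
    counts_or_table: np.ndarray,
    richness_mode: str = "observed",
    global_richness: int | None = None,
) -> tuple[float, float]:
    """Mean and standard deviation of per-row scaled Shannon indices.

    The spread is the sample standard deviation (ddof=1); a single row gives
    sd = 0.
    """
    rel = _normalize_rows(counts_or_table)
    values = np.array(
        [scaled_shannon(row, richness_mode, global_richness) for row in rel]
    )
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return float(values.mean()), sd


def gamma_diversity(
    counts_or_table: np.ndarray,
    richness_mode: str = "observed",
    global_richness: int | None = None,
) -> float:
    """Scaled Shannon index of the pooled (column-summed) community."""
    mat = np.asarray(counts_or_table, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 1:
        raise ValueError("expected a non-empty 2-D community matrix")
    pooled = mat.sum(axis=0)
    total = pooled.sum()
    if total <= 0:
        raise ValueError("pooled community has zero total abundance")
    return scaled_shannon(pooled / total, richness_mode, global_richness)


def pairwise_bray_curtis(counts_or_table: np.ndarray) -> np.ndarray:
    """Condensed vector of Bray-Curtis dissimilarities over all row pairs.

    For row-normalized relative abundances, Bray-Curtis reduces to half the
    L1 (city-block) distance.
    """
    rel = _normalize_rows(counts_or_table)
    if rel.shape[0] < 2:
        raise ValueError("Bray-Curtis requires at least two communities")
    return pdist(rel, metric="cityblock") / 2.0


def beta_diversity(counts_or_table: np.ndarray) -> float:
    """Mean pairwise Bray-Curtis dissimilarity across all unordered pairs.

    Raises ValueError for fewer than two rows: a single community has no
    between-community dissimilarity (undefined, not zero).
    """
    return float(pairwise_bray_curtis(counts_or_table).mean())


def detect_stabilization(
    gamma_series, window: int, tolerance: float, eps: float = 1e-12
) -> bool:
    """True once the gamma trajectory has flattened.

    Compares the means of the last two non-overlapping windows of recorded
    values; the series is stable when their relative difference (against the
    earlier window's mean, floored at ``eps``) drops below ``tolerance``.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    series = np.asarray(gamma_series, dtype=float)
    if series.size < 2 * window:
        return False
    prev = float(series[-2 * window : -window].mean())
    last = float(series[-window:].mean())
    return abs(last - prev) / max(prev, eps) < tolerance
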