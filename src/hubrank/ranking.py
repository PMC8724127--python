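"""Rank vectors, Spearman correlation of rankings, and the hubness score.

The node-level comparison currency of the whole package is the *ranking
vector*: nodes are ranked within each connectome by a graph measure, rank 1
being the best (largest measure value), ties receiving the average of the
ranks they span.  Example: degree values (50, 20, 30, 40, 10) rank as
(1, 4, 3, 2, 5).

Two ranking vectors are compared with Spearman's rank correlation

    rho = 1 - 6 * sum(d_i^2) / (n * (n^2 - 1))

where d_i is the per-node rank difference.  The closed form is exact only
without ties; with ties we use the product-moment correlation of the two rank
vectors, which coincides with the closed form in the tie-free case.

The composite *hubness* score of a node is the arithmetic mean of its ranks
under the five measures (degree, strength, coreness, betweenness, closeness);
lower score = more hub-like.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["rank_vector", "spearman", "hubness", "MEASURES"]

#: The five node-level graph measures entering the composite hubness score.
MEASURES = ("degree", "strength", "coreness", "betweenness", "closeness")


def rank_vector(values, descending: bool = True) -> np.ndarray:
    """Rank values so that rank 1 is the top; ties get fractional (mean) ranks.

    Parameters
    ----------
    values
        Per-node measure values; must be non-empty and free of NaN.
    descending
        If True (default) the largest value receives rank 1 (the convention
        for graph measures); if False the smallest does (the convention for
        hubness scores, where low mean rank = hub).

    Returns
    -------
    ndarray of float ranks summing to n(n+1)/2.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("values must be a non-empty 1-D array")
    if np.any(np.isnan(v)):
        raise ValueError("values contain NaN; ranks are undefined")
    return rankdata(-v if descending else v, method="average")


def spearman(r1, r2) -> float:
    """Spearman rank correlation between two rankings (or score vectors).

    Both inputs are (re-)ranked ascending internally, so score vectors such
    as mean-of-ranks group scores are handled identically to proper rank
    vectors.  Tie-free inputs reproduce the closed form
    ``1 - 6*sum(d^2)/(n(n^2-1))`` exactly.  Returns NaN when either input is
    constant (correlation undefined).
    """
    a = np.asarray(r1, dtype=float)
    b = np.asarray(r2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"rankings must be 1-D and equal length, got {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least two observations")
    ra = rankdata(a, method="average")
    rb = rankdata(b, method="average")
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    denom = np.sqrt((ra**2).sum() * (rb**2).sum())
    if denom == 0:
        return float("nan")
    return float(np.clip((ra * rb).sum() / denom, -1.0, 1.0))


def hubness(
    measures: pd.DataFrame, weights: dict[str, float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Composite hubness from a per-node measure table.

    Parameters
    ----------
    measures
        DataFrame with the five measure columns (see :data:`MEASURES`),
        one row per node.
    weights
        Optional per-measure weights for sensitivity analyses; default is
        equal weighting (the plain mean of the five ranks).

    Returns
    -------
    (hubness_score, hubness_ranking)
        ``hubness_score[i]`` is the (weighted) mean of node i's five measure
        ranks (lower = more hub-like); ``hubness_ranking`` ranks the scores
        ascending, so the node with the smallest score has rank 1.
    """
    missing = [m for m in MEASURES if m not in measures.columns]
    if missing:
        raise ValueError(f"measure table missing columns {missing}")
    if weights is None:
        weights = {m: 1.0 for m in MEASURES}
    wsum = sum(weights[m] for m in MEASURES)
    ranks = np.column_stack([rank_vector(measures[m].to_numpy()) for m in MEASURES])
    wvec = np.array([weights[m] for m in MEASURES], dtype=float)
    score = (ranks * wvec).sum(axis=1) / wsum
    return score, rank_vector(score, descending=False)
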