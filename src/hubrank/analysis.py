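"""Downstream group-level experiments on connectome populations.

Four analyses built on the MTA group hubness ranking:

- sample-size curves: how well the hubness ranking of a random subject
  sample correlates with the full population's, as a function of sample size;
- consistent hubs: ROIs in the best quantile of the group ranking for *all
  five* measures simultaneously;
- hemispheric asymmetry: paired comparison of homologous parcels' median
  ROI hubness ranks across subjects, with a significance test and a margin;
- intraparcel heterogeneity: spread of group-level ROI ranks within parcels.

Parcel-level values are the median of the parcel's ROI hubness ranks, since
sub-parcellation does not align ROIs across hemispheres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .aggregation import SubjectPopulation, aggregate_mta
from .ranking import MEASURES, spearman

__all__ = [
    "SampleSizeCurve",
    "AsymmetryReport",
    "HeterogeneityReport",
    "sample_size_curve",
    "top_consistent_hubs",
    "parcel_rank_table",
    "homolog_pairs_from_nodes",
    "hemispheric_asymmetry",
    "interhemispheric_correlation",
    "intraparcel_heterogeneity",
]

#: Default sample-size grid for representation-power-vs-n experiments.
DEFAULT_SIZES = (1, 2, 5, 10, 20, 50, 100, 200, 500, 1000)


@dataclass
class SampleSizeCurve:
    """Replicate correlations of sample-averaged vs population hubness ranking."""

    sizes: list[int]
    correlations: dict[int, np.ndarray]  # size -> per-replicate Spearman
    seed: int

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "n_s": s,
                "mean": float(np.mean(self.correlations[s])),
                "min": float(np.min(self.correlations[s])),
                "max": float(np.max(self.correlations[s])),
                "n_replicates": len(self.correlations[s]),
            }
            for s in self.sizes
        ]
        return pd.DataFrame(rows)

    def long_frame(self) -> pd.DataFrame:
        """Plot-ready long format: one row per (size, replicate)."""
        return pd.DataFrame(
            [
                {"n_s": s, "replicate": r, "spearman": c}
                for s in self.sizes
                for r, c in enumerate(self.correlations[s])
            ]
        )


def sample_size_curve(
    pop: SubjectPopulation,
    sizes: Sequence[int] | None = None,
    n_replicates: int = 100,
    seed: int = 0,
) -> SampleSizeCurve:
    """Correlation of sample-averaged with population-averaged hubness ranking.

    For each sample size, ``n_replicates`` subject samples are drawn without
    replacement (independently across replicates); each sample's MTA hubness
    ranking is correlated (Spearman) with the full population's.  Sizes
    default to the standard grid truncated at the population size.
    """
    n = pop.n_subjects
    if sizes is None:
        sizes = [s for s in DEFAULT_SIZES if s <= n]
        if not sizes or sizes[-1] != n:
            sizes.append(n)
    sizes = list(sizes)
    if any(s < 1 or s > n for s in sizes):
        raise ValueError(f"sample sizes must be in 1..{n}")
    ranks = pop.subject_ranks("hubness")  # (S, N); MTA score = mean over subjects
    pop_score = ranks.mean(axis=0)
    rng = np.random.default_rng(seed)
    correlations = {}
    for s in sizes:
        corrs = np.empty(n_replicates)
        for r in range(n_replicates):
            idx = rng.choice(n, size=s, replace=False)
            corrs[r] = spearman(ranks[idx].mean(axis=0), pop_score)
        correlations[s] = corrs
    return SampleSizeCurve(sizes, correlations, seed)


def top_consistent_hubs(
    pop: SubjectPopulation,
    quantile: float = 0.20,
    node_table: pd.DataFrame | None = None,
) -> dict:
    """ROIs in the best ``quantile`` of the MTA group ranking for all five measures.

    The per-measure top set contains the ``floor(quantile * n)`` best-scoring
    nodes (ties at the threshold score included); the hub set is the
    intersection over the five measures.  If ``node_table`` (with
    ``roi_id``/``hemisphere`` columns) is given, per-hemisphere counts are
    tallied.
    """
    if not 0 <= quantile <= 1:
        raise ValueError("quantile must be in [0, 1]")
    n = pop.n_nodes
    k = int(quantile * n)
    per_measure: dict[str, set] = {}
    for m in MEASURES:
        score = aggregate_mta(pop, m).score
        if k == 0:
            per_measure[m] = set()
            continue
        threshold = np.sort(score)[k - 1]
        per_measure[m] = {
            node for node, s in zip(pop.node_ids, score) if s <= threshold
        }
    hubs = set.intersection(*per_measure.values()) if per_measure else set()
    result = {
        "hub_rois": sorted(hubs),
        "per_measure_top": {m: sorted(v) for m, v in per_measure.items()},
        "quantile": quantile,
    }
    if node_table is not None:
        hemi = node_table.set_index("roi_id")["hemisphere"]
        counts = hemi.loc[sorted(hubs)].value_counts().to_dict() if hubs else {}
        result["hemisphere_counts"] = {h: int(counts.get(h, 0)) for h in ("L", "R")}
    return result


def parcel_rank_table(pop: SubjectPopulation, node_table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-parcel median ROI hubness ranks.

    ``node_table`` maps roi_id -> (parcel_id, hemisphere); each parcel
    instance (one hemisphere of one parcel) becomes a column named
    ``{parcel_id}_{hemisphere}`` whose value for a subject is the median of
    the subject's hubness ranks over the parcel's ROIs.  The even-count
    median is the midpoint of the two central values.
    """
    required = {"roi_id", "parcel_id", "hemisphere"}
    if not required <= set(node_table.columns):
        raise ValueError(f"node_table must have columns {sorted(required)}")
    lookup = node_table.set_index("roi_id")
    missing = [n for n in pop.node_ids if n not in lookup.index]
    if missing:
        raise ValueError(f"ROIs without a parcel assignment: {missing[:10]}")
    ranks = pop.subject_ranks("hubness")
    keys = [
        f"{lookup.loc[n, 'parcel_id']}_{lookup.loc[n, 'hemisphere']}"
        for n in pop.node_ids
    ]
    frame = pd.DataFrame(ranks, index=pop.subject_ids, columns=keys)
    return frame.T.groupby(level=0).median().T


def homolog_pairs_from_nodes(node_table: pd.DataFrame) -> list[tuple[str, str, str]]:
    """(parcel_id, left_column, right_column) triples for a synthetic node table."""
    pairs = []
    for pid in node_table["parcel_id"].drop_duplicates():
        sub = node_table[node_table["parcel_id"] == pid]
        if {"L", "R"} <= set(sub["hemisphere"]):
            pairs.append((pid, f"{pid}_L", f"{pid}_R"))
    return pairs


@dataclass
class AsymmetryReport:
    """Per homologous parcel pair: effect, p-value, and dominance class."""

    table: pd.DataFrame  # parcel_id, mean_diff, p_value, classification
    margin: float
    alpha: float
    n_units: int
    counts: dict = field(init=False)

    def __post_init__(self) -> None:
        c = self.table["classification"].value_counts().to_dict()
        self.counts = {
            k: int(c.get(k, 0)) for k in ("left-dominant", "right-dominant", "symmetric")
        }


def hemispheric_asymmetry(
    table: pd.DataFrame,
    pairs: Iterable[tuple[str, str, str]],
    margin: float = 0.05,
    alpha: float = 0.01,
    n_units: int | None = None,
    test: str = "wilcoxon",
) -> AsymmetryReport:
    """Classify homologous parcel pairs as left-dominant, right-dominant or symmetric.

    Parameters
    ----------
    table
        Subject-by-parcel rank table (e.g. from :func:`parcel_rank_table`):
        values are median ROI hubness ranks, lower = more hub-like.
    pairs
        Iterable of (parcel_id, left_column, right_column).
    margin
        Acceptable population-level rank difference as a fraction of
        ``n_units``; a pair is dominant only if |mean(left - right)| exceeds
        ``margin * n_units``.
    alpha
        Two-sided significance level of the paired test.
    n_units
        Total number of ranked units the table's values live on (node count
        for ROI-rank medians).  Defaults to the rounded maximum table value,
        a lower bound on the true scale.
    test
        ``"wilcoxon"`` (paired signed-rank; exact for small samples without
        ties) or ``"ttest"`` (paired t).

    Lower ranks are better, so a significantly negative mean (left - right)
    difference means left dominance.
    """
    n_subjects = len(table)
    if n_subjects < 6:
        raise ValueError("need at least 6 subjects for the paired test at alpha 0.01")
    if test not in ("wilcoxon", "ttest"):
        raise ValueError("test must be 'wilcoxon' or 'ttest'")
    if n_units is None:
        n_units = int(round(float(table.to_numpy().max())))
    threshold = margin * n_units
    rows = []
    for parcel_id, left, right in pairs:
        if left not in table.columns or right not in table.columns:
            warnings.warn(f"parcel {parcel_id}: missing column, pair skipped", stacklevel=2)
            continue
        d = (table[left] - table[right]).to_numpy(dtype=float)
        mean_diff = float(d.mean())
        nonzero = d[d != 0]
        if len(nonzero) == 0:
            p = 1.0
        elif test == "wilcoxon":
            p = float(stats.wilcoxon(nonzero, alternative="two-sided", method="auto").pvalue)
        else:
            p = float(stats.ttest_rel(table[left], table[right]).pvalue)
        if p < alpha and abs(mean_diff) > threshold:
            cls = "left-dominant" if mean_diff < 0 else "right-dominant"
        else:
            cls = "symmetric"
        rows.append(
            {"parcel_id": parcel_id, "mean_diff": mean_diff, "p_value": p,
             "classification": cls}
        )
    return AsymmetryReport(pd.DataFrame(rows), margin, alpha, n_units)


def interhemispheric_correlation(left, right) -> float:
    """Spearman correlation between left and right group-level parcel ranks."""
    return spearman(np.asarray(left, dtype=float), np.asarray(right, dtype=float))


@dataclass
class HeterogeneityReport:
    """Within-parcel spread of group-level ROI hubness ranks."""

    table: pd.DataFrame  # parcel column, n_rois, min/max/median/iqr
    rank_spread_correlation: float
    rank_asymmetry_correlation: float | None = None


def intraparcel_heterogeneity(
    group_score: np.ndarray,
    node_table: pd.DataFrame,
    node_ids: np.ndarray | None = None,
    asymmetry: AsymmetryReport | None = None,
) -> HeterogeneityReport:
    """Spread statistics of group-level ROI hubness ranks within each parcel.

    ``group_score`` is a per-node group hubness rank score (e.g. the MTA
    score); one report row per parcel instance with min, max, median and
    interquartile range of its ROIs' scores (IQR 0 for single-ROI parcels).
    Also reported: Spearman between parcel median rank and parcel spread
    (IQR), and - when an :class:`AsymmetryReport` is supplied - between
    parcel median rank and asymmetry magnitude |mean_diff|.
    """
    lookup = node_table.set_index("roi_id")
    if node_ids is None:
        node_ids = lookup.index.to_numpy()
    score = pd.Series(np.asarray(group_score, dtype=float), index=node_ids)
    keys = pd.Series(
        [f"{lookup.loc[n, 'parcel_id']}_{lookup.loc[n, 'hemisphere']}" for n in node_ids],
        index=node_ids,
    )
    rows = []
    for parcel, members in score.groupby(keys):
        v = members.to_numpy()
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append(
            {"parcel": parcel, "n_rois": len(v), "min": v.min(), "max": v.max(),
             "median": med, "iqr": q3 - q1}
        )
    report = pd.DataFrame(rows)
    spread_corr = spearman(report["median"], report["iqr"]) if len(report) > 1 else float("nan")
    asym_corr = None
    if asymmetry is not None:
        mag = asymmetry.table.set_index("parcel_id")["mean_diff"].abs()
        med = (
            report.assign(parcel_id=report["parcel"].str.rsplit("_", n=1).str[0])
            .groupby("parcel_id")["median"].median()
        )
        common = mag.index.intersection(med.index)
        if len(common) > 1:
            asym_corr = spearman(med.loc[common], mag.loc[common])
    return HeterogeneityReport(report, spread_corr, asym_corr)
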