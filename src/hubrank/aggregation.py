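"""Group-level aggregation of subject connectomes: ATM vs MTA.

Two strategies turn a population of subject connectomes into one group-level
node ranking for a measure:

- ATM (aggregate-then-measure): average the weighted matrices elementwise,
  compute the measure on the aggregate connectome, rank.
- MTA (measure-then-aggregate): compute the measure and rank the nodes
  within each subject first, then average each node's rank across subjects.
  The group score is kept as the raw mean of ranks (not re-ranked): Spearman
  comparisons are invariant to the monotone re-ranking except under ties,
  so the raw mean is the more informative score.

*Representation power* of a group ranking is its mean Spearman correlation
with the individual subjects' own rankings; it is the yardstick by which the
two strategies are compared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .measures import measure_all
from .network import ConnectivityMatrix
from .ranking import MEASURES, hubness, rank_vector, spearman

__all__ = [
    "SubjectPopulation",
    "GroupRanking",
    "RepresentationPower",
    "aggregate_atm",
    "aggregate_mta",
    "representation_power",
    "measure_intercorrelation",
    "GROUP_MEASURES",
]

#: Measures accepted by the aggregation API: the five plus the composite.
GROUP_MEASURES = MEASURES + ("hubness",)


class SubjectPopulation:
    """Ordered collection of subject connectomes over one shared node index.

    Per-subject measure values and rank vectors are computed lazily and
    cached, so repeated aggregation calls (e.g. MTA for several measures,
    representation power, sample-size resampling) do each graph computation
    once per subject.
    """

    def __init__(self, matrices, node_ids=None, subject_ids=None):
        mats = []
        for m in matrices:
            if isinstance(m, ConnectivityMatrix):
                if node_ids is not None and not np.array_equal(m.node_ids, node_ids):
                    raise ValueError("subject matrix node index mismatch")
                node_ids = m.node_ids
                mats.append(m.weights)
            else:
                mats.append(np.asarray(m, dtype=float))
        if not mats:
            raise ValueError("population must contain at least one subject")
        self.weights = np.stack(mats)  # (S, N, N)
        n = self.weights.shape[1]
        if self.weights.shape[2] != n:
            raise ValueError("subject matrices must be square")
        self.node_ids = np.arange(n) if node_ids is None else np.asarray(node_ids)
        if len(self.node_ids) != n:
            raise ValueError("node_ids length does not match matrix size")
        self.subject_ids = (
            [f"subject_{i:04d}" for i in range(len(mats))]
            if subject_ids is None
            else list(subject_ids)
        )
        if len(self.subject_ids) != len(mats):
            raise ValueError("subject_ids length does not match population size")
        # validate via the ConnectivityMatrix invariants
        for i in range(self.n_subjects):
            ConnectivityMatrix(self.weights[i], self.node_ids)
        self._values: dict[str, np.ndarray] = {}
        self._ranks: dict[str, np.ndarray] = {}

    @property
    def n_subjects(self) -> int:
        return self.weights.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[1]

    def matrix(self, i: int) -> ConnectivityMatrix:
        return ConnectivityMatrix(self.weights[i], self.node_ids)

    def mean_matrix(self) -> ConnectivityMatrix:
        return ConnectivityMatrix(self.weights.mean(axis=0), self.node_ids)

    def _compute_values(self) -> None:
        if self._values:
            return
        per_measure = {m: np.empty((self.n_subjects, self.n_nodes)) for m in MEASURES}
        for i in range(self.n_subjects):
            table = measure_all(self.matrix(i))
            for m in MEASURES:
                per_measure[m][i] = table[m].to_numpy()
        self._values = per_measure

    def subject_values(self, measure: str) -> np.ndarray:
        """(n_subjects, n_nodes) raw values of one of the five measures."""
        if measure not in MEASURES:
            raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
        self._compute_values()
        return self._values[measure]

    def subject_ranks(self, measure: str) -> np.ndarray:
        """(n_subjects, n_nodes) within-subject rank vectors (1 = top).

        ``measure='hubness'`` yields each subject's composite hubness
        ranking (mean of the subject's five measure ranks, ranked ascending).
        """
        if measure in self._ranks:
            return self._ranks[measure]
        if measure == "hubness":
            score = np.mean(
                [self.subject_ranks(m) for m in MEASURES], axis=0
            )  # (S, N) mean-of-ranks, lower = hub
            ranks = np.vstack(
                [rank_vector(score[i], descending=False) for i in range(self.n_subjects)]
            )
        elif measure in MEASURES:
            values = self.subject_values(measure)
            ranks = np.vstack(
                [rank_vector(values[i]) for i in range(self.n_subjects)]
            )
        else:
            raise ValueError(
                f"unknown measure {measure!r}; expected one of {GROUP_MEASURES}"
            )
        self._ranks[measure] = ranks
        return ranks


@dataclass
class GroupRanking:
    """Group-level rank score per node (lower = better) for one measure."""

    method: str  # "ATM" or "MTA"
    measure: str
    score: np.ndarray
    node_ids: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"group_rank_score": self.score},
            index=pd.Index(self.node_ids, name="roi_id"),
        )


@dataclass
class RepresentationPower:
    """Spearman correlations of a group ranking with each subject's own."""

    method: str
    measure: str
    correlations: np.ndarray
    mean: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean = float(np.mean(self.correlations))


def _aggregate_measure_table(table: pd.DataFrame, measure: str) -> np.ndarray:
    if measure == "hubness":
        score, _ = hubness(table)
        return rank_vector(score, descending=False)
    return rank_vector(table[measure].to_numpy())


def aggregate_atm(
    pop: SubjectPopulation, measure: str, prevalence: float | None = None
) -> GroupRanking:
    """Aggregate-then-measure: rank the measure on the mean connectome.

    Parameters
    ----------
    pop, measure
        Population and one of :data:`GROUP_MEASURES`.
    prevalence
        Optional edge-prevalence threshold in (0, 1]: keep an aggregate edge
        only if it is present in at least this fraction of subjects.  The
        default (None) keeps every edge with positive mean weight, i.e. the
        union graph, which is the literal aggregate-binarization rule but
        densifies with population size.
    """
    if measure not in GROUP_MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {GROUP_MEASURES}")
    mean_w = pop.weights.mean(axis=0)
    if prevalence is not None:
        if not 0 < prevalence <= 1:
            raise ValueError("prevalence must be in (0, 1]")
        frac = (pop.weights > 0).mean(axis=0)
        mean_w = np.where(frac >= prevalence, mean_w, 0.0)
    table = measure_all(ConnectivityMatrix(mean_w, pop.node_ids))
    return GroupRanking("ATM", measure, _aggregate_measure_table(table, measure), pop.node_ids)


def aggregate_mta(pop: SubjectPopulation, measure: str) -> GroupRanking:
    """Measure-then-aggregate: mean of within-subject ranks per node."""
    if measure not in GROUP_MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {GROUP_MEASURES}")
    score = pop.subject_ranks(measure).mean(axis=0)
    return GroupRanking("MTA", measure, score, pop.node_ids)


def representation_power(
    group: GroupRanking, pop: SubjectPopulation, measure: str | None = None
) -> RepresentationPower:
    """Mean Spearman correlation of a group ranking with each subject's own."""
    measure = group.measure if measure is None else measure
    if len(group.score) != pop.n_nodes or not np.array_equal(group.node_ids, pop.node_ids):
        raise ValueError("group ranking and population node indices differ")
    subject_ranks = pop.subject_ranks(measure)
    corrs = np.array(
        [spearman(group.score, subject_ranks[i]) for i in range(pop.n_subjects)]
    )
    # a constant ranking (e.g. the aggregate union graph making coreness
    # uniform) carries no node-ordering information: score it 0, not NaN
    if np.any(~np.isfinite(corrs)):
        warnings.warn(
            f"{group.method}/{measure}: degenerate (constant) ranking in "
            "correlation; representation power recorded as 0",
            stacklevel=2,
        )
        corrs = np.where(np.isfinite(corrs), corrs, 0.0)
    return RepresentationPower(group.method, measure, corrs)


def measure_intercorrelation(pop: SubjectPopulation) -> pd.DataFrame:
    """Pairwise Spearman correlations of the six MTA group rankings.

    Rows/columns are the five measures plus hubness; entries are Spearman
    correlations between the corresponding group-level rank score vectors.
    """
    scores = {m: aggregate_mta(pop, m).score for m in GROUP_MEASURES}
    names = list(GROUP_MEASURES)
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            r = spearman(scores[a], scores[b])
            out.loc[a, b] = out.loc[b, a] = r
    return out
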