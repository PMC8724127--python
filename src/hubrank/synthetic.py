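"""Synthetic connectome populations with known ground truth.

Real tractography-derived populations are too large to ship, so every
downstream stage is exercised on generated data whose hub architecture,
hemispheric asymmetry, and intraparcel heterogeneity are planted and
therefore recoverable.

The generative model:

- A *base connectome* on ``2 * n_parcels_per_hemisphere * rois_per_parcel``
  nodes: a stochastic block structure with one block per parcel (higher
  in-block density), mirror-symmetric across hemispheres so that homologous
  nodes are statistically identical unless asymmetry is injected.
- A designated fraction of nodes are *hubs*: their incident edge probability
  and edge weights are multiplied by ``hub_weight_boost``.  Hubs are chosen
  in the left hemisphere and mirrored, preserving hemispheric symmetry.
- Optional *asymmetry*: left-hemisphere nodes of selected parcels have their
  incident weights scaled by a factor delta.
- Optional *heterogeneity*: a linear within-parcel gradient of expected node
  strength and connectivity (node gain ``1 + slope * (position - 1/2)`` with
  position in [0, 1], applied to both edge probability and weight), mirrored
  across hemispheres so the gradient itself is symmetric.
- Each subject's matrix is the base times i.i.d. elementwise lognormal
  multiplicative weight noise, after which each node pair's edge presence is
  independently toggled with probability ``edge_flip_prob`` (new edges drawn
  at the base weight scale).

With zero noise and zero flip probability every subject equals the base
exactly; all randomness flows from a single seed through per-subject
substreams, so populations are bitwise reproducible.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregation import SubjectPopulation
from .network import ConnectivityMatrix

__all__ = [
    "PopulationSpec",
    "GeneratedPopulation",
    "generate_population",
    "generate_label_volume",
    "generate_streamlines",
    "generate_parcel_rank_table",
]

#: Log-scale spread of base edge weights (and of replacement edges after a flip).
BASE_WEIGHT_SIGMA = 0.5
#: In-block (within-parcel) density multiplier relative to ``base_density``.
WITHIN_PARCEL_DENSITY_FACTOR = 3.0
#: Interhemispheric density multiplier relative to ``base_density``.
CROSS_HEMISPHERE_DENSITY_FACTOR = 0.5


@dataclass
class PopulationSpec:
    """Parameters of a synthetic connectome population.

    Defaults describe the standard test-bed: 50 subjects, 200 nodes
    (25 parcels per hemisphere, 4 ROIs each), 10% edge density, 10% of nodes
    boosted threefold as hubs, lognormal weight noise sigma 0.5 and a 5%
    per-pair edge flip probability for inter-subject variability.
    """

    n_subjects: int = 50
    n_parcels_per_hemisphere: int = 25
    rois_per_parcel: int = 4
    base_density: float = 0.1
    hub_fraction: float = 0.1
    hub_weight_boost: float = 3.0
    weight_noise_sigma: float = 0.5
    edge_flip_prob: float = 0.05
    asymmetry_effects: Mapping[str, float] = field(default_factory=dict)
    heterogeneity_slope: float | Mapping[str, float] = 0.0
    seed: int = 0

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_parcels_per_hemisphere * self.rois_per_parcel

    def parcel_ids(self) -> list[str]:
        return [f"P{p:03d}" for p in range(self.n_parcels_per_hemisphere)]

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_parcels_per_hemisphere < 1:
            raise ValueError("n_parcels_per_hemisphere must be >= 1")
        if self.rois_per_parcel < 1:
            raise ValueError("rois_per_parcel must be >= 1")
        if not 0 < self.base_density <= 1:
            raise ValueError("base_density must be in (0, 1]")
        if not 0 <= self.hub_fraction <= 1:
            raise ValueError("hub_fraction must be in [0, 1]")
        if self.hub_weight_boost < 1:
            raise ValueError("hub_weight_boost must be >= 1")
        if self.weight_noise_sigma < 0:
            raise ValueError("weight_noise_sigma must be >= 0")
        if not 0 <= self.edge_flip_prob < 1:
            raise ValueError("edge_flip_prob must be in [0, 1)")
        known = set(self.parcel_ids())
        for parcel, delta in self.asymmetry_effects.items():
            if parcel not in known:
                raise ValueError(f"asymmetry_effects refers to unknown parcel {parcel!r}")
            if delta <= 0:
                raise ValueError(f"asymmetry_effects[{parcel!r}] must be > 0")
        for parcel, slope in self._slope_map().items():
            if parcel not in known:
                raise ValueError(f"heterogeneity_slope refers to unknown parcel {parcel!r}")
            if abs(slope) >= 2.0:  # centered gradient: gains 1 +/- slope/2 must stay > 0
                raise ValueError(f"heterogeneity_slope for {parcel!r} must satisfy |slope| < 2")

    def _slope_map(self) -> dict[str, float]:
        if isinstance(self.heterogeneity_slope, Mapping):
            return dict(self.heterogeneity_slope)
        return {p: float(self.heterogeneity_slope) for p in self.parcel_ids()}


@dataclass
class GeneratedPopulation:
    """A generated population plus the ground truth that was planted."""

    spec: PopulationSpec
    base_matrix: ConnectivityMatrix
    population: SubjectPopulation
    node_table: pd.DataFrame  # roi_id, parcel_id, hemisphere, roi_in_parcel
    hub_nodes: np.ndarray

    @property
    def ground_truth(self) -> dict:
        return {
            "hub_nodes": [int(i) for i in self.hub_nodes],
            "asymmetric_parcels": dict(self.spec.asymmetry_effects),
            "heterogeneous_parcels": {
                p: s for p, s in self.spec._slope_map().items() if s != 0.0
            },
            "spec": {
                k: (dict(v) if isinstance(v, Mapping) else v)
                for k, v in vars(self.spec).items()
            },
        }


def _node_table(spec: PopulationSpec) -> pd.DataFrame:
    rows = []
    roi = 0
    for hemi in ("L", "R"):
        for parcel in spec.parcel_ids():
            for r in range(spec.rois_per_parcel):
                rows.append((roi, parcel, hemi, r))
                roi += 1
    return pd.DataFrame(rows, columns=["roi_id", "parcel_id", "hemisphere", "roi_in_parcel"])


def generate_population(spec: PopulationSpec) -> GeneratedPopulation:
    """Draw a subject population from the generative model (see module docs)."""
    spec.validate()
    nodes = _node_table(spec)
    n = spec.n_nodes
    half = n // 2
    rng_streams = np.random.SeedSequence(spec.seed).spawn(spec.n_subjects + 1)
    base_rng = np.random.default_rng(rng_streams[0])

    # --- base structure on the left hemisphere, mirrored to the right ---
    parcel_idx = nodes["parcel_id"].iloc[:half].to_numpy()
    same_parcel = parcel_idx[:, None] == parcel_idx[None, :]
    p_within = min(1.0, WITHIN_PARCEL_DENSITY_FACTOR * spec.base_density)
    prob_ll = np.where(same_parcel, p_within, spec.base_density)
    prob_lr = np.full((half, half), CROSS_HEMISPHERE_DENSITY_FACTOR * spec.base_density)

    n_hubs = int(round(spec.hub_fraction * n))
    left_hubs = np.sort(base_rng.choice(half, size=n_hubs // 2 + n_hubs % 2, replace=False))
    hub_nodes = np.sort(np.concatenate([left_hubs, left_hubs[: n_hubs // 2] + half]))
    hub_left = np.zeros(half, dtype=bool)
    hub_left[left_hubs] = True
    hub_pair_ll = hub_left[:, None] | hub_left[None, :]
    boost_ll = np.where(hub_pair_ll, spec.hub_weight_boost, 1.0)
    boost_lr = boost_ll  # mirrored hubs: same pattern interhemispherically

    # within-parcel gradients scale both expected weight and edge probability,
    # so the planted strength gradient is visible in the binary measures too
    slopes = spec._slope_map()
    gain = np.ones(n)
    if any(s != 0.0 for s in slopes.values()):
        denom = max(spec.rois_per_parcel - 1, 1)
        for _, row in nodes.iterrows():
            s = slopes.get(row["parcel_id"], 0.0)
            # centered: the parcel spans below- and above-average strength
            gain[row["roi_id"]] = 1.0 + s * (row["roi_in_parcel"] / denom - 0.5)
    gain_half = gain[:half]  # mirror symmetry: right gains equal left gains
    gain_outer = gain_half[:, None] * gain_half[None, :]

    prob_ll = np.minimum(1.0, prob_ll * boost_ll * gain_outer)
    prob_lr = np.minimum(1.0, prob_lr * boost_lr * gain_outer)

    def _sym_draw(prob, rng, hollow):
        """Symmetric Bernoulli draw from an upper-triangular probability field."""
        m = prob.shape[0]
        u = rng.random((m, m))
        upper = np.triu(u < prob, k=1)
        out = upper | upper.T
        if not hollow:
            diag = np.diag(u) < np.diag(prob)
            out[np.diag_indices(m)] = diag
        return out

    adj_ll = _sym_draw(prob_ll, base_rng, hollow=True)
    adj_lr = _sym_draw(prob_lr, base_rng, hollow=False)  # i_L-i_R homotopic edges allowed

    w_ll = np.triu(base_rng.lognormal(0.0, BASE_WEIGHT_SIGMA, (half, half)), 1)
    w_ll = (w_ll + w_ll.T) * adj_ll * boost_ll
    w_lr_raw = base_rng.lognormal(0.0, BASE_WEIGHT_SIGMA, (half, half))
    w_lr = (np.triu(w_lr_raw) + np.triu(w_lr_raw, 1).T) * adj_lr * boost_lr

    base = np.zeros((n, n))
    base[:half, :half] = w_ll
    base[half:, half:] = w_ll  # mirror symmetry: right-right copies left-left
    base[:half, half:] = w_lr  # symmetric cross block keeps homologs identical
    base[half:, :half] = w_lr.T

    # --- planted asymmetry and within-parcel gradients ---
    delta = np.ones(n)
    for parcel, d in spec.asymmetry_effects.items():
        mask = (nodes["parcel_id"] == parcel) & (nodes["hemisphere"] == "L")
        delta[mask.to_numpy()] = d
    if np.any(delta != 1.0):
        logd = np.log(delta)
        # scale each edge once, by the endpoint deviating most from 1
        pick = np.where(np.abs(logd[:, None]) >= np.abs(logd[None, :]),
                        delta[:, None], delta[None, :])
        base = base * pick

    if np.any(gain != 1.0):
        base = base * gain[:, None] * gain[None, :]

    np.fill_diagonal(base, 0.0)
    base_matrix = ConnectivityMatrix(base, nodes["roi_id"].to_numpy())

    # --- subject-level noise ---
    iu = np.triu_indices(n, k=1)
    base_upper = base[iu]
    subjects = np.empty((spec.n_subjects, n, n))
    for s in range(spec.n_subjects):
        rng = np.random.default_rng(rng_streams[s + 1])
        w = base_upper * rng.lognormal(0.0, spec.weight_noise_sigma, base_upper.shape)
        if spec.edge_flip_prob > 0:
            flip = rng.random(base_upper.shape) < spec.edge_flip_prob
            new_w = rng.lognormal(0.0, BASE_WEIGHT_SIGMA, base_upper.shape)
            w = np.where(flip, np.where(w > 0, 0.0, new_w), w)
        mat = np.zeros((n, n))
        mat[iu] = w
        subjects[s] = mat + mat.T
    population = SubjectPopulation(subjects, node_ids=nodes["roi_id"].to_numpy())
    return GeneratedPopulation(spec, base_matrix, population, nodes, hub_nodes)


def generate_label_volume(
    n_parcels: int,
    voxels_per_parcel: Sequence[int],
    seed: int = 0,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    grid_shape: tuple[int, int, int] | None = None,
):
    """Synthetic 3-D atlas label volume with compact parcels of exact sizes.

    Parcels are grown voxel-by-voxel by breadth-first search from random
    unclaimed seed voxels (6-connectivity), which yields spatially compact,
    non-overlapping regions with exactly the requested voxel counts;
    background is label 0.  Deterministic given ``seed``.

    Returns a :class:`~hubrank.parcellation.LabelVolume`.
    """
    from .parcellation import LabelVolume  # local import avoids a cycle

    counts = list(voxels_per_parcel)
    if len(counts) != n_parcels:
        raise ValueError("voxels_per_parcel length must equal n_parcels")
    if any(c < 1 for c in counts):
        raise ValueError("every parcel needs at least one voxel")
    total = sum(counts)
    if grid_shape is None:
        side = int(np.ceil((2.0 * total) ** (1.0 / 3.0))) + 1
        grid_shape = (side, side, side)
    capacity = int(np.prod(grid_shape))
    if total > capacity:
        raise ValueError(
            f"requested {total} voxels exceed grid capacity {capacity}"
        )

    rng = np.random.default_rng(seed)
    grid = np.zeros(grid_shape, dtype=np.int32)
    free = np.ones(grid_shape, dtype=bool)
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]

    def claim(label: int, count: int) -> None:
        free_idx = np.argwhere(free)
        start = tuple(free_idx[rng.integers(len(free_idx))])
        queue: deque = deque([start])
        queued = {start}
        taken = 0
        while taken < count:
            if not queue:  # trapped pocket: restart growth from a fresh voxel
                remaining = np.argwhere(free)
                nxt = tuple(remaining[rng.integers(len(remaining))])
                queue.append(nxt)
                queued.add(nxt)
                continue
            v = queue.popleft()
            if not free[v]:
                continue
            grid[v] = label
            free[v] = False
            taken += 1
            for off in offsets:
                nb = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                if all(0 <= nb[k] < grid_shape[k] for k in range(3)):
                    if free[nb] and nb not in queued:
                        queue.append(nb)
                        queued.add(nb)

    for label, count in enumerate(counts, start=1):
        claim(label, count)

    half = (n_parcels + 1) // 2
    labels = pd.DataFrame(
        {
            "label": np.arange(1, n_parcels + 1),
            "name": [f"parcel_{l}" for l in range(1, n_parcels + 1)],
            "hemisphere": ["L" if l <= half else "R" for l in range(1, n_parcels + 1)],
            "homolog_label": 0,  # fixture volumes carry no homolog pairing
        }
    )
    return LabelVolume(grid, voxel_size, labels)


def generate_streamlines(
    matrix: ConnectivityMatrix,
    roi_sizes: dict | pd.Series,
    length_range: tuple[float, float] = (30.0, 300.0),
    seed: int = 0,
    count_scale: float = 1.0,
) -> pd.DataFrame:
    """Invert the edge-weight formula: emit a streamline table rebuilding ``matrix``.

    For each edge (i, j) a mean length L is drawn uniformly from
    ``length_range`` and the streamline count is set to
    ``round(count_scale * w_ij * L * (V_i + V_j) / 2)`` (at least 1), with all
    streamlines of the pair given the constant length L.  Rebuilding with
    :func:`~hubrank.network.build_weighted_matrix` then recovers
    ``count_scale * matrix`` exactly up to integer rounding of the counts.
    ``count_scale`` trades table size against rounding error.
    """
    lo, hi = length_range
    if not (0 < lo <= hi):
        raise ValueError("length_range must satisfy 0 < min <= max")
    if count_scale <= 0:
        raise ValueError("count_scale must be > 0")
    sizes = pd.Series(roi_sizes, dtype=float)
    rng = np.random.default_rng(seed)
    rows_a, rows_b, rows_len = [], [], []
    n = matrix.n_nodes
    ids = matrix.node_ids
    for i in range(n):
        for j in range(i + 1, n):
            w = matrix.weights[i, j]
            if w <= 0:
                continue
            length = float(rng.uniform(lo, hi))
            v_mean = (sizes.loc[ids[i]] + sizes.loc[ids[j]]) / 2.0
            count = max(1, int(round(count_scale * w * length * v_mean)))
            rows_a.extend([ids[i]] * count)
            rows_b.extend([ids[j]] * count)
            rows_len.extend([length] * count)
    return pd.DataFrame({"roi_a": rows_a, "roi_b": rows_b, "length_mm": rows_len})


def generate_parcel_rank_table(
    n_pairs: int = 100,
    n_subjects: int = 50,
    n_units: int = 1000,
    shifted_parcels: Sequence[int] = (),
    shift: float = 0.0,
    noise_sd: float | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[tuple[str, str, str]]]:
    """Synthetic subject-by-parcel median-rank table with planted left dominance.

    Each homologous parcel pair shares a latent median hubness rank (uniform
    over the middle of the 1..n_units scale); per-subject observed values add
    independent Gaussian noise (default sd = 10% of ``n_units``).  Parcels in
    ``shifted_parcels`` have their *left* values lowered by ``shift`` rank
    units (lower rank = more hub-like = left dominance).

    Returns the table (columns ``P###_L`` / ``P###_R``) and the homolog pair
    list ``(parcel_id, left_column, right_column)`` expected by
    :func:`~hubrank.analysis.hemispheric_asymmetry`.
    """
    if noise_sd is None:
        noise_sd = 0.1 * n_units
    rng = np.random.default_rng(seed)
    latent = rng.uniform(0.2 * n_units, 0.8 * n_units, n_pairs)
    data = {}
    pairs = []
    shifted = set(shifted_parcels)
    for p in range(n_pairs):
        pid = f"P{p:03d}"
        left = latent[p] - (shift if p in shifted else 0.0) + rng.normal(0, noise_sd, n_subjects)
        right = latent[p] + rng.normal(0, noise_sd, n_subjects)
        data[f"{pid}_L"] = left
        data[f"{pid}_R"] = right
        pairs.append((pid, f"{pid}_L", f"{pid}_R"))
    table = pd.DataFrame(data, index=[f"subject_{i:04d}" for i in range(n_subjects)])
    return table, pairs
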