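"""On-disk formats: matrices, populations, label volumes, streamline tables.

Conventions: delimited outputs are tab-separated UTF-8 with ``#``-prefixed
metadata lines; matrices are dense TSV (``.tsv``) or Matrix Market
(``.mtx``, with a ``<stem>.nodes.tsv`` node-index sidecar); label volumes
are NIfTI with a ``<stem>.labels.tsv`` metadata sidecar; ground truth and
run summaries are JSON.  Rank direction is 1 = top everywhere.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .aggregation import SubjectPopulation
from .network import ConnectivityMatrix, validate_streamlines
from .parcellation import LabelVolume, SubparcellationMap

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_population",
    "write_population",
    "read_label_volume",
    "write_label_volume",
    "read_streamlines",
    "write_streamlines",
    "read_subparcellation",
    "write_subparcellation",
    "write_table",
]


def _nodes_sidecar(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".nodes.tsv")


def write_matrix(matrix: ConnectivityMatrix, path) -> None:
    """Write a connectivity matrix as dense TSV or Matrix Market (.mtx)."""
    path = Path(path)
    if path.suffix == ".mtx":
        spio.mmwrite(str(path), sparse.coo_matrix(matrix.weights))
        pd.DataFrame({"roi_id": matrix.node_ids}).to_csv(
            _nodes_sidecar(path), sep="\t", index=False
        )
    else:
        frame = pd.DataFrame(matrix.weights, index=matrix.node_ids, columns=matrix.node_ids)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# hubrank connectivity matrix; symmetric, hollow, weights >= 0\n")
            frame.to_csv(fh, sep="\t", index_label="roi_id")


def read_matrix(path) -> ConnectivityMatrix:
    """Read a connectivity matrix (TSV or .mtx); validates the invariants."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".mtx":
        weights = np.asarray(spio.mmread(str(path)).todense() if sparse.issparse(
            spio.mmread(str(path))) else spio.mmread(str(path)), dtype=float)
        sidecar = _nodes_sidecar(path)
        node_ids = (
            pd.read_csv(sidecar, sep="\t")["roi_id"].to_numpy()
            if sidecar.exists()
            else None
        )
    else:
        frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        weights = frame.to_numpy(dtype=float)
        node_ids = frame.index.to_numpy()
    return ConnectivityMatrix(weights, node_ids)


def write_population(gen_or_pop, out_dir, fmt: str = "mtx") -> None:
    """Write a population: one matrix per subject plus JSON ground truth.

    Accepts a :class:`~hubrank.synthetic.GeneratedPopulation` (ground truth
    and node table included) or a bare :class:`SubjectPopulation`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pop = getattr(gen_or_pop, "population", gen_or_pop)
    for i in range(pop.n_subjects):
        write_matrix(pop.matrix(i), out / f"{pop.subject_ids[i]}.{fmt}")
    pd.DataFrame({"roi_id": pop.node_ids}).to_csv(out / "node_index.tsv", sep="\t", index=False)
    node_table = getattr(gen_or_pop, "node_table", None)
    if node_table is not None:
        node_table.to_csv(out / "node_table.tsv", sep="\t", index=False)
    ground_truth = getattr(gen_or_pop, "ground_truth", None)
    if ground_truth is not None:
        (out / "ground_truth.json").write_text(json.dumps(ground_truth, indent=2))


def read_population(in_dir) -> tuple[SubjectPopulation, pd.DataFrame | None]:
    """Read a population directory; returns (population, node_table or None)."""
    in_dir = Path(in_dir)
    files = sorted(
        p for p in in_dir.iterdir()
        if p.suffix in (".mtx", ".tsv")
        and p.name not in ("node_index.tsv", "node_table.tsv")
        and not p.name.endswith(".nodes.tsv")
    )
    if not files:
        raise FileNotFoundError(f"no subject matrices found in {in_dir}")
    matrices = [read_matrix(p) for p in files]
    pop = SubjectPopulation(matrices, subject_ids=[p.stem for p in files])
    node_table_path = in_dir / "node_table.tsv"
    node_table = (
        pd.read_csv(node_table_path, sep="\t") if node_table_path.exists() else None
    )
    return pop, node_table


def _labels_sidecar(path: Path) -> Path:
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return path.with_name(name[: -len(ext)] + ".labels.tsv")
    return path.with_suffix(".labels.tsv")


def write_label_volume(volume: LabelVolume, path) -> None:
    path = Path(path)
    affine = np.diag(list(volume.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(volume.grid.astype(np.int32), affine), str(path))
    volume.labels.to_csv(_labels_sidecar(path), sep="\t", index=False)


def read_label_volume(path) -> LabelVolume:
    path = Path(path)
    img = nib.load(str(path))
    grid = np.asarray(img.dataobj).astype(np.int32)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    sidecar = _labels_sidecar(path)
    labels = pd.read_csv(sidecar, sep="\t") if sidecar.exists() else None
    return LabelVolume(grid, voxel_size, labels)


def write_streamlines(table: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# hubrank streamline endpoints: roi_a, roi_b, length_mm (one row per streamline)\n")
        table.to_csv(fh, sep="\t", index=False)


def read_streamlines(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", comment="#")
    return validate_streamlines(table)


def write_subparcellation(smap: SubparcellationMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# hubrank subparcellation map; one row per ROI\n")
        smap.table.to_csv(fh, sep="\t", index=False)


def read_subparcellation(path) -> SubparcellationMap:
    return SubparcellationMap(pd.read_csv(path, sep="\t", comment="#"))


def write_table(frame: pd.DataFrame, path, comment: str | None = None, index: bool = False) -> None:
    """Write a result table as TSV with an optional ``#`` metadata header."""
    with open(path, "w", encoding="utf-8") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        frame.to_csv(fh, sep="\t", index=index)
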