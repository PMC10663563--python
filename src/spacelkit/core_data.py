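"""Shared data model, file I/O, gene-space harmonization and normalization.

Coordinates are real-valued micrometres in a planar Cartesian frame; all
alignment math downstream is metric, so no pixel/array-index convention is
exposed anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import issparse

logger = logging.getLogger("spacelkit")

__all__ = [
    "SingleCellReference",
    "SliceData",
    "CompositionMatrix",
    "DomainAssignment",
    "RunConfig",
    "load_slice",
    "write_slice",
    "load_reference",
    "to_anndata",
    "from_anndata",
    "harmonize_genes",
    "normalize_counts",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SingleCellReference:
    """A cells x genes nonnegative count matrix with one type label per cell.

    ``type_freq`` holds the per-type composition f_t of the reference
    (fractions summing to 1), the quantity that drives pseudo-spot sampling.
    """

    counts: np.ndarray
    gene_names: np.ndarray
    cell_types: np.ndarray
    type_names: np.ndarray = field(init=False)
    type_freq: np.ndarray = field(init=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.cell_types = np.asarray(self.cell_types, dtype=object)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (cells x genes)")
        if self.counts.shape[0] != len(self.cell_types):
            raise ValueError(
                f"counts has {self.counts.shape[0]} cells but "
                f"{len(self.cell_types)} labels"
            )
        if self.counts.shape[1] != len(self.gene_names):
            raise ValueError("gene_names length does not match counts columns")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        _check_unique(self.gene_names)
        types, counts_per_type = np.unique(self.cell_types, return_counts=True)
        keep_types = types[counts_per_type >= 2]
        if len(keep_types) < len(types):
            dropped = sorted(set(types) - set(keep_types))
            logger.warning("dropping types with <2 cells: %s", dropped)
            mask = np.isin(self.cell_types, keep_types)
            self.counts = self.counts[mask]
            self.cell_types = self.cell_types[mask]
            types, counts_per_type = np.unique(self.cell_types, return_counts=True)
        self.type_names = types
        self.type_freq = counts_per_type / counts_per_type.sum()

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_types(self) -> int:
        return len(self.type_names)


@dataclass
class SliceData:
    """One ST slice: spots x genes counts plus planar coordinates in um."""

    counts: np.ndarray
    gene_names: np.ndarray
    coords: np.ndarray
    slice_id: str = "slice0"
    z: float | None = None
    spot_ids: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.counts.shape[0] != self.coords.shape[0]:
            raise ValueError(
                f"matrix rows and coordinate rows differ: "
                f"{self.counts.shape[0]} vs {self.coords.shape[0]}"
            )
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be n x 2")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        _check_unique(self.gene_names)
        if self.spot_ids is None:
            self.spot_ids = np.array(
                [f"{self.slice_id}_spot{i}" for i in range(self.counts.shape[0])],
                dtype=object,
            )

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]


@dataclass
class CompositionMatrix:
    """Spots x cell-types proportions; every row lives on the simplex."""

    proportions: np.ndarray
    type_names: np.ndarray

    def __post_init__(self):
        self.proportions = np.asarray(self.proportions, dtype=float)
        self.type_names = np.asarray(self.type_names, dtype=object)
        p = self.proportions
        if np.any(p < -1e-9) or np.any(p > 1 + 1e-9):
            raise ValueError("proportions must lie in [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("proportion rows must sum to 1 within 1e-6")

    @property
    def n_spots(self) -> int:
        return self.proportions.shape[0]


@dataclass
class DomainAssignment:
    """Per-spot integer domain labels shared across slices."""

    labels: np.ndarray
    slice_of_spot: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.slice_of_spot = np.asarray(self.slice_of_spot, dtype=object)
        if len(self.labels) != len(self.slice_of_spot):
            raise ValueError("labels and slice_of_spot must be aligned")
        if np.any(self.labels < 0):
            raise ValueError("labels must be nonnegative integers")

    def for_slice(self, slice_id) -> np.ndarray:
        return self.labels[self.slice_of_spot == slice_id]

    @property
    def n_domains(self) -> int:
        return int(self.labels.max()) + 1


@dataclass
class RunConfig:
    """Global run configuration; one seed drives derived per-module seeds."""

    seed: int = 0
    normalization: str = "lognorm"  # {"raw", "lognorm"} for model inputs
    out_dir: str = "."
    log_level: str = "INFO"

    # fixed offsets keep modules reproducible without coupling them
    _OFFSETS = {
        "simdata": 11,
        "spoint": 101,
        "splane": 211,
        "scube": 307,
        "gpr3d": 401,
    }

    def module_seed(self, module: str) -> int:
        return (int(self.seed) + self._OFFSETS[module]) % (2**31 - 1)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _check_unique(names) -> None:
    values, counts = np.unique(np.asarray(names, dtype=object), return_counts=True)
    if np.any(counts > 1):
        raise ValueError(f"duplicate names: {list(values[counts > 1])[:5]}")


def _collapse_duplicate_genes(matrix: np.ndarray, genes: np.ndarray):
    """Sum columns that share a gene name (conservative, deterministic)."""
    uniq, inverse, counts = np.unique(genes, return_inverse=True, return_counts=True)
    if not np.any(counts > 1):
        return matrix, genes
    logger.warning(
        "collapsing %d duplicate gene names by summation",
        int((counts > 1).sum()),
    )
    out = np.zeros((matrix.shape[0], len(uniq)), dtype=matrix.dtype)
    np.add.at(out.T, inverse, matrix.T)
    return out, uniq.astype(object)


def _read_matrix(path: Path, fmt: str):
    """Return (matrix, gene_names or None). Dense CSV/TSV carry gene headers."""
    if fmt == "mtx":
        m = mmread(str(path))
        m = m.toarray() if issparse(m) else np.asarray(m)
        genes = None
        gene_file = path.with_suffix(".genes.txt")
        if gene_file.exists():
            genes = np.loadtxt(gene_file, dtype=str, ndmin=1).astype(object)
        return np.asarray(m), genes
    sep = "," if fmt == "csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df.to_numpy(), df.columns.to_numpy(dtype=object)


def load_slice(
    matrix_path, coords_path, fmt: str = "csv", slice_id: str | None = None
) -> SliceData:
    """Read one slice from a counts matrix plus a spot_id,x,y[,z] coordinate CSV.

    Duplicate gene names are collapsed by summation (logged). Matrix rows
    must match coordinate rows one-to-one.
    """
    matrix_path, coords_path = Path(matrix_path), Path(coords_path)
    if fmt not in {"mtx", "csv", "tsv"}:
        raise ValueError(f"unknown format {fmt!r}")
    matrix, genes = _read_matrix(matrix_path, fmt)
    coords_df = pd.read_csv(coords_path)
    if matrix.shape[0] != len(coords_df):
        raise ValueError(
            f"matrix rows and coordinate rows differ: "
            f"{matrix.shape[0]} vs {len(coords_df)}"
        )
    if genes is None:
        genes = np.array([f"gene{i}" for i in range(matrix.shape[1])], dtype=object)
    matrix, genes = _collapse_duplicate_genes(matrix, genes)
    z = None
    if "z" in coords_df.columns:
        zs = coords_df["z"].to_numpy(float)
        z = float(zs[0]) if np.allclose(zs, zs[0]) else None
    return SliceData(
        counts=matrix,
        gene_names=genes,
        coords=coords_df[["x", "y"]].to_numpy(float),
        slice_id=slice_id or matrix_path.stem,
        z=z,
        spot_ids=coords_df.iloc[:, 0].to_numpy(dtype=object),
    )


def write_slice(sl: SliceData, matrix_path, coords_path, fmt: str = "csv") -> None:
    matrix_path, coords_path = Path(matrix_path), Path(coords_path)
    if fmt == "mtx":
        mmwrite(str(matrix_path), np.asarray(sl.counts))
        np.savetxt(matrix_path.with_suffix(".genes.txt"), sl.gene_names, fmt="%s")
    else:
        sep = "," if fmt == "csv" else "\t"
        pd.DataFrame(sl.counts, index=sl.spot_ids, columns=sl.gene_names).to_csv(
            matrix_path, sep=sep
        )
    df = pd.DataFrame(
        {"spot_id": sl.spot_ids, "x": sl.coords[:, 0], "y": sl.coords[:, 1]}
    )
    if sl.z is not None:
        df["z"] = sl.z
    df.to_csv(coords_path, index=False)


def to_anndata(sl: SliceData):
    """Mirror a slice as an AnnData with coordinates in ``obsm['spatial']``."""
    import anndata as ad

    adata = ad.AnnData(
        X=np.asarray(sl.counts, dtype=float),
        obs=pd.DataFrame(index=pd.Index(sl.spot_ids, name="spot_id")),
        var=pd.DataFrame(index=pd.Index(sl.gene_names, name="gene")),
    )
    adata.obsm["spatial"] = sl.coords.copy()
    adata.uns["slice_id"] = sl.slice_id
    if sl.z is not None:
        adata.uns["z"] = float(sl.z)
    return adata


def from_anndata(adata) -> SliceData:
    """Build a SliceData from an AnnData carrying ``obsm['spatial']``."""
    X = adata.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    return SliceData(
        counts=np.asarray(X),
        gene_names=adata.var_names.to_numpy(dtype=object),
        coords=np.asarray(adata.obsm["spatial"], dtype=float),
        slice_id=str(adata.uns.get("slice_id", "slice0")),
        z=float(adata.uns["z"]) if "z" in adata.uns else None,
        spot_ids=adata.obs_names.to_numpy(dtype=object),
    )


def load_reference(matrix_path, labels_path, fmt: str = "csv") -> SingleCellReference:
    """Read a single-cell reference matrix plus a cell_id,cell_type label CSV."""
    matrix, genes = _read_matrix(Path(matrix_path), fmt)
    labels = pd.read_csv(labels_path)
    if matrix.shape[0] != len(labels):
        raise ValueError(
            f"matrix rows and label rows differ: {matrix.shape[0]} vs {len(labels)}"
        )
    if genes is None:
        genes = np.array([f"gene{i}" for i in range(matrix.shape[1])], dtype=object)
    matrix, genes = _collapse_duplicate_genes(matrix, genes)
    return SingleCellReference(
        counts=matrix, gene_names=genes, cell_types=labels["cell_type"].to_numpy(object)
    )


# ---------------------------------------------------------------------------
# gene-space harmonization and normalization
# ---------------------------------------------------------------------------

def harmonize_genes(
    ref: SingleCellReference, slices: list[SliceData]
) -> tuple[SingleCellReference, list[SliceData]]:
    """Restrict the reference and every slice to the shared gene set.

    All outputs use one identical (sorted) gene order; the operation is
    idempotent. An empty intersection raises.
    """
    common = set(ref.gene_names)
    for sl in slices:
        common &= set(sl.gene_names)
    if not common:
        raise ValueError("no genes shared between reference and slices")
    order = np.array(sorted(common), dtype=object)

    def _index(names):
        pos = {g: i for i, g in enumerate(names)}
        return np.array([pos[g] for g in order])

    new_ref = SingleCellReference(
        counts=ref.counts[:, _index(ref.gene_names)],
        gene_names=order,
        cell_types=ref.cell_types,
    )
    new_slices = [
        SliceData(
            counts=sl.counts[:, _index(sl.gene_names)],
            gene_names=order,
            coords=sl.coords,
            slice_id=sl.slice_id,
            z=sl.z,
            spot_ids=sl.spot_ids,
        )
        for sl in slices
    ]
    return new_ref, new_slices


def normalize_counts(counts: np.ndarray, target_sum: float | None = None) -> np.ndarray:
    """Library-size normalization to the median total followed by log1p."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1)
    totals = np.where(totals == 0, 1.0, totals)
    if target_sum is None:
        target_sum = float(np.median(totals))
    return np.log1p(counts / totals[:, None] * target_sum)
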