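"""Loading, validation, gene filtering and alignment of paired expression data.

Supported matrix formats:

* dense CSV/TSV: header row = gene ids, first column = cell/spot ids;
* MatrixMarket ``.mtx`` triplets (rows = cells/spots, cols = genes) with two
  sidecar index files ``<stem>_rows.txt`` and ``<stem>_cols.txt`` holding one
  identifier per line.

Coordinates are a TSV/CSV with columns ``spot_id, x, y``; labels a TSV/CSV with
``cell_id, cell_type[, stage]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "GeneExpressionMatrix",
    "SpatialDataset",
    "load_paired_dataset",
    "filter_and_align",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input matrix or annotation fails an invariant check."""


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(ids) != len(set(ids)):
        dup = pd.Series(ids).value_counts()
        dup = dup[dup > 1].index.tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dup}")


def _check_values(values: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"{what} contains non-finite values")
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"{what} contains negative value {values[i, j]!r} at row {i}, col {j}"
        )


@dataclass
class GeneExpressionMatrix:
    """Cells x genes expression with per-cell label annotations.

    Parameters
    ----------
    values : (n_cells, n_genes) nonnegative float array
    gene_ids, cell_ids : ordered identifier sequences
    labels : DataFrame indexed by cell id; one column per label name
        (``cell_type`` always present, ``stage`` optional).
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    labels: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} != "
                f"({len(self.cell_ids)} cells, {len(self.gene_ids)} genes)"
            )
        _check_unique(np.asarray(self.gene_ids), "gene_ids")
        _check_unique(np.asarray(self.cell_ids), "cell_ids")
        _check_values(self.values, "expression matrix")
        if len(self.labels):
            missing = sorted(set(self.cell_ids) - set(self.labels.index.astype(str)))
            if missing:
                raise ValidationError(
                    f"{len(missing)} cell(s) missing from labels: {missing[:10]}"
                )
            self.labels = self.labels.loc[self.cell_ids]
            if self.labels.isna().any().any():
                raise ValidationError("labels contain missing values")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset_genes(self, genes: list[str]) -> "GeneExpressionMatrix":
        idx = pd.Index(self.gene_ids).get_indexer(genes)
        if np.any(idx < 0):
            raise ValidationError("requested genes absent from matrix")
        return GeneExpressionMatrix(
            self.values[:, idx], list(genes), list(self.cell_ids), self.labels.copy()
        )


@dataclass
class SpatialDataset:
    """Spots x genes expression with 2-D spot coordinates."""

    values: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]
    coords: np.ndarray  # (n_spots, 2) [x, y]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.spot_ids = [str(s) for s in self.spot_ids]
        self.coords = np.asarray(self.coords, dtype=float)
        if self.values.shape != (len(self.spot_ids), len(self.gene_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} != "
                f"({len(self.spot_ids)} spots, {len(self.gene_ids)} genes)"
            )
        if self.coords.shape != (len(self.spot_ids), 2):
            raise ValidationError(
                f"coords shape {self.coords.shape} != ({len(self.spot_ids)}, 2)"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coordinates contain non-finite values")
        _check_unique(np.asarray(self.gene_ids), "gene_ids")
        _check_unique(np.asarray(self.spot_ids), "spot_ids")
        _check_values(self.values, "spatial matrix")

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset_genes(self, genes: list[str]) -> "SpatialDataset":
        idx = pd.Index(self.gene_ids).get_indexer(genes)
        if np.any(idx < 0):
            raise ValidationError("requested genes absent from matrix")
        return SpatialDataset(
            self.values[:, idx], list(genes), list(self.spot_ids), self.coords.copy()
        )

    def coords_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coords, index=self.spot_ids, columns=["x", "y"])


def _read_table(path: Path) -> pd.DataFrame:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def _read_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a matrix file; returns (values, row_ids, col_ids).

    Rows are observations (cells or spots), columns are genes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        stem = path.with_suffix("")
        rows_file = Path(str(stem) + "_rows.txt")
        cols_file = Path(str(stem) + "_cols.txt")
        for f in (rows_file, cols_file):
            if not f.exists():
                raise FileNotFoundError(f"MTX index file not found: {f}")
        row_ids = rows_file.read_text().split()
        col_ids = cols_file.read_text().split()
        if mat.shape != (len(row_ids), len(col_ids)):
            raise ValidationError(
                f"MTX shape {mat.shape} inconsistent with index files "
                f"({len(row_ids)} rows, {len(col_ids)} cols)"
            )
        return mat, row_ids, col_ids
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return (
        df.to_numpy(dtype=float),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
    )


def load_paired_dataset(
    sc_path: str | Path,
    st_path: str | Path,
    coords_path: str | Path,
    labels_path: str | Path,
) -> tuple[GeneExpressionMatrix, SpatialDataset]:
    """Load a paired single-cell + spatial dataset from disk.

    Raises
    ------
    FileNotFoundError
        if any input file is missing.
    ValidationError
        for negative values, spots absent from the coordinate table, or cells
        absent from the label table.
    """
    sc_vals, cell_ids, sc_genes = _read_matrix(sc_path)
    st_vals, spot_ids, st_genes = _read_matrix(st_path)

    coords_path = Path(coords_path)
    if not coords_path.exists():
        raise FileNotFoundError(coords_path)
    coords_df = _read_table(coords_path)
    required = {"spot_id", "x", "y"}
    if not required.issubset(coords_df.columns):
        raise ValidationError(
            f"coordinate file must have columns {sorted(required)}, "
            f"got {list(coords_df.columns)}"
        )
    coords_df = coords_df.set_index(coords_df["spot_id"].astype(str))
    missing_spots = [s for s in spot_ids if str(s) not in coords_df.index]
    if missing_spots:
        raise ValidationError(
            f"spot(s) in matrix absent from coordinates: {missing_spots[:10]}"
        )
    coords = coords_df.loc[[str(s) for s in spot_ids], ["x", "y"]].to_numpy(float)

    labels_path = Path(labels_path)
    if not labels_path.exists():
        raise FileNotFoundError(labels_path)
    labels_df = _read_table(labels_path)
    if "cell_id" not in labels_df.columns:
        raise ValidationError("labels file must have a cell_id column")
    labels_df = labels_df.set_index(labels_df["cell_id"].astype(str)).drop(
        columns="cell_id"
    )

    sc = GeneExpressionMatrix(sc_vals, sc_genes, cell_ids, labels_df)
    st = SpatialDataset(st_vals, st_genes, spot_ids, coords)
    return sc, st


def filter_and_align(
    sc: GeneExpressionMatrix,
    st: SpatialDataset,
    cell_frac: float = 0.05,
    spot_frac: float = 0.01,
) -> tuple[GeneExpressionMatrix, SpatialDataset]:
    """Drop lowly expressed genes and restrict both matrices to common genes.

    A gene survives if it is expressed (value strictly > 0) in at least
    ``cell_frac`` of cells AND at least ``spot_frac`` of spots; both matrices
    are then restricted to the intersection of surviving genes, in identical
    order.
    """
    if not (0 < cell_frac < 1) or not (0 < spot_frac < 1):
        raise ValueError("fractions must lie in (0, 1)")

    sc_prev = pd.Series(
        (sc.values > 0).mean(axis=0), index=sc.gene_ids, dtype=float
    )
    st_prev = pd.Series(
        (st.values > 0).mean(axis=0), index=st.gene_ids, dtype=float
    )
    common = [g for g in sc.gene_ids if g in set(st.gene_ids)]
    keep = [
        g
        for g in common
        if sc_prev[g] >= cell_frac and st_prev[g] >= spot_frac
    ]
    if not keep:
        raise ValidationError(
            "no genes survive filtering; relax cell_frac/spot_frac thresholds "
            "or verify that gene identifiers match between modalities"
        )
    logger.info(
        "filter_and_align: %d/%d common genes retained (cell_frac=%g, spot_frac=%g)",
        len(keep),
        len(common),
        cell_frac,
        spot_frac,
    )
    return sc.subset_genes(keep), st.subset_genes(keep)


def save_paired_dataset(
    sc: GeneExpressionMatrix, st: SpatialDataset, outdir: str | Path
) -> dict[str, Path]:
    """Write a paired dataset in the dense CSV layout consumed by the loader."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sc": outdir / "sc.csv",
        "st": outdir / "st.csv",
        "coords": outdir / "coords.tsv",
        "labels": outdir / "labels.tsv",
    }
    pd.DataFrame(sc.values, index=sc.cell_ids, columns=sc.gene_ids).to_csv(paths["sc"])
    pd.DataFrame(st.values, index=st.spot_ids, columns=st.gene_ids).to_csv(paths["st"])
    coords = st.coords_frame().reset_index(names="spot_id")
    coords.to_csv(paths["coords"], sep="\t", index=False)
    sc.labels.reset_index(names="cell_id").to_csv(paths["labels"], sep="\t", index=False)
    return paths
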