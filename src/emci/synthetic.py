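"""Synthetic paired single-cell + pseudo-spot fixtures with known composition.

Cells are drawn from a negative-binomial expression model with disjoint
per-type signature gene sets (elevated means) and placed in space as one
Gaussian blob per type plus a uniformly mixed fraction. The bounding box is
then gridded into square tiles; each occupied tile becomes a pseudo-spot
whose expression is the sum of its member cells and whose ground-truth
proportions are the member type counts divided by the member count. Defaults
are calibrated so a seeded run yields roughly 189 occupied spots holding 1-18
cells each.

A held-out, stratified fraction of the cells (default half) is emitted as the
"single-cell reference" so the reference and the spots come from different
cells, mimicking a separate dissociated-cell experiment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from emci.preprocess import GeneExpressionMatrix, SpatialDataset, save_paired_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "simulate_cells",
    "grid_to_spots",
    "make_fixture",
    "write_fixture",
]


@dataclass
class SyntheticConfig:
    q: int = 4
    m: int = 120
    signature_genes_per_type: int = 12
    n_cells: int = 1500
    grid: tuple[int, int] = (14, 14)
    cells_per_spot_range: tuple[int, int] = (1, 18)
    background_mean: float = 1.0
    fold_change: float = 8.0
    dispersion: float = 0.5
    noise: float = 0.0  # sd of multiplicative log-normal noise on means
    blob_sd: float = 0.18  # in units of the domain side
    mix_frac: float = 0.25  # fraction of cells placed uniformly
    domain: float = 14.0  # square side length of the spatial domain
    reference_frac: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.q < 2:
            raise ValueError("need at least 2 cell types")
        if self.q * self.signature_genes_per_type > self.m:
            raise ValueError("signature sets must be disjoint: q * signatures <= m")
        if self.cells_per_spot_range[0] < 1:
            raise ValueError("cells_per_spot_range lower bound must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground-truth composition of the simulated pseudo-spots."""

    proportions: pd.DataFrame  # spots x types
    cell_types: pd.Series  # cell id -> type (spot-forming cells)
    cell_coords: pd.DataFrame  # cell id -> x, y
    members: dict[str, list[str]] = field(default_factory=dict)  # spot -> cell ids


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (Poisson at dispersion 0)."""
    mean = np.maximum(mean, 1e-12)
    if dispersion <= 0:
        return rng.poisson(mean).astype(float)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p).astype(float)


def type_names(q: int) -> list[str]:
    return [f"type{chr(ord('A') + t)}" for t in range(q)]


def signature_sets(cfg: SyntheticConfig) -> dict[str, list[str]]:
    genes = [f"gene{i:04d}" for i in range(cfg.m)]
    out = {}
    for t, name in enumerate(type_names(cfg.q)):
        lo = t * cfg.signature_genes_per_type
        out[name] = genes[lo : lo + cfg.signature_genes_per_type]
    return out


def simulate_cells(cfg: SyntheticConfig) -> tuple[GeneExpressionMatrix, pd.DataFrame]:
    """Draw all simulated cells; returns the labeled matrix and per-cell coords."""
    rng = np.random.default_rng(cfg.seed)
    genes = [f"gene{i:04d}" for i in range(cfg.m)]
    names = type_names(cfg.q)
    types = np.array([names[i % cfg.q] for i in range(cfg.n_cells)], dtype=object)
    rng.shuffle(types)

    mean = np.full((cfg.n_cells, cfg.m), cfg.background_mean)
    for t, name in enumerate(names):
        rows = types == name
        lo = t * cfg.signature_genes_per_type
        hi = lo + cfg.signature_genes_per_type
        mean[np.ix_(rows, range(lo, hi))] *= cfg.fold_change
    if cfg.noise > 0:
        mean *= np.exp(rng.normal(0.0, cfg.noise, size=mean.shape))
    counts = _nb_draw(rng, mean, cfg.dispersion)

    # spatial placement: one blob center per type + uniform mixing fraction
    L = cfg.domain
    angles = 2 * np.pi * np.arange(cfg.q) / cfg.q
    centers = np.column_stack(
        [L / 2 + 0.3 * L * np.cos(angles), L / 2 + 0.3 * L * np.sin(angles)]
    )
    coords = np.empty((cfg.n_cells, 2))
    uniform = rng.random(cfg.n_cells) < cfg.mix_frac
    for t, name in enumerate(names):
        rows = np.where(types == name)[0]
        blob = rng.normal(centers[t], cfg.blob_sd * L, size=(len(rows), 2))
        coords[rows] = blob
    coords[uniform] = rng.uniform(0, L, size=(int(uniform.sum()), 2))
    coords = np.clip(coords, 0, np.nextafter(L, 0))

    cell_ids = [f"cell{i:05d}" for i in range(cfg.n_cells)]
    labels = pd.DataFrame({"cell_type": types}, index=cell_ids)
    gem = GeneExpressionMatrix(counts, genes, cell_ids, labels)
    coords_df = pd.DataFrame(coords, index=cell_ids, columns=["x", "y"])
    return gem, coords_df


def grid_to_spots(
    cells: GeneExpressionMatrix,
    coords: pd.DataFrame,
    grid: tuple[int, int],
) -> tuple[SpatialDataset, SyntheticTruth]:
    """Sum cells within square tiles into pseudo-spots with known composition.

    The coordinate bounding box is tiled into ``grid = (rows, cols)`` squares;
    spot expression = sum of member cells, spot coordinate = tile center,
    truth proportions = member type counts / member count. Empty tiles are
    dropped.
    """
    rows, cols = grid
    xy = coords.loc[cells.cell_ids, ["x", "y"]].to_numpy(float)
    if len(xy) == 0:
        raise ValueError("no cells to grid")
    x_min, y_min = xy.min(axis=0)
    x_max, y_max = xy.max(axis=0)
    x_span = max(x_max - x_min, 1e-12)
    y_span = max(y_max - y_min, 1e-12)
    ci = np.minimum((xy[:, 0] - x_min) / x_span * cols, cols - 1e-9).astype(int)
    ri = np.minimum((xy[:, 1] - y_min) / y_span * rows, rows - 1e-9).astype(int)

    tile_of_cell = ri * cols + ci
    occupied = np.unique(tile_of_cell)
    if len(occupied) == 0:
        raise ValueError("all tiles empty")

    tnames = sorted(cells.labels["cell_type"].astype(str).unique())
    spot_ids, spot_vals, spot_xy, prop_rows, members = [], [], [], [], {}
    for tile in occupied:
        sel = np.where(tile_of_cell == tile)[0]
        r, c = divmod(int(tile), cols)
        sid = f"spot_r{r:02d}c{c:02d}"
        spot_ids.append(sid)
        spot_vals.append(cells.values[sel].sum(axis=0))
        cx = x_min + (c + 0.5) / cols * x_span
        cy = y_min + (r + 0.5) / rows * y_span
        spot_xy.append((cx, cy))
        member_ids = [cells.cell_ids[i] for i in sel]
        members[sid] = member_ids
        tcounts = cells.labels.loc[member_ids, "cell_type"].astype(str).value_counts()
        prop_rows.append([tcounts.get(t, 0) / len(sel) for t in tnames])

    st = SpatialDataset(
        np.vstack(spot_vals), list(cells.gene_ids), spot_ids, np.array(spot_xy)
    )
    truth = SyntheticTruth(
        proportions=pd.DataFrame(prop_rows, index=spot_ids, columns=tnames),
        cell_types=cells.labels["cell_type"].astype(str),
        cell_coords=coords.loc[cells.cell_ids],
        members=members,
    )
    return st, truth


def make_fixture(
    cfg: SyntheticConfig | None = None,
) -> tuple[GeneExpressionMatrix, SpatialDataset, SyntheticTruth]:
    """Full paired fixture: reference cells, pseudo-spots, and ground truth.

    Splits the simulated cells (stratified by type) into a reference set
    (returned as the single-cell matrix) and a spot-forming set (gridded into
    pseudo-spots). With ``reference_frac = 0`` all cells form spots and the
    full matrix is also the reference.
    """
    cfg = cfg or SyntheticConfig()
    gem, coords = simulate_cells(cfg)
    if cfg.reference_frac > 0:
        rng = np.random.default_rng(cfg.seed + 7)
        ref_ids: list[str] = []
        for t in type_names(cfg.q):
            ids = [c for c, v in gem.labels["cell_type"].items() if v == t]
            ids = list(np.array(ids, dtype=object)[rng.permutation(len(ids))])
            n_ref = max(1, int(round(cfg.reference_frac * len(ids))))
            ref_ids.extend(ids[:n_ref])
        ref_set = set(ref_ids)
        spot_ids = [c for c in gem.cell_ids if c not in ref_set]
        ref = _subset_cells(gem, sorted(ref_ids))
        spotters = _subset_cells(gem, spot_ids)
    else:
        ref = gem
        spotters = gem
    st, truth = grid_to_spots(spotters, coords, cfg.grid)
    return ref, st, truth


def _subset_cells(gem: GeneExpressionMatrix, cell_ids: list[str]) -> GeneExpressionMatrix:
    idx = pd.Index(gem.cell_ids).get_indexer(cell_ids)
    return GeneExpressionMatrix(
        gem.values[idx], list(gem.gene_ids), list(cell_ids), gem.labels.loc[cell_ids]
    )


def write_fixture(cfg: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the fixture in the file formats consumed by the preprocess loader."""
    outdir = Path(outdir)
    ref, st, truth = make_fixture(cfg)
    paths = save_paired_dataset(ref, st, outdir)
    truth_path = outdir / "truth.csv"
    truth.proportions.rename_axis("spot_id").to_csv(truth_path)
    paths["truth"] = truth_path
    return paths
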