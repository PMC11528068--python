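"""Per-spot cell-type proportion estimation from the correlation tensor, and ARI.

The three tensor layers are each min-max normalized to [0, 1] (mutual
information is in nats and unbounded; Pearson lives in [-1, 1], so raw
averaging would be scale-incoherent), averaged into a single cell x spot
matrix, then averaged over cells of each type to give per-type spot profiles.
Dividing each spot's profile vector by its sum yields proportions on the
simplex. ``fuse_mode="raw"`` skips the per-layer rescaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from emci.correlation import CorrelationTensor

logger = logging.getLogger(__name__)

__all__ = ["ProportionMatrix", "fuse_and_profile", "proportions", "ari"]


@dataclass
class ProportionMatrix:
    """Spots x cell-types matrix with rows on the probability simplex."""

    values: pd.DataFrame  # index = spot ids, columns = type names
    fuse_mode: str = "minmax"

    def __post_init__(self) -> None:
        v = self.values.to_numpy(float)
        if np.any(v < 0):
            raise ValueError("proportions must be nonnegative")
        if not np.allclose(v.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("proportion rows must sum to 1")

    @property
    def spot_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def type_names(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    def predominant_type(self) -> pd.Series:
        """Argmax type per spot; ties broken by lexicographically first type."""
        cols_sorted = sorted(self.values.columns, key=str)
        return self.values[cols_sorted].idxmax(axis=1).astype(str)


def fuse_and_profile(
    tensor: CorrelationTensor, labels: pd.Series, fuse_mode: str = "minmax"
) -> pd.DataFrame:
    """Average the tensor layers and then rows within each cell type.

    Returns a (type x spot) DataFrame of mean fused correlations. Every cell
    in the tensor must be labeled; empty types raise.
    """
    if fuse_mode not in ("minmax", "raw"):
        raise ValueError("fuse_mode must be 'minmax' or 'raw'")
    labels = labels.astype(str)
    missing = [c for c in tensor.cell_ids if c not in labels.index]
    if missing:
        raise ValueError(f"cells missing labels: {missing[:10]}")
    layers = tensor.values
    if fuse_mode == "minmax":
        scaled = np.empty_like(layers)
        for i in range(3):
            lo, hi = layers[i].min(), layers[i].max()
            scaled[i] = (layers[i] - lo) / (hi - lo) if hi > lo else 0.0
        fused = scaled.mean(axis=0)
    else:
        fused = layers.mean(axis=0)
    fused_df = pd.DataFrame(fused, index=tensor.cell_ids, columns=tensor.spot_ids)
    cell_types = labels.loc[tensor.cell_ids]
    profiles = fused_df.groupby(cell_types).mean()
    if (profiles.index == "").any():
        raise ValueError("empty cell-type label")
    profiles.index = profiles.index.astype(str)
    return profiles.sort_index()


def proportions(profiles: pd.DataFrame, fuse_mode: str = "minmax") -> ProportionMatrix:
    """Normalize per-type spot profiles into per-spot proportions.

    Negative profile entries are clipped to 0 first; spots whose profile sums
    to 0 fall back to the uniform distribution (logged).
    """
    if profiles.shape[0] < 1:
        raise ValueError("need at least one cell type")
    mat = profiles.to_numpy(float).T.copy()  # spots x types
    mat[mat < 0] = 0.0
    sums = mat.sum(axis=1)
    zero = sums == 0
    if zero.any():
        logger.warning("proportions: %d spot(s) with all-zero profile set to uniform",
                       int(zero.sum()))
        mat[zero] = 1.0
        sums[zero] = mat.shape[1]
    mat = mat / sums[:, None]
    df = pd.DataFrame(mat, index=profiles.columns, columns=profiles.index)
    return ProportionMatrix(df, fuse_mode=fuse_mode)


def ari(clusters, regions) -> float:
    """Adjusted Rand index between two labelings of the same spot set.

    Evaluated with exact binomial coefficients from the contingency table.
    Degenerate single-cluster-vs-single-cluster input is defined as 1; a zero
    adjustment denominator (e.g. both partitions all-singletons) returns 1
    when the index equals its expectation.
    """
    c = pd.Series(list(clusters), dtype=object)
    r = pd.Series(list(regions), dtype=object)
    if len(c) == 0:
        raise ValueError("empty input")
    if len(c) != len(r):
        raise ValueError("labelings must cover the same spot set")
    n = len(c)
    table = pd.crosstab(c, r).to_numpy(int)
    if table.shape == (1, 1):
        return 1.0
    sum_ij = sum(comb(int(w), 2) for w in table.ravel())
    a = [comb(int(x), 2) for x in table.sum(axis=1)]
    b = [comb(int(x), 2) for x in table.sum(axis=0)]
    expected = sum(a) * sum(b) / comb(n, 2)
    max_index = 0.5 * (sum(a) + sum(b))
    denom = max_index - expected
    if denom == 0:
        return 1.0 if sum_ij == expected else 0.0
    return float((sum_ij - expected) / denom)
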