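"""Colocalization of cell-type attribution maps (ICC) and spatial enrichment.

ICC between two attribution maps is the mean of three components computed on
the flattened spot-bearing pixels: Gaussian mutual information (same clamped
closed form as the correlation module), cosine similarity, and Pearson
correlation. The enrichment test asks whether a gene's expressed spots overlap
the high-attribution spots more than chance, via the upper-tail
hypergeometric probability evaluated with exact integer binomials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from emci.attribution import CellTypeAttribution, high_attribution_spots
from emci.correlation import mutual_information, pearson
from emci.imaging import SpotPixelMap
from emci.preprocess import SpatialDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ICCMatrix",
    "EnrichmentTest",
    "icc_components",
    "icc_matrix",
    "hypergeometric_p",
    "attribution_enrichment",
]


@dataclass
class ICCMatrix:
    """Symmetric q x q colocalization matrix with its three component matrices."""

    values: pd.DataFrame
    mi: pd.DataFrame
    sc: pd.DataFrame
    pcc: pd.DataFrame
    vector_length: int

    def __post_init__(self) -> None:
        v = self.values.to_numpy(float)
        if not np.allclose(v, v.T):
            raise ValueError("ICC matrix must be symmetric")

    def delta(self, other: "ICCMatrix") -> pd.DataFrame:
        """Elementwise ICC(other) - ICC(self) for matched type pairs."""
        return other.values - self.values


@dataclass
class EnrichmentTest:
    gene: str
    M: int  # background spots
    N: int  # gene-expressed spots
    H: int  # high-attribution spots
    C: int  # overlap
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na = np.sqrt(a @ a)
    nb = np.sqrt(b @ b)
    if na == 0 or nb == 0:
        logger.debug("cosine: zero vector, returning 0")
        return 0.0
    return float((a @ b) / (na * nb))


def icc_components(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """(MI, cosine, PCC) between two flattened attribution vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    return mutual_information(a, b), _cosine(a, b), pearson(a, b)


def icc_matrix(
    maps: dict[str, CellTypeAttribution],
    pmap: SpotPixelMap | None = None,
) -> ICCMatrix:
    """Pairwise ICC over cell-type attribution maps.

    Grids are flattened over spot-bearing pixels when ``pmap`` is given
    (recommended: constant background pixels inflate correlations), else over
    the full grid.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 attribution maps")
    types = sorted(maps)
    shapes = {maps[t].values.shape for t in types}
    if len(shapes) > 1:
        raise ValueError(f"maps have mixed raster shapes: {shapes}")
    if pmap is not None:
        mask = pmap.mask()
        vecs = {t: maps[t].values[mask] for t in types}
    else:
        vecs = {t: maps[t].values.ravel() for t in types}
    T = len(next(iter(vecs.values())))

    q = len(types)
    mi = np.zeros((q, q))
    sc = np.zeros((q, q))
    pc = np.zeros((q, q))
    for i, ti in enumerate(types):
        for j in range(i, q):
            m, s, p = icc_components(vecs[ti], vecs[types[j]])
            mi[i, j] = mi[j, i] = m
            sc[i, j] = sc[j, i] = s
            pc[i, j] = pc[j, i] = p
    icc = (mi + sc + pc) / 3.0

    def _df(x: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(x, index=types, columns=types)

    return ICCMatrix(_df(icc), _df(mi), _df(sc), _df(pc), T)


def hypergeometric_p(M: int, N: int, H: int, C: int) -> float:
    """Upper-tail hypergeometric probability P(overlap >= C).

    Exact integer-binomial arithmetic; C = 0 returns exactly 1.0.
    """
    M, N, H, C = int(M), int(N), int(H), int(C)
    if min(M, N, H, C) < 0 or N > M or H > M:
        raise ValueError(f"inconsistent counts M={M}, N={N}, H={H}, C={C}")
    if C > min(H, N):
        raise ValueError(f"overlap C={C} exceeds min(H, N)={min(H, N)}")
    if C < max(0, H + N - M):
        # requested lower bound below the support: the tail is the full mass
        C = max(0, H + N - M)
    if C == 0 and max(0, H + N - M) == 0:
        return 1.0
    total = comb(M, H)
    num = sum(comb(N, k) * comb(M - N, H - k) for k in range(C, min(H, N) + 1))
    return float(num / total)


def attribution_enrichment(
    att: CellTypeAttribution,
    st: SpatialDataset,
    gene: str,
    pmap: SpotPixelMap,
    top_frac: float = 0.2,
) -> EnrichmentTest:
    """Test overlap between a gene's expressed spots and high-attribution spots.

    "Expressed" means value > 0. M counts all spots in the dataset.
    """
    if gene not in st.gene_ids:
        raise ValueError(f"gene {gene!r} absent from the spatial dataset")
    gi = st.gene_ids.index(gene)
    expressed = {s for s, v in zip(st.spot_ids, st.values[:, gi]) if v > 0}
    high = high_attribution_spots(att, pmap, top_frac=top_frac)
    M = st.n_spots
    N = len(expressed)
    H = len(high)
    C = len(expressed & high)
    p = hypergeometric_p(M, N, H, C)
    return EnrichmentTest(gene=gene, M=M, N=N, H=H, C=C, p_value=p)
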