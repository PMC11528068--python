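"""Superpixel surrogate explanations and cell-type attribution maps.

A pseudo-image is partitioned into spatially contiguous superpixels (spot
pixels only). Binary on/off masks over superpixels generate perturbed images
(off segments replaced by the per-channel mean over spot pixels), the frozen
classifier scores them, and a depth-limited regression tree is fitted to
(mask -> target-class score) with proximity weights
``exp(-d_cos^2 / sigma^2)``. The tree's impurity importances, normalized to
sum to 1, are spread over each segment's pixels to form the attribution grid;
per-type maps are elementwise means over cells of one type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from emci.imaging import PseudoImage, SpotPixelMap

logger = logging.getLogger(__name__)

__all__ = [
    "SuperpixelSegmentation",
    "AttributionMap",
    "CellTypeAttribution",
    "segment_superpixels",
    "explain",
    "aggregate_by_type",
    "high_attribution_spots",
]

KERNEL_SIGMA = 0.25
TREE_DEPTH = 3


@dataclass
class SuperpixelSegmentation:
    """Partition of the spot-bearing pixels into K contiguous segments."""

    segment_of_pixel: dict[tuple[int, int], int]
    K: int
    method: str = "grid"

    def __post_init__(self) -> None:
        seen = sorted(set(self.segment_of_pixel.values()))
        if seen != list(range(self.K)):
            raise ValueError("segment ids must be exactly 0..K-1, all nonempty")

    def pixels_of(self, seg: int) -> list[tuple[int, int]]:
        return [px for px, s in self.segment_of_pixel.items() if s == seg]

    def sizes(self) -> np.ndarray:
        counts = np.zeros(self.K, dtype=int)
        for s in self.segment_of_pixel.values():
            counts[s] += 1
        return counts


@dataclass
class AttributionMap:
    """Per-pixel importance grid for one cell's prediction; background is 0."""

    values: np.ndarray
    cell_id: str
    target: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("attribution values must be finite")


@dataclass
class CellTypeAttribution:
    """Elementwise mean of member-cell attribution grids for one cell type."""

    values: np.ndarray
    cell_type: str
    n_cells: int

    def spot_values(self, pmap: SpotPixelMap) -> pd.Series:
        vals = {s: float(self.values[r, c]) for s, (r, c) in pmap.pixel_of_spot.items()}
        return pd.Series(vals, name=self.cell_type)


def _equal_count_splits(sorted_vals: np.ndarray, n_bins: int) -> list[np.ndarray]:
    """Split a sorted index array into n_bins contiguous near-equal chunks."""
    return [np.array(c) for c in np.array_split(sorted_vals, n_bins)]


def segment_superpixels(pmap: SpotPixelMap, K: int = 40) -> SuperpixelSegmentation:
    """Tile the spot pixels into K contiguous, near-equal-count segments.

    Pixels are first banded into rows of near-equal pixel count, then each
    band is cut column-wise into near-equal chunks; chunk counts per band sum
    to exactly K.
    """
    pixels = sorted(pmap.spots_of_pixel.keys())
    n_pix = len(pixels)
    if K > n_pix:
        raise ValueError(f"K={K} exceeds the number of spot pixels ({n_pix})")
    if K < 1:
        raise ValueError("K must be >= 1")
    seg: dict[tuple[int, int], int] = {}
    if K == n_pix:
        for i, px in enumerate(pixels):
            seg[px] = i
        return SuperpixelSegmentation(seg, K)

    rows = np.array([p[0] for p in pixels])
    cols = np.array([p[1] for p in pixels])
    h_span = rows.max() - rows.min() + 1
    w_span = cols.max() - cols.min() + 1
    aspect = h_span / w_span
    gr = int(round(np.sqrt(K * aspect)))
    gr = min(max(gr, 1), K)

    order = np.lexsort((cols, rows))  # row-major
    bands = _equal_count_splits(order, gr)
    # chunk counts per band: proportional to band size, each in [1, band size],
    # summing to exactly K (greedy largest-load assignment)
    sizes = [len(b) for b in bands]
    per_band = [1] * gr
    for _ in range(K - gr):
        loads = [
            (sizes[i] / per_band[i]) if per_band[i] < sizes[i] else -1.0
            for i in range(gr)
        ]
        per_band[int(np.argmax(loads))] += 1
    seg_id = 0
    for band, n_chunks in zip(bands, per_band):
        band = band[np.lexsort((rows[band], cols[band]))]  # column-major inside band
        for chunk in _equal_count_splits(band, n_chunks):
            for i in chunk:
                seg[pixels[i]] = seg_id
            seg_id += 1
    _repair_contiguity(seg, K)
    _balance_sizes(seg, K)
    return SuperpixelSegmentation(seg, K)


def _components(pixels: set[tuple[int, int]]) -> list[set[tuple[int, int]]]:
    """8-connected components of a pixel set."""
    remaining = set(pixels)
    comps = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            r, c = frontier.pop()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    nb = (r + dr, c + dc)
                    if nb in remaining:
                        remaining.discard(nb)
                        comp.add(nb)
                        frontier.append(nb)
        comps.append(comp)
    return comps


def _repair_contiguity(seg: dict[tuple[int, int], int], K: int,
                       max_rounds: int = 20) -> None:
    """Reassign stray 8-connected components to the smallest adjacent segment.

    Layout holes can split a box-tiled segment; each segment keeps its largest
    component and donates the rest to touching neighbors (no-op on hole-free
    layouts). Isolated islands with no neighbor stay put.
    """
    for _ in range(max_rounds):
        sizes = [0] * K
        members: list[set[tuple[int, int]]] = [set() for _ in range(K)]
        for px, s in seg.items():
            members[s].add(px)
            sizes[s] += 1
        changed = False
        for s in range(K):
            comps = _components(members[s])
            if len(comps) <= 1:
                continue
            comps.sort(key=len, reverse=True)
            for comp in comps[1:]:
                adjacent = set()
                for (r, c) in comp:
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            nb = (r + dr, c + dc)
                            t = seg.get(nb)
                            if t is not None and t != s:
                                adjacent.add(t)
                if not adjacent:
                    continue
                target = min(adjacent, key=lambda t: (sizes[t], t))
                for px in comp:
                    seg[px] = target
                sizes[target] += len(comp)
                sizes[s] -= len(comp)
                changed = True
        if not changed:
            return


def _neighbors8(px: tuple[int, int]):
    r, c = px
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr or dc:
                yield (r + dr, c + dc)


def _balance_sizes(seg: dict[tuple[int, int], int], K: int,
                   max_steps: int = 500) -> None:
    """Nudge boundary pixels between adjacent segments so sizes stay within
    roughly +/-40% of the mean, preserving 8-connectivity of the donor."""
    members: list[set[tuple[int, int]]] = [set() for _ in range(K)]
    for px, s in seg.items():
        members[s].add(px)
    mean = len(seg) / K

    def _move_one(into: int) -> bool:
        candidates = []
        for px in members[into]:
            for nb in _neighbors8(px):
                donor = seg.get(nb)
                if donor is not None and donor != into and len(members[donor]) > len(members[into]):
                    candidates.append((len(members[donor]), donor, nb))
        for _, donor, px in sorted(candidates, reverse=True):
            rest = members[donor] - {px}
            if rest and len(_components(rest)) == 1:
                members[donor].discard(px)
                members[into].add(px)
                seg[px] = into
                return True
        return False

    def _shed_one(frm: int) -> bool:
        candidates = []
        for px in members[frm]:
            for nb in _neighbors8(px):
                into = seg.get(nb)
                if into is not None and into != frm and len(members[into]) < len(members[frm]) - 1:
                    candidates.append((len(members[into]), into, px))
        for _, into, px in sorted(candidates):
            rest = members[frm] - {px}
            if rest and len(_components(rest)) == 1:
                members[frm].discard(px)
                members[into].add(px)
                seg[px] = into
                return True
        return False

    for _ in range(max_steps):
        order = sorted(range(K), key=lambda s: len(members[s]))
        smallest, largest = order[0], order[-1]
        if len(members[smallest]) < 0.6 * mean:
            if _move_one(smallest):
                continue
        if len(members[largest]) > 1.4 * mean:
            if _shed_one(largest):
                continue
        break


def _perturb_batch(
    image: np.ndarray,
    seg: SuperpixelSegmentation,
    masks: np.ndarray,
    spot_pixels: list[tuple[int, int]],
) -> np.ndarray:
    """Build perturbed images: off segments -> per-channel mean over spot pixels."""
    rr = np.array([p[0] for p in spot_pixels])
    cc = np.array([p[1] for p in spot_pixels])
    fill = image[rr, cc, :].mean(axis=0)  # per-channel mean
    out = np.repeat(image[None], masks.shape[0], axis=0)
    for s in range(seg.K):
        px = seg.pixels_of(s)
        r = np.array([p[0] for p in px])
        c = np.array([p[1] for p in px])
        off = np.where(masks[:, s] == 0)[0]
        # pair (r, c) per pixel; broadcasting off against the pixel list
        out[off[:, None], r[None, :], c[None, :], :] = fill
    return out


def explain(
    clf,
    image: PseudoImage | np.ndarray,
    seg: SuperpixelSegmentation,
    target: int | str,
    n_samples: int = 500,
    seed: int = 0,
    head: int = 0,
    masks: np.ndarray | None = None,
) -> AttributionMap:
    """Fit a local surrogate tree and return the per-pixel attribution grid.

    ``clf`` is any object with ``predict_scores(images) -> list of (n, q)
    score arrays`` (a TrainedClassifier, or a stub in tests); ``target`` is a
    class name or column index for the chosen head. ``masks`` overrides the
    random mask draw (used by exhaustive-enumeration oracles); the all-ones
    mask is always included.
    """
    if isinstance(image, PseudoImage):
        arr = image.channels
        cell_id = image.cell_id
    else:
        arr = np.asarray(image, dtype=float)
        cell_id = ""
    K = seg.K
    rng = np.random.default_rng(seed)
    if masks is None:
        masks = rng.integers(0, 2, size=(n_samples, K)).astype(float)
        masks[0, :] = 1.0
    else:
        masks = np.asarray(masks, dtype=float)
        if not np.any(np.all(masks == 1.0, axis=1)):
            masks = np.vstack([np.ones((1, K)), masks])

    spot_pixels = sorted(seg.segment_of_pixel.keys())
    batch = _perturb_batch(arr, seg, masks, spot_pixels)
    scores = clf.predict_scores(batch)
    if isinstance(scores, list):
        scores = scores[head]
    scores = np.asarray(scores, dtype=float)
    if isinstance(target, str):
        names = clf.class_names[head]
        target_idx = names.index(target)
    else:
        target_idx = int(target)
    y = scores[:, target_idx] if scores.ndim == 2 else scores

    # proximity: cosine distance between each mask and the all-ones mask
    on = masks.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(on > 0, np.sqrt(on / K), 0.0)
    d = 1.0 - cos
    weights = np.exp(-(d**2) / KERNEL_SIGMA**2)

    values = np.zeros_like(arr[..., 0])
    if np.ptp(y) == 0.0:
        logger.debug("explain: constant model output; returning all-zero map")
        return AttributionMap(values, cell_id, str(target))

    tree = DecisionTreeRegressor(max_depth=TREE_DEPTH, random_state=seed)
    tree.fit(masks, y, sample_weight=weights)
    imp = tree.feature_importances_
    total = imp.sum()
    if total > 0:
        imp = imp / total
    for s in range(K):
        px = seg.pixels_of(s)
        share = imp[s] / len(px)
        for (r, c) in px:
            values[r, c] = share
    return AttributionMap(values, cell_id, str(target))


def aggregate_by_type(
    maps: list[AttributionMap], labels: pd.Series
) -> dict[str, CellTypeAttribution]:
    """Average per-cell attribution grids into one map per cell type.

    ``labels`` maps cell id -> type; types with zero mapped cells are omitted
    with a warning.
    """
    shapes = {m.values.shape for m in maps}
    if len(shapes) > 1:
        raise ValueError(f"attribution maps have mixed shapes: {shapes}")
    by_cell = {m.cell_id: m for m in maps}
    out: dict[str, CellTypeAttribution] = {}
    for t in sorted(labels.astype(str).unique()):
        ids = [str(c) for c in labels.index[labels.astype(str) == t]]
        member = [by_cell[c].values for c in ids if c in by_cell]
        if not member:
            logger.warning("aggregate_by_type: no attribution maps for type %r", t)
            continue
        out[t] = CellTypeAttribution(np.mean(member, axis=0), t, len(member))
    return out


def high_attribution_spots(
    att: CellTypeAttribution, pmap: SpotPixelMap, top_frac: float = 0.2
) -> set[str]:
    """Spots whose attribution value reaches the top ``top_frac`` quantile.

    The threshold is the (1 - top_frac) quantile of per-spot values; ties at
    the threshold are included.
    """
    if not (0 < top_frac < 1):
        raise ValueError("top_frac must lie in (0, 1)")
    vals = att.spot_values(pmap)
    thresh = float(np.quantile(vals.to_numpy(), 1.0 - top_frac))
    return set(vals.index[vals >= thresh])
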