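"""Rasterization of spot layouts and per-cell RGB pseudo-images.

Each cell's three correlation row-vectors are painted onto the spot layout as
grayscale channels (MI -> red, R2 -> green, PCC -> blue) and stacked into an
H x W x 3 pseudo-image. Channel values are min-max scaled to [0, 1] with
*global* per-metric bounds so images are comparable across cells; non-spot
(background) pixels are exactly 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from emci.correlation import CorrelationTensor

logger = logging.getLogger(__name__)

__all__ = [
    "SpotPixelMap",
    "PseudoImage",
    "build_pixel_map",
    "choose_raster",
    "global_bounds",
    "render_cell_image",
    "render_all",
]

DEFAULT_RASTER = 64


@dataclass
class SpotPixelMap:
    """Deterministic spot -> pixel assignment for a fixed raster."""

    H: int
    W: int
    pixel_of_spot: dict[str, tuple[int, int]]
    spots_of_pixel: dict[tuple[int, int], list[str]]
    bbox: tuple[float, float, float, float]  # (x_min, x_max, y_min, y_max)

    @property
    def spot_ids(self) -> list[str]:
        return list(self.pixel_of_spot)

    @property
    def n_pixels(self) -> int:
        return len(self.spots_of_pixel)

    def mask(self) -> np.ndarray:
        """Boolean H x W array, True at spot-bearing pixels."""
        m = np.zeros((self.H, self.W), dtype=bool)
        for (r, c) in self.spots_of_pixel:
            m[r, c] = True
        return m

    def save(self, path: str | Path) -> None:
        rows = [
            {"spot_id": s, "row": rc[0], "col": rc[1]}
            for s, rc in self.pixel_of_spot.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class PseudoImage:
    """H x W x 3 raster in [0, 1] for one cell; background pixels are 0."""

    channels: np.ndarray
    cell_id: str
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 3 or self.channels.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 channels, got {self.channels.shape}")
        if self.channels.min() < 0 or self.channels.max() > 1:
            raise ValueError("channel values must lie in [0, 1]")
        if np.any(self.channels[~self.mask] != 0):
            raise ValueError("background pixels must be exactly 0")

    def to_png(self, path: str | Path) -> None:
        from PIL import Image

        arr = np.round(self.channels * 255).astype(np.uint8)
        Image.fromarray(arr, mode="RGB").save(path)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(int)


def build_pixel_map(coords: pd.DataFrame, H: int, W: int) -> SpotPixelMap:
    """Map spot coordinates onto an H x W raster.

    x maps linearly to columns [0, W-1]; y maps to rows with the vertical axis
    flipped (max y -> row 0). Indices are rounded half-up; spots landing on the
    same pixel are recorded as collisions.

    ``coords`` is indexed by spot id with columns x, y (see
    ``SpatialDataset.coords_frame``).
    """
    if H < 4 or W < 4:
        raise ValueError("raster dimensions must be >= 4")
    if len(coords) == 0:
        raise ValueError("need at least one spot")
    x = coords["x"].to_numpy(float)
    y = coords["y"].to_numpy(float)
    x_min, x_max = float(x.min()), float(x.max())
    y_min, y_max = float(y.min()), float(y.max())
    x_span = x_max - x_min
    y_span = y_max - y_min
    if x_span == 0 and y_span == 0 and len(coords) > 1:
        logger.warning("all %d spots coincident; mapping to a single pixel", len(coords))
    cols = _round_half_up((x - x_min) / x_span * (W - 1)) if x_span > 0 else np.zeros(len(x), int)
    rows = _round_half_up((y_max - y) / y_span * (H - 1)) if y_span > 0 else np.zeros(len(y), int)

    pixel_of_spot: dict[str, tuple[int, int]] = {}
    spots_of_pixel: dict[tuple[int, int], list[str]] = {}
    for sid, r, c in zip(coords.index.astype(str), rows, cols):
        pixel_of_spot[sid] = (int(r), int(c))
        spots_of_pixel.setdefault((int(r), int(c)), []).append(sid)
    n_coll = len(pixel_of_spot) - len(spots_of_pixel)
    if n_coll:
        logger.info("build_pixel_map: %d spot(s) share pixels with another", n_coll)
    return SpotPixelMap(H, W, pixel_of_spot, spots_of_pixel, (x_min, x_max, y_min, y_max))


def choose_raster(coords: pd.DataFrame, default: int = DEFAULT_RASTER) -> tuple[int, int]:
    """Pick (H, W): the integer grid dimensions when coordinates are gridded,
    else ``default`` square. Never below 4 on either axis."""
    x = coords["x"].to_numpy(float)
    y = coords["y"].to_numpy(float)

    def _grid_size(v: np.ndarray) -> int | None:
        uniq = np.unique(v)
        if len(uniq) < 2:
            return None
        steps = np.diff(uniq)
        step = steps.min()
        if step <= 0:
            return None
        # gridded iff every unique value sits on a multiple of the min step
        k = (uniq - uniq[0]) / step
        if np.allclose(k, np.round(k), atol=1e-6):
            return int(round(k[-1])) + 1
        return None

    gw, gh = _grid_size(x), _grid_size(y)
    if gw is not None and gh is not None and gw <= default and gh <= default:
        return max(gh, 4), max(gw, 4)
    return default, default


def global_bounds(tensor: CorrelationTensor) -> list[tuple[float, float]]:
    """Per-metric (lo, hi) min-max bounds over the whole tensor."""
    return [
        (float(tensor.values[i].min()), float(tensor.values[i].max()))
        for i in range(3)
    ]


def render_cell_image(
    tensor: CorrelationTensor,
    cell_index: int,
    pmap: SpotPixelMap,
    norm: list[tuple[float, float]] | None = None,
) -> PseudoImage:
    """Render one cell's pseudo-image from its three correlation row-vectors.

    ``norm`` holds per-metric (lo, hi) bounds; defaults to global bounds over
    the tensor. Collided pixels receive the mean of their spots' scaled values.
    """
    if not (0 <= cell_index < tensor.n_cells):
        raise IndexError(f"cell_index {cell_index} out of range [0, {tensor.n_cells})")
    if norm is None:
        norm = global_bounds(tensor)
    spot_index = {s: k for k, s in enumerate(tensor.spot_ids)}
    channels = np.zeros((pmap.H, pmap.W, 3), dtype=float)
    mask = np.zeros((pmap.H, pmap.W), dtype=bool)
    for i in range(3):
        lo, hi = norm[i]
        row = tensor.values[i, cell_index, :]
        if hi > lo:
            scaled = np.clip((row - lo) / (hi - lo), 0.0, 1.0)
        else:
            scaled = np.zeros_like(row)
        for (r, c), spots in pmap.spots_of_pixel.items():
            vals = [scaled[spot_index[s]] for s in spots if s in spot_index]
            if vals:
                channels[r, c, i] = float(np.mean(vals))
                mask[r, c] = True
    return PseudoImage(channels, tensor.cell_ids[cell_index], mask)


def render_all(
    tensor: CorrelationTensor,
    pmap: SpotPixelMap,
    norm: list[tuple[float, float]] | None = None,
) -> np.ndarray:
    """Render every cell; returns an (n_cells, H, W, 3) array (vectorized)."""
    if norm is None:
        norm = global_bounds(tensor)
    spot_index = {s: k for k, s in enumerate(tensor.spot_ids)}
    n1 = tensor.n_cells
    out = np.zeros((n1, pmap.H, pmap.W, 3), dtype=float)
    scaled = np.empty_like(tensor.values)
    for i in range(3):
        lo, hi = norm[i]
        if hi > lo:
            scaled[i] = np.clip((tensor.values[i] - lo) / (hi - lo), 0.0, 1.0)
        else:
            scaled[i] = 0.0
    for (r, c), spots in pmap.spots_of_pixel.items():
        idx = [spot_index[s] for s in spots if s in spot_index]
        if idx:
            out[:, r, c, :] = scaled[:, :, idx].mean(axis=2).T
    return out
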