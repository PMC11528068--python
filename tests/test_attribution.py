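import itertools

import numpy as np
import pandas as pd
import pytest

from emci.attribution import (
    AttributionMap,
    CellTypeAttribution,
    SuperpixelSegmentation,
    aggregate_by_type,
    explain,
    high_attribution_spots,
    segment_superpixels,
)
from emci.imaging import SpotPixelMap, build_pixel_map


def _block_pmap(h, w):
    """Full h x w block of spots, one per pixel."""
    coords = pd.DataFrame(
        {"x": [c for r in range(h) for c in range(w)],
         "y": [h - 1 - r for r in range(h) for c in range(w)]},
        index=[f"s{r}_{c}" for r in range(h) for c in range(w)],
    )
    return build_pixel_map(coords, max(h, 4), max(w, 4))


class TestSegmentation:
    def test_quadrants_on_square_block(self):
        pmap = _block_pmap(10, 10)
        seg = segment_superpixels(pmap, K=4)
        sizes = seg.sizes()
        assert list(sizes) == [25, 25, 25, 25]
        # each segment is an exact quadrant
        for s in range(4):
            px = seg.pixels_of(s)
            rows = {p[0] for p in px}
            cols = {p[1] for p in px}
            assert len(rows) == 5 and len(cols) == 5

    def test_singleton_segments(self):
        pmap = _block_pmap(4, 5)
        seg = segment_superpixels(pmap, K=20)
        assert seg.K == 20
        assert np.all(seg.sizes() == 1)

    def test_k_exceeds_pixels_rejected(self):
        pmap = _block_pmap(4, 4)
        with pytest.raises(ValueError):
            segment_superpixels(pmap, K=17)

    def test_irregular_layout_near_equal_contiguous(self, small_pmap):
        seg = segment_superpixels(small_pmap, K=40)
        sizes = seg.sizes()
        mean = sizes.mean()
        assert sizes.min() >= 0.5 * mean
        assert sizes.max() <= 1.5 * mean
        # contiguity under 8-connectivity
        for s in range(seg.K):
            px = set(seg.pixels_of(s))
            seen = {next(iter(px))}
            frontier = list(seen)
            while frontier:
                r, c = frontier.pop()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nb = (r + dr, c + dc)
                        if nb in px and nb not in seen:
                            seen.add(nb)
                            frontier.append(nb)
            assert seen == px, f"segment {s} not contiguous"

    def test_partition_is_exact(self, small_pmap):
        seg = segment_superpixels(small_pmap, K=25)
        assert set(seg.segment_of_pixel) == set(small_pmap.spots_of_pixel)
        assert seg.sizes().sum() == small_pmap.n_pixels


class _SegmentOracle:
    """Score = mean channel-0 intensity over one planted segment's pixels."""

    class_names = [["on", "off"]]

    def __init__(self, seg, planted):
        self.px = seg.pixels_of(planted)

    def predict_scores(self, images):
        images = np.asarray(images)
        s = np.mean([images[:, r, c, 0] for (r, c) in self.px], axis=0)
        return [np.column_stack([s, 1 - s])]


class _ConstantModel:
    class_names = [["x", "y"]]

    def predict_scores(self, images):
        n = np.asarray(images).shape[0]
        return [np.full((n, 2), 0.5)]


def _segment_totals(amap: AttributionMap, seg: SuperpixelSegmentation) -> np.ndarray:
    tot = np.zeros(seg.K)
    for (r, c), s in seg.segment_of_pixel.items():
        tot[s] += amap.values[r, c]
    return tot


@pytest.fixture(scope="module")
def planted_setup():
    pmap = _block_pmap(10, 10)
    seg = segment_superpixels(pmap, K=10)
    rng = np.random.default_rng(0)
    img = rng.random((10, 10, 3))
    return pmap, seg, img


class TestExplain:
    def test_constant_model_gives_zero_map(self, planted_setup):
        _, seg, img = planted_setup
        amap = explain(_ConstantModel(), img, seg, target=0, n_samples=64, seed=0)
        assert np.all(amap.values == 0)

    def test_planted_segment_recovered(self, planted_setup):
        _, seg, img = planted_setup
        planted = 3
        oracle = _SegmentOracle(seg, planted)
        hits = 0
        for seed in range(20):
            amap = explain(oracle, img, seg, target=0, n_samples=200, seed=seed)
            hits += int(np.argmax(_segment_totals(amap, seg)) == planted)
        assert hits >= 19

    def test_sampled_matches_exhaustive_on_four_segments(self):
        pmap = _block_pmap(4, 4)
        seg = segment_superpixels(pmap, K=4)
        rng = np.random.default_rng(1)
        img = rng.random((4, 4, 3))
        oracle = _SegmentOracle(seg, 2)
        all_masks = np.array(list(itertools.product([0, 1], repeat=4)), dtype=float)
        exhaustive = explain(oracle, img, seg, target=0, masks=all_masks, seed=0)
        sampled = explain(oracle, img, seg, target=0, n_samples=500, seed=0)
        assert np.argmax(_segment_totals(exhaustive, seg)) == np.argmax(
            _segment_totals(sampled, seg)
        )

    def test_attribution_sums_to_one(self, planted_setup):
        _, seg, img = planted_setup
        amap = explain(_SegmentOracle(seg, 1), img, seg, target=0, n_samples=200, seed=0)
        assert amap.values.sum() == pytest.approx(1.0)

    def test_relabeling_invariance_exhaustive(self):
        pmap = _block_pmap(4, 4)
        seg = segment_superpixels(pmap, K=4)
        perm = [2, 0, 3, 1]
        seg_perm = SuperpixelSegmentation(
            {px: perm[s] for px, s in seg.segment_of_pixel.items()}, 4
        )
        rng = np.random.default_rng(2)
        img = rng.random((4, 4, 3))
        oracle = _SegmentOracle(seg, 1)  # reads fixed pixels, independent of labels
        all_masks = np.array(list(itertools.product([0, 1], repeat=4)), dtype=float)
        a = explain(oracle, img, seg, target=0, masks=all_masks, seed=0)
        # permute mask columns so each physical segment sees the same on/off
        # pattern under the relabeled segmentation
        masks_perm = all_masks[:, np.argsort(perm)]
        b = explain(oracle, img, seg_perm, target=0, masks=masks_perm, seed=0)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)


class TestAggregate:
    def _map(self, grid, cid, target="A"):
        return AttributionMap(np.asarray(grid, dtype=float), cid, target)

    def test_single_cell_per_type(self):
        m = self._map([[0.5, 0.0], [0.0, 0.5]], "c1")
        labels = pd.Series({"c1": "A"})
        out = aggregate_by_type([m], labels)
        np.testing.assert_array_equal(out["A"].values, m.values)

    def test_identical_maps_mean(self):
        grid = [[0.1, 0.2], [0.3, 0.4]]
        out = aggregate_by_type(
            [self._map(grid, "c1"), self._map(grid, "c2")],
            pd.Series({"c1": "A", "c2": "A"}),
        )
        np.testing.assert_allclose(out["A"].values, grid)

    def test_hand_mean(self):
        maps = [self._map([[v]], f"c{i}") for i, v in enumerate([0.0, 0.3, 0.6])]
        labels = pd.Series({f"c{i}": "A" for i in range(3)})
        out = aggregate_by_type(maps, labels)
        assert out["A"].values[0, 0] == pytest.approx(0.3)

    def test_empty_type_omitted(self):
        m = self._map([[1.0]], "c1")
        labels = pd.Series({"c1": "A", "c_missing": "B"})
        out = aggregate_by_type([m], labels)
        assert "B" not in out

    def test_aggregation_linearity(self):
        rng = np.random.default_rng(0)
        grids = [rng.random((3, 3)) for _ in range(4)]
        maps = [self._map(g, f"c{i}") for i, g in enumerate(grids)]
        labels = pd.Series({f"c{i}": "A" for i in range(4)})
        whole = aggregate_by_type(maps, labels)["A"].values
        g1 = np.mean(grids[:2], axis=0)
        g2 = np.mean(grids[2:], axis=0)
        np.testing.assert_allclose(whole, (g1 + g2) / 2, atol=1e-12)


class TestHighAttributionSpots:
    def _att_and_pmap(self, values):
        n = len(values)
        coords = pd.DataFrame(
            {"x": np.arange(n, dtype=float), "y": np.zeros(n)},
            index=[f"s{i}" for i in range(n)],
        )
        pmap = build_pixel_map(coords, 4, max(n, 4))
        grid = np.zeros((4, max(n, 4)))
        for i, v in enumerate(values):
            r, c = pmap.pixel_of_spot[f"s{i}"]
            grid[r, c] = v
        return CellTypeAttribution(grid, "A", 1), pmap

    def test_top_two_of_ten(self):
        att, pmap = self._att_and_pmap(np.arange(10) / 10.0)
        assert high_attribution_spots(att, pmap, 0.2) == {"s8", "s9"}

    def test_all_ties_included(self):
        att, pmap = self._att_and_pmap(np.full(8, 0.5))
        assert high_attribution_spots(att, pmap, 0.2) == {f"s{i}" for i in range(8)}

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(0)
        vals = rng.random(100)
        att, pmap = self._att_and_pmap(vals)
        got = high_attribution_spots(att, pmap, 0.2)
        order = np.argsort(vals)[::-1]
        thresh = np.quantile(vals, 0.8)
        expect = {f"s{i}" for i in order if vals[i] >= thresh}
        assert got == expect

    def test_bad_fraction(self):
        att, pmap = self._att_and_pmap(np.arange(5) / 5.0)
        with pytest.raises(ValueError):
            high_attribution_spots(att, pmap, 1.0)
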