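import math

import numpy as np
import pandas as pd
import pytest

from emci.attribution import CellTypeAttribution
from emci.communication import (
    attribution_enrichment,
    hypergeometric_p,
    icc_components,
    icc_matrix,
)
from emci.imaging import build_pixel_map
from emci.preprocess import SpatialDataset

from tests._oracles import direct_sum_pearson, hypergeom_enumeration


def _maps(arrays):
    return {
        f"t{i}": CellTypeAttribution(np.asarray(a, dtype=float), f"t{i}", 1)
        for i, a in enumerate(arrays)
    }


class TestICC:
    def test_zero_when_all_components_vanish(self):
        # sample rho = 0 and orthogonal vectors
        a = [[1.0, -1.0], [1.0, -1.0]]
        b = [[1.0, 1.0], [-1.0, -1.0]]
        icc = icc_matrix(_maps([a, b]))
        assert icc.values.loc["t0", "t1"] == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        icc = icc_matrix(_maps([rng.normal(size=(3, 3)) for _ in range(4)]))
        np.testing.assert_allclose(icc.values.to_numpy(), icc.values.to_numpy().T)

    def test_hand_maps_vs_component_oracles(self):
        a = np.array([[0.1, 0.4], [0.2, 0.3]])
        b = np.array([[0.3, 0.1], [0.5, 0.2]])
        icc = icc_matrix(_maps([a, b]))
        av, bv = a.ravel(), b.ravel()
        rho = direct_sum_pearson(av, bv)
        mi = -0.5 * math.log(1 - rho**2)
        sc = sum(x * y for x, y in zip(av, bv)) / math.sqrt(
            sum(x * x for x in av) * sum(y * y for y in bv)
        )
        expect = (mi + sc + rho) / 3
        assert icc.values.loc["t0", "t1"] == pytest.approx(expect, abs=1e-9)
        assert icc.mi.loc["t0", "t1"] == pytest.approx(mi, abs=1e-9)
        assert icc.sc.loc["t0", "t1"] == pytest.approx(sc, abs=1e-12)
        assert icc.pcc.loc["t0", "t1"] == pytest.approx(rho, abs=1e-12)

    def test_component_decomposition_exact(self):
        rng = np.random.default_rng(1)
        icc = icc_matrix(_maps([rng.normal(size=(4, 4)) for _ in range(3)]))
        lhs = 3.0 * icc.values.to_numpy()
        rhs = icc.mi.to_numpy() + icc.sc.to_numpy() + icc.pcc.to_numpy()
        np.testing.assert_array_equal(lhs, rhs)

    def test_independent_random_maps_mean_near_zero(self):
        rng = np.random.default_rng(2)
        vals = []
        for _ in range(200):
            a = rng.normal(size=(5, 5))
            b = rng.normal(size=(5, 5))
            m, s, p = icc_components(a.ravel(), b.ravel())
            vals.append((m + s + p) / 3)
        assert abs(np.mean(vals)) < 0.05

    def test_constant_map_flagged_components(self):
        a = np.full((2, 2), 0.5)
        b = np.array([[0.1, 0.2], [0.3, 0.4]])
        mi, sc, pcc = icc_components(a.ravel(), b.ravel())
        assert mi == 0.0 and pcc == 0.0
        assert sc == pytest.approx(
            (a.ravel() @ b.ravel())
            / (np.linalg.norm(a.ravel()) * np.linalg.norm(b.ravel()))
        )

    def test_spot_pixel_flattening(self, small_pmap):
        rng = np.random.default_rng(3)
        H, W = small_pmap.H, small_pmap.W
        maps = _maps([rng.normal(size=(H, W)) for _ in range(2)])
        icc = icc_matrix(maps, small_pmap)
        assert icc.vector_length == small_pmap.n_pixels

    def test_single_map_rejected(self):
        with pytest.raises(ValueError):
            icc_matrix(_maps([np.zeros((2, 2))]))


class TestHypergeometric:
    def test_zero_overlap_is_exactly_one(self):
        assert hypergeometric_p(50, 10, 10, 0) == 1.0

    def test_hand_example_one_sixth(self):
        assert hypergeometric_p(4, 2, 2, 2) == pytest.approx(1 / 6, abs=1e-15)

    def test_matches_enumeration_small_grid(self):
        for M in (4, 6, 8):
            for N in range(M + 1):
                for H in range(M + 1):
                    lo = max(0, H + N - M)
                    for C in range(lo, min(H, N) + 1):
                        assert hypergeometric_p(M, N, H, C) == pytest.approx(
                            hypergeom_enumeration(M, N, H, C), abs=1e-12
                        ), (M, N, H, C)

    def test_monotone_nonincreasing_in_overlap(self):
        prev = 1.1
        for C in range(0, 8):
            p = hypergeometric_p(30, 12, 8, min(C, 8))
            assert p <= prev + 1e-15
            prev = p

    def test_bounds(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            M = int(rng.integers(2, 40))
            N = int(rng.integers(0, M + 1))
            H = int(rng.integers(0, M + 1))
            lo = max(0, H + N - M)
            C = int(rng.integers(lo, min(H, N) + 1))
            p = hypergeometric_p(M, N, H, C)
            assert 0 < p <= 1

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_p(4, 5, 2, 1)
        with pytest.raises(ValueError):
            hypergeometric_p(10, 2, 2, 3)


class TestEnrichment:
    def _setup(self, n_spots=25, expressed_frac=1.0, planted=None, seed=0):
        rng = np.random.default_rng(seed)
        side = int(np.ceil(np.sqrt(n_spots)))
        spots = [f"s{i}" for i in range(n_spots)]
        coords = np.array([[i % side, i // side] for i in range(n_spots)], dtype=float)
        vals = np.zeros((n_spots, 1))
        if planted is not None:
            for i in planted:
                vals[i, 0] = 5.0
        else:
            n_on = int(round(expressed_frac * n_spots))
            vals[:n_on, 0] = 1.0
        st = SpatialDataset(vals, ["lig1"], spots, coords)
        pmap = build_pixel_map(st.coords_frame(), max(side, 4), max(side, 4))
        att_vals = rng.random(n_spots)
        grid = np.zeros((pmap.H, pmap.W))
        for i, s in enumerate(spots):
            r, c = pmap.pixel_of_spot[s]
            grid[r, c] = att_vals[i]
        att = CellTypeAttribution(grid, "A", 1)
        return att, st, pmap

    def test_gene_everywhere_p_is_one(self):
        att, st, pmap = self._setup(expressed_frac=1.0)
        res = attribution_enrichment(att, st, "lig1", pmap)
        assert res.N == res.M
        assert res.C == res.H
        assert res.p_value == 1.0

    def test_gene_nowhere_p_is_one(self):
        att, st, pmap = self._setup(expressed_frac=0.0)
        res = attribution_enrichment(att, st, "lig1", pmap)
        assert res.N == 0 and res.C == 0
        assert res.p_value == 1.0

    def test_planted_block_highly_significant(self):
        rng = np.random.default_rng(1)
        n = 100
        att, st, pmap = self._setup(n_spots=n, expressed_frac=0.0, seed=1)
        # plant: the top-20 attribution spots are exactly the expressed spots
        vals = att.spot_values(pmap)
        top = vals.sort_values(ascending=False).index[:20]
        planted = [int(s[1:]) for s in top]
        st.values[:] = 0.0
        for i in planted:
            st.values[i, 0] = 3.0
        res = attribution_enrichment(att, st, "lig1", pmap)
        assert (res.M, res.N, res.H, res.C) == (100, 20, 20, 20)
        assert res.p_value < 1e-15
        assert res.significant

    def test_absent_gene_rejected(self):
        att, st, pmap = self._setup()
        with pytest.raises(ValueError, match="nope"):
            attribution_enrichment(att, st, "nope", pmap)
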