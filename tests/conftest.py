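import numpy as np
import pandas as pd
import pytest

from emci import correlation, imaging, preprocess, synthetic


@pytest.fixture(scope="session")
def small_fixture():
    """Paired synthetic dataset: 3 types, ~200 reference cells, gridded spots."""
    cfg = synthetic.SyntheticConfig(q=3, n_cells=400, seed=1)
    ref, st, truth = synthetic.make_fixture(cfg)
    sc, st = preprocess.filter_and_align(ref, st)
    return sc, st, truth


@pytest.fixture(scope="session")
def small_tensor(small_fixture):
    sc, st, _ = small_fixture
    return correlation.build_tensor(sc, st)


@pytest.fixture(scope="session")
def small_pmap(small_fixture):
    _, st, _ = small_fixture
    return imaging.build_pixel_map(st.coords_frame(), 14, 14)


@pytest.fixture()
def tiny_sc():
    values = np.array(
        [
            [1.0, 0.0, 2.0, 3.0],
            [0.0, 1.0, 1.0, 0.0],
            [2.0, 2.0, 0.0, 1.0],
        ]
    )
    labels = pd.DataFrame(
        {"cell_type": ["A", "B", "A"]}, index=["c1", "c2", "c3"]
    )
    return preprocess.GeneExpressionMatrix(
        values, ["g1", "g2", "g3", "g4"], ["c1", "c2", "c3"], labels
    )


@pytest.fixture()
def tiny_st():
    values = np.array(
        [
            [1.0, 1.0, 0.0, 2.0],
            [0.0, 2.0, 1.0, 1.0],
        ]
    )
    coords = np.array([[0.0, 0.0], [1.0, 1.0]])
    return preprocess.SpatialDataset(
        values, ["g1", "g2", "g3", "g4"], ["s1", "s2"], coords
    )
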