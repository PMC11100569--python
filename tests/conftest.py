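import numpy as np
import pandas as pd
import pytest

from gliospat.tissue import CellTable


def make_cells(xy, labels, region_id="r1", case_id="c1", region_class="edge",
               markers=None, populations=None):
    xy = np.asarray(xy, float)
    df = pd.DataFrame({
        "cell_id": [f"{region_id}_c{i}" for i in range(len(xy))],
        "x": xy[:, 0], "y": xy[:, 1],
        "case_id": case_id, "region_id": region_id,
        "region_class": region_class,
        "population": np.asarray(labels, dtype=str),
    })
    marker_cols = []
    if markers is not None:
        for name, vals in markers.items():
            df[name] = np.asarray(vals, float)
            marker_cols.append(name)
    return CellTable(df, marker_cols=marker_cols, populations=populations)


def csr_cells(n, n_pop=2, size=500.0, seed=0, **kw):
    """Complete-spatial-randomness region with uniformly random labels."""
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0, size, (n, 2))
    labels = rng.choice([chr(65 + i) for i in range(n_pop)], n)
    return make_cells(xy, labels, **kw)


@pytest.fixture(scope="session")
def sim_region():
    from gliospat.simulate import TissueConfig, simulate_region

    return simulate_region(TissueConfig(seed=11))


@pytest.fixture(scope="session")
def sim_spots():
    from gliospat.simulate import SpotSimConfig, simulate_spots

    return simulate_spots(SpotSimConfig(seed=11, low_library_fraction=0.1))
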