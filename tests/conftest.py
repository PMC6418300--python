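import numpy as np
import pandas as pd
import pytest

import twinpath as tp


@pytest.fixture
def toy_csv(tmp_path):
    """3-pair toy file: 2 MZ, 1 DZ, two items, canonical column names."""
    path = tmp_path / "toy.csv"
    pd.DataFrame({
        "pair_id": [1, 2, 3],
        "zygosity": ["MZ", "MZ", "DZ"],
        "item1_t1": [1.0, 2.0, 3.0], "item1_t2": [2.0, 1.0, 4.0],
        "item2_t1": [2.0, 3.0, 2.0], "item2_t2": [3.0, 2.0, 1.0],
    }).to_csv(path, index=False)
    return path


@pytest.fixture(scope="session")
def ace_dataset():
    """Univariate ACE data: a^2=0.5, c^2=0.25, e^2=0.25, 2000 pairs/group."""
    params = tp.UnivariateACEParams(a=np.sqrt(0.5), c=np.sqrt(0.25),
                                    e=np.sqrt(0.25))
    cfg = tp.SimConfig(n_mz=2000, n_dz=2000, model="univariate_ace",
                       parameters=params, seed=11)
    return tp.simulate(cfg), params


@pytest.fixture(scope="session")
def small_item_dataset():
    """6-item common-pathway data at the default study scale (continuous)."""
    from twinpath.simulate import default_item_params
    cfg = tp.SimConfig(n_mz=278, n_dz=478, model="cpm",
                       parameters=default_item_params(), seed=7)
    return tp.simulate(cfg)


@pytest.fixture(scope="session")
def item_stage_report(small_item_dataset):
    """Fitted item-level ladder on the default-scale dataset (shared: the
    eight multivariate fits are the expensive part of the suite)."""
    return tp.run_item_stage(small_item_dataset, n_restarts=1, seed=0)


@pytest.fixture(scope="session")
def tiny_item_dataset():
    """Small 6-item dataset for structural (EP/moment) checks only."""
    from twinpath.simulate import default_item_params
    cfg = tp.SimConfig(n_mz=30, n_dz=40, model="cpm",
                       parameters=default_item_params(), seed=5)
    return tp.simulate(cfg)
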