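import warnings
from types import SimpleNamespace

import numpy as np
import pytest

import occutrait as ot


@pytest.fixture(scope="session")
def tiny_world():
    """Small mixed-record-type world with one implanted mediation."""
    cfg = ot.WorldConfig(
        grid_size=12, years=12, n_drivers=3, n_groups=2, species_per_group=6,
        n_traits=2, beta=[1.0, -0.8, 0.0], mediation_list=[(0, 0, 0.8)],
        driver_trend=[0.03, 0.0, 0.0], visits_per_year=60, n_fulllist_groups=1,
        detection_prob=0.9, seed=3,
    )
    drivers, species, truth, records, visits = ot.generate_world(cfg)
    table = ot.build_contingency(records, drivers, min_records=10)
    train_idx, test_idx = ot.split_train_test(table, 0.25, seed=1)
    return SimpleNamespace(
        cfg=cfg, drivers=drivers, species=species, truth=truth, records=records,
        visits=visits, table=table, train_idx=train_idx, test_idx=test_idx,
    )


@pytest.fixture(scope="session")
def tiny_ensemble(tiny_world):
    mc = ot.ModelConfig(hidden_shared=(16, 16), hidden_species=(16, 16),
                        max_epochs=120, patience=15)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ens = ot.run_ensemble(
            tiny_world.table, tiny_world.species, tiny_world.train_idx,
            tiny_world.test_idx, mc, n_bags=4, seed=5,
        )
    return ens


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
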