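"""Reference study worlds: the recovery world and the null (type-I) world.

These are the package's standard synthetic experiments:

* the *recovery world* — 3 insect groups x 10 species on a 20x20 grid over
  31 years with 6 drivers, one full-list and two presence-only groups,
  south- and recency-biased sampling, one strongly positive and one strongly
  negative direct driver effect, and a warming driver whose effect is
  positively mediated by the first trait (the temperature x voltinism
  archetype). Twenty half-overlapping bags of small two-network models are
  trained on it, and all downstream statistics (direct-effect flags,
  mediation detection, assemblage trends, leading local causes) should
  recover the implanted structure;
* the *null world* — a reduced single-group world with direct driver
  effects but zero trait mediation, used in replicate to measure the false
  discovery rate of the three-quartile mediation rule.

Problem sizes are chosen so a full recovery study runs in well under a
minute on one CPU and a 50-replicate null study in a few minutes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import (
    ModelConfig,
    WorldConfig,
    assign_regions,
    build_contingency,
    community_effect,
    compute_effects,
    compute_truth,
    driver_change_slopes,
    flag_direct_effects,
    generate_world,
    mark_trend,
    rank_local_causes,
    run_ensemble,
    scan_mediation,
    split_train_test,
    trait_assemblage,
)

__all__ = ["recovery_config", "null_config", "RecoveryStudy", "run_recovery_study",
           "run_null_replicate", "IMPLANTED"]

# implanted structure of the recovery world
IMPLANTED = {
    "mediated_driver": "driver_0",      # warming driver, trend +0.03 SD/yr
    "mediating_trait": "trait_0",       # the voltinism analogue
    "positive_driver": "driver_1",      # beta = +1
    "negative_driver": "driver_2",      # beta = -1
}


def recovery_config(seed: int = 7) -> WorldConfig:
    return WorldConfig(
        grid_size=20, years=31, n_drivers=6, n_groups=3, species_per_group=10,
        n_traits=3, beta=[0.5, 1.0, -1.0, 0.0, 0.0, 0.0],
        mediation_list=[(0, 0, 0.8)], driver_trend=[0.03, 0, 0, 0, 0, 0],
        visits_per_year=60, n_fulllist_groups=1, detection_prob=0.9, seed=seed,
    )


def recovery_model_config() -> ModelConfig:
    return ModelConfig(hidden_shared=(16, 16), hidden_species=(16, 16),
                       max_epochs=150, patience=15)


def null_config(seed: int) -> WorldConfig:
    return WorldConfig(
        grid_size=12, years=12, n_drivers=2, n_groups=1, species_per_group=12,
        n_traits=2, beta=[0.8, -0.5], mediation_list=[], driver_trend=[0.0, 0.0],
        visits_per_year=60, n_fulllist_groups=1, detection_prob=1.0, seed=seed,
    )


@dataclass
class RecoveryStudy:
    config: WorldConfig
    table: object
    species: object
    drivers: object
    ensemble: object
    effects: pd.DataFrame
    flags: pd.DataFrame
    mediation: pd.DataFrame
    assemblage_slope: float               # predicted trait_0 assemblage, per year
    truth_assemblage_slope: float
    cause_map: object
    test_idx: np.ndarray = field(default=None)


def _random_location_assemblage_slope(ensemble, table, drivers, test_idx, trait_values,
                                      seed) -> float:
    """Predicted assemblage trend at uniform random pixels with yearly
    location counts matched to the test split."""
    rng = np.random.default_rng(seed)
    ny, nx = drivers.grid_shape
    counts = table.samples.iloc[test_idx].groupby("year").size()
    xs, ys, yrs = [], [], []
    for year, k in counts.items():
        pix = rng.choice(ny * nx, size=int(k), replace=int(k) > ny * nx)
        xs.append(pix % nx)
        ys.append(pix // nx)
        yrs.append(np.full(int(k), year))
    x, y, year = np.concatenate(xs), np.concatenate(ys), np.concatenate(yrs)
    X = drivers.at(x, y, year)
    series = trait_assemblage(
        ensemble, table, None, np.zeros(len(X), int), trait_values, X=X, years=year
    )
    return mark_trend(series["year"], series["value"], effect_threshold=0.0).slope


def run_recovery_study(seed: int = 7, n_bags: int = 20) -> RecoveryStudy:
    """Run the full pipeline on the recovery world."""
    cfg = recovery_config(seed)
    drivers, species, truth, records, _ = generate_world(cfg)
    table = build_contingency(records, drivers, min_records=30)
    train_idx, test_idx = split_train_test(table, 0.25, seed=seed + 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ensemble = run_ensemble(table, species, train_idx, test_idx,
                                recovery_model_config(), n_bags=n_bags, seed=seed + 2)
        effects = compute_effects(ensemble, table, n_samples=50, n_backgrounds=50,
                                  seed=seed + 3)
        flags = flag_direct_effects(effects, n_bags=n_bags)
        mediation = scan_mediation(effects, species.frame,
                                   [f"trait_{m}" for m in range(cfg.n_traits)],
                                   n_bags=n_bags)
        order = [species.species.index(s) for s in table.species]
        trait0 = species.frame["trait_0"].to_numpy()[order]
        slope = _random_location_assemblage_slope(
            ensemble, table, drivers, test_idx, trait0, seed + 4
        )
    truth_flat = compute_truth(cfg, drivers, species, region_cuts=np.array([]))
    tser = truth_flat.assemblage.query("trait == 'trait_0'")
    truth_slope = mark_trend(tser["year"], tser["value"], effect_threshold=0.0).slope
    cause_map = rank_local_causes(
        driver_change_slopes(drivers),
        community_effect(effects, drivers.driver_names),
        drivers.driver_names,
    )
    return RecoveryStudy(
        config=cfg, table=table, species=species, drivers=drivers, ensemble=ensemble,
        effects=effects, flags=flags, mediation=mediation,
        assemblage_slope=float(slope), truth_assemblage_slope=float(truth_slope),
        cause_map=cause_map, test_idx=test_idx,
    )


def run_null_replicate(seed: int) -> np.ndarray:
    """One gamma=0 replicate: boolean strong-mediation flags over all
    (trait, driver) pairs of the null world."""
    cfg = null_config(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        drivers, species, truth, records, _ = generate_world(cfg)
        table = build_contingency(records, drivers, min_records=30)
        train_idx, test_idx = split_train_test(table, 0.25, seed=seed)
        mc = ModelConfig(hidden_shared=(8,), hidden_species=(8,), max_epochs=80, patience=10)
        ensemble = run_ensemble(table, species, train_idx, test_idx, mc,
                                n_bags=20, seed=seed + 1)
        effects = compute_effects(ensemble, table, n_samples=50, n_backgrounds=50,
                                  seed=seed + 2)
        med = scan_mediation(effects, species.frame, ["trait_0", "trait_1"])
    return med["strong_consistent"].to_numpy()
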