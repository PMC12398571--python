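"""Bootstrap-aggregation of community models.

Each of the (default 20) bags trains on an independent uniform 50% subsample
of the training pool drawn without replacement, so any two bags share in
expectation half of each bag's training data. Predictions and explanations
are summarised across bags by linear-interpolation percentiles — 5/50/95 for
occupancy (the 90% prediction interval) plus 25/75 for model explanations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ContingencyTable
from .msdm import CommunityModel, ModelConfig, evaluate_skill, train
from .synthetic import SpeciesTable

__all__ = ["Bag", "BagEnsemble", "make_bags", "aggregate", "run_ensemble",
           "PREDICTION_PERCENTILES", "EFFECT_PERCENTILES"]

PREDICTION_PERCENTILES = (5, 50, 95)
EFFECT_PERCENTILES = (5, 25, 50, 75, 95)


@dataclass
class Bag:
    bag_id: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int
    model: CommunityModel | None = None
    skill: pd.DataFrame | None = None


@dataclass
class BagEnsemble:
    bags: list[Bag]
    seed: int
    manifest: dict = field(default_factory=dict)

    @property
    def n_bags(self) -> int:
        return len(self.bags)

    def skill_array(self, species: list[str]) -> np.ndarray:
        """(n_bags, S) MCC matrix aligned with a species order."""
        out = np.zeros((self.n_bags, len(species)))
        for b, bag in enumerate(self.bags):
            mcc = bag.skill.set_index("species")["mcc"]
            out[b] = mcc.reindex(species).to_numpy()
        return out

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        for bag in self.bags:
            d = directory / f"bag_{bag.bag_id:02d}"
            d.mkdir(parents=True, exist_ok=True)
            np.savetxt(d / "train_idx.csv", bag.train_idx, fmt="%d")
            np.savetxt(d / "test_idx.csv", bag.test_idx, fmt="%d")
            if bag.skill is not None:
                bag.skill.to_csv(d / "skill.csv", index=False)
        (directory / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def derive_bag_seeds(master_seed: int, n_bags: int) -> np.ndarray:
    """Counter-based per-bag seeds from the master seed (kept below 2^31)."""
    state = np.random.SeedSequence(master_seed).generate_state(n_bags, dtype=np.uint32)
    return (state % np.uint32(2**31)).astype(np.int64)


def make_bags(
    train_pool: np.ndarray, n_bags: int = 20, seed: int = 0, test_idx: np.ndarray | None = None
) -> list[Bag]:
    """Half-overlapping training bags over a training pool.

    Each bag draws 50% of the pool uniformly without replacement, so the
    expected pairwise shared fraction of any bag's training data is 0.5.
    The per-bag test set is the global test split (disjoint from the pool).
    """
    if n_bags < 2:
        raise ValueError("n_bags must be >= 2")
    train_pool = np.asarray(train_pool, dtype=int)
    if len(train_pool) < 4:
        raise ValueError("training pool smaller than 4 samples")
    test_idx = np.array([], dtype=int) if test_idx is None else np.asarray(test_idx, dtype=int)
    seeds = derive_bag_seeds(seed, n_bags)
    bags = []
    for b in range(n_bags):
        rng = np.random.default_rng(int(seeds[b]))
        half = rng.choice(train_pool, size=len(train_pool) // 2, replace=False)
        bags.append(
            Bag(bag_id=b, train_idx=np.sort(half), test_idx=test_idx, seed=int(seeds[b]))
        )
    return bags


def aggregate(values: list[np.ndarray] | np.ndarray, percentiles=EFFECT_PERCENTILES) -> dict:
    """Element-wise linear-interpolation percentiles across bags.

    Returns {percentile: array}; envelopes are monotone in the percentile by
    construction.
    """
    arrays = [np.asarray(v, dtype=float) for v in values]
    if len(arrays) < 2:
        raise ValueError("need at least 2 bags to aggregate")
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("misaligned bag value shapes")
    stack = np.stack(arrays)
    qs = np.percentile(stack, percentiles, axis=0, method="linear")
    return {q: qs[i] for i, q in enumerate(percentiles)}


def run_ensemble(
    table: ContingencyTable,
    traits: SpeciesTable | np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    model_config: ModelConfig | None = None,
    n_bags: int = 20,
    seed: int = 0,
) -> BagEnsemble:
    """Train one community model per bag and score each on the test split.

    Any bag failing to train aborts the whole run; bags are never silently
    dropped.
    """
    model_config = model_config or ModelConfig()
    bags = make_bags(train_idx, n_bags=n_bags, seed=seed, test_idx=test_idx)
    for bag in bags:
        bag.model = train(table, traits, model_config, seed=bag.seed, train_idx=bag.train_idx)
        bag.skill = evaluate_skill(bag.model, table, bag.test_idx)
    manifest = {
        "n_bags": n_bags,
        "master_seed": seed,
        "bag_seeds": [bag.seed for bag in bags],
        "seed_derivation": "SeedSequence(master).generate_state(n_bags) % 2**31",
        "percentiles_predictions": list(PREDICTION_PERCENTILES),
        "percentiles_effects": list(EFFECT_PERCENTILES),
    }
    return BagEnsemble(bags=bags, seed=seed, manifest=manifest)
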