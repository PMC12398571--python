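"""Driver-effect explanations: perturbation attributions, slope effects,
consistency flags and trait-mediation detection.

The attribution is a single-feature interventional perturbation: for a
sample x and driver j,

    phi_s(x) = p_s(x) - mean_b [ p_s(x with x_j := b) ]

with backgrounds b drawn from the empirical marginal of driver j over the
model's data. Regressing phi_s against the (standardised) driver value over
a set of random samples yields one linear slope per (bag, species, driver) —
the EffectRecord atom from which all downstream statistics are built.

Strength and consistency conventions (all percentiles linear-interpolated):

* a group x driver effect distribution (over species slopes) is *strong*
  when it excludes zero by three quartiles — 25th percentile > 0 (positive)
  or 75th percentile < 0 (negative);
* a trait mediation is *strong* when two of the low/mid/high trait terciles
  exclude each other by three quartiles (one tercile's 25th percentile above
  another's 75th);
* strength found in >= 15 / 18 / 19 / 20 of 20 bags maps to consistency
  levels 75% / 90% / 95% / 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bagging import BagEnsemble
from .data import ContingencyTable
from .msdm import CommunityModel, predict

__all__ = [
    "shap_attribution",
    "effect_slope",
    "compute_effects",
    "flag_direct_effects",
    "group_by_trait",
    "detect_mediation",
    "scan_mediation",
    "consistency_level",
    "MediationSummary",
]

CONSISTENCY_LADDER = ((20, "100%"), (19, "95%"), (18, "90%"), (15, "75%"))
BOX_PERCENTILES = (5, 25, 50, 75, 95)


def consistency_level(n_strong_bags: int, n_bags: int = 20) -> str:
    """Map a strong-bag count (out of 20) onto the consistency ladder."""
    scale = n_bags / 20.0
    for k, label in CONSISTENCY_LADDER:
        if n_strong_bags >= k * scale:
            return label
    return "none"


def shap_attribution(
    predict_fn, X: np.ndarray, driver_id: int, backgrounds: np.ndarray
) -> np.ndarray:
    """Perturbation attribution of one driver for every row of X.

    ``predict_fn`` maps an (n, D) driver matrix to (n, S) probabilities.
    Returns (n, S): prediction minus its mean over background substitutions
    of column ``driver_id``.
    """
    backgrounds = np.asarray(backgrounds, dtype=float).ravel()
    if backgrounds.size == 0:
        raise ValueError("empty background set")
    X = np.asarray(X, dtype=float)
    base = predict_fn(X)
    rep = np.repeat(X, len(backgrounds), axis=0)
    rep[:, driver_id] = np.tile(backgrounds, len(X))
    perturbed = predict_fn(rep).reshape(len(X), len(backgrounds), -1)
    return base - perturbed.mean(axis=1)


def effect_slope(
    model,
    X_pool: np.ndarray,
    driver_id: int,
    n_samples: int = 50,
    n_backgrounds: int = 50,
    rng: np.random.Generator | int = 0,
) -> tuple[np.ndarray, bool]:
    """OLS slope of attribution values on the standardised driver value.

    ``model`` is a CommunityModel, or any callable mapping an (n, D) driver
    matrix to (n, S) responses (then taken as already standardised). Samples
    and backgrounds are drawn from ``X_pool`` (the bag's own data). Returns
    (slopes per species, degenerate_flag); a zero-variance draw of the
    driver yields slopes 0 with the flag set.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    X_pool = np.asarray(X_pool, dtype=float)
    take = rng.choice(len(X_pool), size=min(n_samples, len(X_pool)), replace=False)
    X = X_pool[take]
    backgrounds = X_pool[rng.choice(len(X_pool), size=n_backgrounds, replace=True), driver_id]
    if callable(model):
        predict_fn = model
        mean, std = 0.0, 1.0
    else:
        predict_fn = lambda M: predict(model, M)
        mean = model.driver_mean[driver_id]
        std = model.driver_std[driver_id]
    phi = shap_attribution(predict_fn, X, driver_id, backgrounds)
    z = (X[:, driver_id] - mean) / std
    var = np.var(z)
    if var == 0.0:
        return np.zeros(phi.shape[1]), True
    zc = z - z.mean()
    slopes = (zc @ (phi - phi.mean(axis=0))) / (zc @ zc)
    return slopes, False


def compute_effects(
    ensemble: BagEnsemble,
    table: ContingencyTable,
    n_samples: int = 50,
    n_backgrounds: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format EffectRecords: one slope per (bag, species, driver).

    Attribution samples are drawn from each bag's own training data; for a
    given species only samples of its group are used (other samples carry no
    signal for it under the masked response).
    """
    rows = []
    groups = table.species_group
    for bag in ensemble.bags:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(bag.bag_id,)))
        sample_groups = table.samples["group"].to_numpy()[bag.train_idx]
        for g in sorted(set(groups)):
            sp_idx = np.where(groups == g)[0]
            pool = table.driver_matrix[bag.train_idx[sample_groups == g]]
            if len(pool) < 2:
                raise ValueError(f"bag {bag.bag_id}: too few samples of group {g}")
            for j in range(len(table.driver_names)):
                take = rng.choice(len(pool), size=min(n_samples, len(pool)), replace=False)
                X = pool[take]
                backgrounds = pool[rng.choice(len(pool), size=n_backgrounds, replace=True), j]
                phi = shap_attribution(
                    lambda M: predict(bag.model, M, species_idx=sp_idx), X, j, backgrounds
                )
                z = (X[:, j] - bag.model.driver_mean[j]) / bag.model.driver_std[j]
                zc = z - z.mean()
                denom = zc @ zc
                if denom == 0.0:
                    slopes = np.zeros(len(sp_idx))
                else:
                    slopes = (zc @ (phi - phi.mean(axis=0))) / denom
                for k, s in enumerate(sp_idx):
                    rows.append(
                        {
                            "bag": bag.bag_id,
                            "group": int(g),
                            "species": table.species[s],
                            "driver": table.driver_names[j],
                            "slope": float(slopes[k]),
                            "n_samples": len(X),
                            "n_backgrounds": n_backgrounds,
                        }
                    )
    return pd.DataFrame(rows)


def flag_direct_effects(effects: pd.DataFrame, n_bags: int = 20) -> pd.DataFrame:
    """Strong/consistent direct-effect summary per group x driver.

    Per bag the distribution over species slopes is strong positive when its
    25th percentile exceeds 0 and strong negative when its 75th percentile is
    below 0; the consistency level follows the 15/18/19/20-bag ladder on the
    count of bags strong with the same sign. Groups with fewer than 4 species
    are excluded with a warning (quartiles unstable).
    """
    out = []
    for (g, drv), sub in effects.groupby(["group", "driver"], sort=True):
        n_species = sub["species"].nunique()
        if n_species < 4:
            warnings.warn(f"group {g}: only {n_species} species, direct-effect flags skipped",
                          stacklevel=2)
            continue
        n_pos = n_neg = 0
        for _, bag_sub in sub.groupby("bag"):
            q25, q75 = np.percentile(bag_sub["slope"], [25, 75])
            if q25 > 0:
                n_pos += 1
            elif q75 < 0:
                n_neg += 1
        direction, n_strong = max((("positive", n_pos), ("negative", n_neg)), key=lambda t: t[1])
        if n_strong == 0:
            direction = "none"
        out.append(
            {
                "group": g,
                "driver": drv,
                "median_slope": float(sub["slope"].median()),
                "direction": direction,
                "n_strong_bags": int(n_strong),
                "consistency": consistency_level(n_strong, n_bags),
            }
        )
    return pd.DataFrame(out)


def group_by_trait(trait_values: np.ndarray) -> np.ndarray:
    """Tercile labels 0 (low) / 1 (mid) / 2 (high) by ranked trait value.

    Sizes are equal up to remainder, extras assigned low-first; ties broken
    by stable input order. All-equal trait values degenerate to stable-order
    terciles with a warning.
    """
    trait_values = np.asarray(trait_values, dtype=float)
    n = len(trait_values)
    if n < 3:
        raise ValueError("need at least 3 species to form trait terciles")
    if np.all(trait_values == trait_values[0]):
        warnings.warn("all trait values equal; terciles follow stable species order",
                      stacklevel=2)
    order = np.argsort(trait_values, kind="stable")
    base, r = divmod(n, 3)
    sizes = [base + (1 if r > 0 else 0), base + (1 if r > 1 else 0), base]
    labels = np.empty(n, dtype=int)
    start = 0
    for lab, size in enumerate(sizes):
        labels[order[start : start + size]] = lab
        start += size
    return labels


@dataclass
class MediationSummary:
    group: int
    trait: str
    driver: str
    boxes: pd.DataFrame            # tercile x percentile box over pooled (bag, species) slopes
    n_strong_bags: int             # bags where some tercile pair excludes the other
    direction: tuple[int, int] | None   # (upper tercile, lower tercile) of the modal pair
    consistent_level: str


def _strong_pairs(slopes_by_tercile: dict[int, np.ndarray]) -> set[tuple[int, int]]:
    """Ordered tercile pairs (a, b) with a's 25th percentile above b's 75th."""
    pairs = set()
    boxes = {t: np.percentile(v, [25, 75]) for t, v in slopes_by_tercile.items()}
    for a in boxes:
        for b in boxes:
            if a != b and boxes[a][0] > boxes[b][1]:
                pairs.add((a, b))
    return pairs


def detect_mediation(
    effects: pd.DataFrame,
    tercile_of_species: dict[str, int],
    group: int,
    trait: str,
    driver: str,
    bag_threshold: int = 15,
    n_bags: int = 20,
) -> MediationSummary:
    """Three-quartile trait-mediation test for one group x trait x driver.

    Per bag, the species-slope distribution of each trait tercile is boxed;
    the mediation is strong in that bag when two terciles' 25th-75th ranges
    are disjoint. It is consistent when the same ordered tercile pair is
    strong in at least ``bag_threshold`` of ``n_bags`` bags.
    """
    sub = effects[(effects["group"] == group) & (effects["driver"] == driver)]
    bags_present = set(sub["bag"])
    if bags_present != set(range(n_bags)):
        raise ValueError(f"effect records missing bags: {sorted(set(range(n_bags)) - bags_present)}")
    terciles = sub["species"].map(tercile_of_species)
    if terciles.isna().any():
        raise ValueError("tercile labels missing for some species in the group")
    counts = terciles.groupby(sub["bag"]).value_counts().groupby(level=1).min()
    if (counts < 2).any():
        raise ValueError("need >= 2 species per tercile for mediation boxes")

    pair_counts: dict[tuple[int, int], int] = {}
    for _, bag_sub in sub.groupby("bag"):
        by_t = {
            int(t): bag_sub["slope"][terciles.loc[bag_sub.index] == t].to_numpy()
            for t in sorted(terciles.unique())
        }
        for pair in _strong_pairs(by_t):
            pair_counts[pair] = pair_counts.get(pair, 0) + 1
    if pair_counts:
        direction, n_strong = max(pair_counts.items(), key=lambda kv: kv[1])
    else:
        direction, n_strong = None, 0

    box_rows = []
    for t in sorted(terciles.unique()):
        v = sub["slope"][terciles == t].to_numpy()
        qs = np.percentile(v, BOX_PERCENTILES)
        box_rows.append({"tercile": int(t), **{f"p{q}": qs[i] for i, q in enumerate(BOX_PERCENTILES)}})
    return MediationSummary(
        group=group,
        trait=trait,
        driver=driver,
        boxes=pd.DataFrame(box_rows),
        n_strong_bags=int(n_strong),
        direction=direction,
        consistent_level=consistency_level(n_strong, n_bags),
    )


def scan_mediation(
    effects: pd.DataFrame,
    species_frame: pd.DataFrame,
    trait_names: list[str],
    bag_threshold: int = 15,
    n_bags: int = 20,
) -> pd.DataFrame:
    """Mediation summary for every (group, trait, driver) combination.

    ``species_frame`` needs columns species, group and the trait columns.
    Groups with fewer than 6 species (2 per tercile) are skipped.
    """
    rows = []
    for g, gsub in species_frame.groupby("group"):
        if len(gsub) < 6:
            warnings.warn(f"group {g}: fewer than 6 species, mediation scan skipped",
                          stacklevel=2)
            continue
        for trait in trait_names:
            labels = group_by_trait(gsub[trait].to_numpy())
            tercile_of_species = dict(zip(gsub["species"], labels))
            for driver in sorted(effects["driver"].unique()):
                summ = detect_mediation(
                    effects, tercile_of_species, int(g), trait, driver,
                    bag_threshold=bag_threshold, n_bags=n_bags,
                )
                rows.append(
                    {
                        "group": int(g),
                        "trait": trait,
                        "driver": driver,
                        "n_strong_bags": summ.n_strong_bags,
                        "direction": summ.direction,
                        "consistent_level": summ.consistent_level,
                        "strong_consistent": summ.n_strong_bags >= bag_threshold,
                    }
                )
    return pd.DataFrame(rows)
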