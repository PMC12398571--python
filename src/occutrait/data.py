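"""From raw occurrence records to model-ready contingency tables.

Presence-only records are turned into presence-absence samples by treating
the presences of the other species in a group as pseudo-absences for the
focal species at every recorded site-year. Species-specific class weights
then equalise the total loss contribution of presences and absences:

    w0 = (n0 + n1) / (2 n0),    w1 = (n0 + n1) / (2 n1)

(linear weights; the square-root variant takes element-wise square roots).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import FULL_LIST, PRESENCE_ONLY, DriverStack

__all__ = [
    "ClassWeights",
    "ContingencyTable",
    "compute_class_weights",
    "build_contingency",
    "assign_regions",
    "split_train_test",
]


@dataclass(frozen=True)
class ClassWeights:
    n0: int
    n1: int
    w0: float
    w1: float
    variant: str


def compute_class_weights(n0: int, n1: int, variant: str = "linear") -> ClassWeights:
    """Class weights balancing presence and absence loss mass.

    Under the linear variant w0*n0 = w1*n1 = (n0+n1)/2 exactly; with 10x more
    absences than presences each absence matters 10x less than each presence.
    A species with no absences (recorded present everywhere sampled) gets
    w0 = 1 with a warning.
    """
    if variant not in ("linear", "sqrt"):
        raise ValueError(f"unknown class-weight variant {variant!r}")
    if n1 < 1:
        raise ValueError("species without presences must be filtered before weighting")
    if n0 < 0:
        raise ValueError("negative absence count")
    if n0 == 0:
        warnings.warn("species has no absences; w0 set to 1", stacklevel=2)
        w0 = 1.0
    else:
        w0 = (n0 + n1) / (2.0 * n0)
    w1 = (n0 + n1) / (2.0 * n1)
    if variant == "sqrt":
        w0, w1 = float(np.sqrt(w0)), float(np.sqrt(w1))
    return ClassWeights(n0=int(n0), n1=int(n1), w0=float(w0), w1=float(w1), variant=variant)


@dataclass
class ContingencyTable:
    """(site, year, group) samples with a species response matrix.

    ``mask[i, s]`` is True when species s belongs to sample i's group and was
    retained; ``response`` and ``weights`` are only meaningful (and weights
    only positive) where the mask holds.
    """

    samples: pd.DataFrame                 # site_id, x, y, year, group
    response: np.ndarray                  # (n, S) float 0/1
    mask: np.ndarray                      # (n, S) bool
    weights: np.ndarray                   # (n, S) float, 0 where masked out
    species: list[str]
    species_group: np.ndarray             # (S,)
    data_kind: dict[int, str]
    driver_matrix: np.ndarray             # (n, D)
    driver_names: list[str]
    class_weights: dict[str, ClassWeights]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.samples.to_csv(directory / "samples.csv", index=False)
        pd.DataFrame(self.response, columns=self.species).to_csv(
            directory / "response.csv", index=False
        )
        pd.DataFrame(self.driver_matrix, columns=self.driver_names).to_csv(
            directory / "drivers.csv", index=False
        )
        meta = {
            "species": self.species,
            "species_group": self.species_group.tolist(),
            "data_kind": {str(k): v for k, v in self.data_kind.items()},
            "class_weights": {
                s: {"n0": w.n0, "n1": w.n1, "w0": w.w0, "w1": w.w1, "variant": w.variant}
                for s, w in self.class_weights.items()
            },
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def build_contingency(
    records: pd.DataFrame,
    drivers: DriverStack,
    min_records: int = 30,
    weight_variant: str | None = None,
) -> ContingencyTable:
    """Build the presence-absence contingency table from raw records.

    For presence-only groups every (site, year) holding at least one record
    of the group becomes a sample; species recorded there get 1 and every
    other retained group member gets a pseudo-absence 0. Full-list groups
    pass their recorded 1/0 statuses through unchanged. Species with fewer
    than ``min_records`` presences are dropped before table construction.

    Weight variant defaults per record type — linear for presence-only
    groups, square-root for full-list groups — and can be forced globally
    with ``weight_variant``.
    """
    required = {"species", "group", "x", "y", "year", "status", "data_kind"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    ny, nx = drivers.grid_shape
    bad = records[
        (records["x"] < 0)
        | (records["x"] >= nx)
        | (records["y"] < 0)
        | (records["y"] >= ny)
        | (~records["year"].isin(drivers.years))
    ]
    if len(bad):
        raise ValueError(
            f"{len(bad)} record(s) outside the driver grid/years, e.g.\n{bad.head()}"
        )

    presences = records[records["status"] == 1]
    counts = presences.groupby("species").size()
    retained = sorted(counts[counts >= min_records].index)
    if not retained:
        raise ValueError(f"no species reaches min_records={min_records} presences")
    recs = records[records["species"].isin(retained)].copy()

    kind_of_group = dict(
        recs.groupby("group")["data_kind"].agg(lambda s: s.iloc[0])
    )
    group_of_species = dict(recs.groupby("species")["group"].agg(lambda s: int(s.iloc[0])))
    for g, kind in kind_of_group.items():
        n_sp = sum(1 for s in retained if group_of_species[s] == g)
        if kind == PRESENCE_ONLY and n_sp < 2:
            raise ValueError(
                f"presence-only group {g} retains a single species: "
                "no pseudo-absences constructible"
            )

    species = retained
    sp_index = {s: i for i, s in enumerate(species)}
    species_group = np.array([group_of_species[s] for s in species])

    sample_key = recs[["x", "y", "year", "group"]].drop_duplicates().sort_values(
        ["group", "year", "y", "x"], kind="stable"
    )
    sample_key = sample_key.reset_index(drop=True)
    sample_key["site_id"] = sample_key["y"] * nx + sample_key["x"]
    n = len(sample_key)
    S = len(species)
    row_of = {
        (x, y, yr, g): i
        for i, (x, y, yr, g) in enumerate(
            zip(sample_key["x"], sample_key["y"], sample_key["year"], sample_key["group"])
        )
    }

    response = np.zeros((n, S))
    mask = np.zeros((n, S), dtype=bool)
    for g in kind_of_group:
        cols = np.where(species_group == g)[0]
        rows = [
            row_of[k]
            for k in row_of
            if k[3] == g
        ]
        mask[np.ix_(rows, cols)] = True
    for rec in recs.itertuples(index=False):
        i = row_of[(rec.x, rec.y, rec.year, rec.group)]
        response[i, sp_index[rec.species]] = float(rec.status)

    # NA statuses in full-list input (unchecked species) fall outside the mask
    na_rows = recs[recs["status"].isna()]
    for rec in na_rows.itertuples(index=False):
        i = row_of[(rec.x, rec.y, rec.year, rec.group)]
        mask[i, sp_index[rec.species]] = False
        response[i, sp_index[rec.species]] = 0.0

    weights = np.zeros((n, S))
    class_weights: dict[str, ClassWeights] = {}
    for s, name in enumerate(species):
        rows = mask[:, s]
        y = response[rows, s]
        n1 = int(y.sum())
        n0 = int(len(y) - n1)
        if n1 < 1:
            raise ValueError(f"species {name} has no presences after table construction")
        variant = weight_variant or (
            "sqrt" if kind_of_group[species_group[s]] == FULL_LIST else "linear"
        )
        cw = compute_class_weights(n0, n1, variant)
        class_weights[name] = cw
        weights[rows, s] = np.where(y == 1, cw.w1, cw.w0)

    samples = sample_key[["site_id", "x", "y", "year", "group"]].copy()
    driver_matrix = drivers.at(
        samples["x"].to_numpy(), samples["y"].to_numpy(), samples["year"].to_numpy()
    )
    return ContingencyTable(
        samples=samples,
        response=response,
        mask=mask,
        weights=weights,
        species=species,
        species_group=species_group,
        data_kind={int(g): k for g, k in kind_of_group.items()},
        driver_matrix=driver_matrix,
        driver_names=list(drivers.driver_names),
        class_weights=class_weights,
    )


def assign_regions(northing: np.ndarray, cuts) -> np.ndarray:
    """Latitudinal slice labels from northing cut points.

    Slices are lower-inclusive / upper-exclusive; a northing exactly at a cut
    joins the upper slice. An empty cut list yields a single region 0.
    """
    cuts = np.asarray(list(cuts), dtype=float)
    if len(cuts) and np.any(np.diff(cuts) <= 0):
        raise ValueError("cuts must be strictly increasing")
    return np.searchsorted(cuts, np.asarray(northing, dtype=float), side="right")


def split_train_test(
    table: ContingencyTable, test_fraction: float = 0.25, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive sample split stratified by (group, year).

    Within each stratum round(n * test_fraction) samples go to test; a
    singleton stratum goes to train with a warning.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    strata = table.samples.groupby(["group", "year"], sort=True).indices
    for key in sorted(strata):
        idx = np.asarray(strata[key])
        if len(idx) == 1:
            warnings.warn(f"stratum {key} has a single sample; assigned to train", stacklevel=2)
            train.append(idx)
            continue
        perm = rng.permutation(idx)
        k = int(round(len(idx) * test_fraction))
        k = min(max(k, 0), len(idx) - 1)
        test.append(perm[:k])
        train.append(perm[k:])
    train_idx = np.sort(np.concatenate(train))
    test_idx = np.sort(np.concatenate(test)) if test else np.array([], dtype=int)
    return train_idx, test_idx
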