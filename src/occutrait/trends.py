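"""Occupancy and trait-assemblage trend series with significance marking.

The trait assemblage for region r, year y is the skill- and
probability-weighted community mean trait over the region-year's sample set
X:

    t_bar(r, y) = (1/|X|) * sum_x [ sum_s t_s p_sx max{MCC_s, 0}
                                    / sum_s p_sx max{MCC_s, 0} ]

Linear trends are tested by a two-sided t test on the OLS slope with
Bonferroni adjustment, and flagged only when the adjusted p-value clears
alpha AND the absolute effect size per decade clears a floor (1% probability
of presence for occupancy; 1% or 2% of a trait SD for assemblages).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bagging import BagEnsemble, PREDICTION_PERCENTILES
from .data import ContingencyTable, assign_regions
from .msdm import predict
from .synthetic import DriverStack

__all__ = [
    "occupancy_trend",
    "random_location_trend",
    "trait_assemblage",
    "mark_trend",
    "TrendTest",
]


def _series_frame(per_bag: np.ndarray, keys: pd.DataFrame, source: str) -> pd.DataFrame:
    """Percentile envelope across bags -> tidy (region, year, value, p5, p95)."""
    qs = np.percentile(per_bag, PREDICTION_PERCENTILES, axis=0)
    out = keys.copy()
    out["p5"], out["value"], out["p95"] = qs[0], qs[1], qs[2]
    out["source"] = source
    return out


def _region_year_cells(
    regions: np.ndarray, years: np.ndarray
) -> tuple[pd.DataFrame, list[np.ndarray]]:
    """Group samples by (region, year); mean of masked entries per cell."""
    keys = pd.DataFrame({"region": regions, "year": years})
    groups = keys.groupby(["region", "year"], sort=True).indices
    rows, cells = [], []
    for key in sorted(groups):
        idx = np.asarray(groups[key])
        rows.append({"region": key[0], "year": key[1], "n": len(idx)})
        cells.append(idx)
    return pd.DataFrame(rows), cells


def occupancy_trend(
    ensemble: BagEnsemble,
    table: ContingencyTable,
    idx: np.ndarray,
    regions: np.ndarray,
    source: str = "predicted_at_samples",
) -> pd.DataFrame:
    """Mean occupancy per region-year: observed or predicted at the samples.

    ``regions`` are labels per table sample. For the predicted source each
    bag contributes a series and the envelope is the 90% prediction
    interval; the observed source uses the recorded responses (no bags).
    Region-years without samples are simply absent from the output.
    """
    idx = np.asarray(idx, dtype=int)
    keys, cells = _region_year_cells(
        np.asarray(regions)[idx], table.samples["year"].to_numpy()[idx]
    )
    mask = table.mask[idx]
    if source == "observed":
        resp = table.response[idx]
        vals = np.array([resp[c][mask[c]].mean() for c in cells])
        out = keys.copy()
        out["value"] = vals
        out["p5"] = out["p95"] = vals
        out["source"] = source
        return out
    per_bag = np.empty((ensemble.n_bags, len(cells)))
    for b, bag in enumerate(ensemble.bags):
        p = predict(bag.model, table.driver_matrix[idx])
        per_bag[b] = [p[c][mask[c]].mean() for c in cells]
    return _series_frame(per_bag, keys, source)


def random_location_trend(
    ensemble: BagEnsemble,
    table: ContingencyTable,
    drivers: DriverStack,
    test_idx: np.ndarray,
    region_cuts,
    seed: int = 0,
) -> pd.DataFrame:
    """Predicted occupancy at uniform random pixels, with per group-year
    location counts matched to the test split.

    Random locations are less affected by preferential sampling, so this
    series is the more representative estimate of regional change.
    """
    rng = np.random.default_rng(seed)
    test_idx = np.asarray(test_idx, dtype=int)
    samples = table.samples.iloc[test_idx]
    ny, nx = drivers.grid_shape
    n_pix = ny * nx
    xs, ys, yrs, grps = [], [], [], []
    for (g, year), sub in samples.groupby(["group", "year"], sort=True):
        k = len(sub)
        if k > n_pix:
            warnings.warn("more matched locations than pixels; sampling with replacement",
                          stacklevel=2)
        pix = rng.choice(n_pix, size=k, replace=k > n_pix)
        xs.append(pix % nx)
        ys.append(pix // nx)
        yrs.append(np.full(k, year))
        grps.append(np.full(k, g))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    year = np.concatenate(yrs)
    group = np.concatenate(grps)
    X = drivers.at(x, y, year)
    regions = assign_regions(y, region_cuts)

    keys = pd.DataFrame({"region": regions, "year": year})
    groups_ = keys.groupby(["region", "year"], sort=True).indices
    cells = [np.asarray(groups_[k]) for k in sorted(groups_)]
    keys_out = pd.DataFrame(
        [{"region": k[0], "year": k[1], "n": len(groups_[k])} for k in sorted(groups_)]
    )
    sp_group = table.species_group
    mask = sp_group[None, :] == group[:, None]
    per_bag = np.empty((ensemble.n_bags, len(cells)))
    for b, bag in enumerate(ensemble.bags):
        p = predict(bag.model, X)
        per_bag[b] = [p[c][mask[c]].mean() for c in cells]
    return _series_frame(per_bag, keys_out, "predicted_at_random")


def assemblage_means(
    p: np.ndarray, mask: np.ndarray, traits: np.ndarray, mcc: np.ndarray,
    regions: np.ndarray, years: np.ndarray,
) -> pd.DataFrame:
    """Skill-weighted community mean trait per region-year for one bag.

    Samples whose species all carry zero weight (p or max{MCC,0} zero) are
    excluded from the sample set with a warning.
    """
    w = np.maximum(mcc, 0.0)
    wp = p * w[None, :] * mask
    den = wp.sum(axis=1)
    ok = den > 0
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} sample(s) with all-zero assemblage weights excluded",
                      stacklevel=2)
    t_bar = np.full(len(p), np.nan)
    t_bar[ok] = (wp[ok] @ traits) / den[ok]
    frame = pd.DataFrame({"region": regions, "year": years, "t": t_bar})
    out = (
        frame[ok]
        .groupby(["region", "year"], sort=True)["t"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "value", "size": "n"})
    )
    return out


def trait_assemblage(
    ensemble: BagEnsemble,
    table: ContingencyTable,
    idx: np.ndarray,
    regions: np.ndarray,
    trait_values: np.ndarray,
    X: np.ndarray | None = None,
    years: np.ndarray | None = None,
) -> pd.DataFrame:
    """Bagged trait-assemblage series at the given samples.

    ``trait_values`` is the per-species trait vector (aligned with the
    table's species). Pass ``X``/``years``/``regions`` directly to evaluate
    at arbitrary (e.g. random) locations instead of table samples; in that
    case ``idx`` is ignored and the species mask is all-True.
    """
    trait_values = np.asarray(trait_values, dtype=float)
    if X is None:
        idx = np.asarray(idx, dtype=int)
        X = table.driver_matrix[idx]
        years = table.samples["year"].to_numpy()[idx]
        regions = np.asarray(regions)[idx]
        mask = table.mask[idx]
    else:
        mask = np.ones((len(X), table.n_species), dtype=bool)
        years = np.asarray(years)
        regions = np.asarray(regions)
    per_bag = []
    keys = None
    for bag in ensemble.bags:
        p = predict(bag.model, X)
        mcc = bag.skill.set_index("species")["mcc"].reindex(table.species).to_numpy()
        out = assemblage_means(p, mask, trait_values, mcc, regions, years)
        if keys is None:
            keys = out[["region", "year", "n"]]
        per_bag.append(out["value"].to_numpy())
    return _series_frame(np.stack(per_bag), keys.copy(), "assemblage")


@dataclass(frozen=True)
class TrendTest:
    slope: float                 # per year
    p_value: float
    p_adjusted: float
    significant: bool
    n_years: int


def mark_trend(
    years: np.ndarray,
    values: np.ndarray,
    alpha: float = 0.01,
    n_comparisons: int = 1,
    effect_threshold: float = 0.01,
) -> TrendTest:
    """Linear-trend marking: Bonferroni-adjusted two-sided t test on the OLS
    slope, plus an absolute effect-size floor per decade.

    A series is flagged significant only when the adjusted p-value is below
    ``alpha`` AND |slope| x 10 years exceeds ``effect_threshold``. Missing
    values are dropped listwise; a constant series has slope 0 and is never
    significant.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values) & np.isfinite(years)
    years, values = years[ok], values[ok]
    if len(years) < 3:
        raise ValueError("need at least 3 year points for a trend test")
    if np.all(values == values[0]) or np.all(years == years[0]):
        return TrendTest(0.0, 1.0, 1.0, False, len(years))
    res = stats.linregress(years, values)
    p_adj = min(1.0, res.pvalue * n_comparisons)
    significant = bool(p_adj < alpha and abs(res.slope) * 10.0 > effect_threshold)
    return TrendTest(float(res.slope), float(res.pvalue), float(p_adj), significant, len(years))
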