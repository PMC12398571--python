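"""Per-pixel leading local drivers of occupancy change.

For every pixel the rate of change of each driver over the study period
(OLS slope on year) is multiplied by the driver's community-level occupancy
effect, giving an impact in probability per year. Drivers are then ranked
per pixel as the leading (and 2nd, 3rd, ...) positive and negative local
causes of change, and map coverage shares are reported per driver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import DriverStack

__all__ = ["driver_change_slopes", "community_effect", "rank_local_causes", "LocalCauseMap"]


def driver_change_slopes(drivers: DriverStack) -> np.ndarray:
    """OLS slope of driver value on year, per pixel and driver: (D, ny, nx).

    Invariant to re-coding of the year axis; constant drivers get slope 0.
    """
    if len(drivers.years) < 3:
        raise ValueError("need at least 3 years to fit per-pixel slopes")
    t = drivers.years - drivers.years.mean()
    return np.einsum("t,jtyx->jyx", t, drivers.values) / (t @ t)


def community_effect(effects: pd.DataFrame, driver_names: list[str], agg: str = "median") -> np.ndarray:
    """One community-level occupancy effect per driver.

    Aggregates EffectRecords to the bag-median slope per species, then takes
    the median (or mean) across species.
    """
    if agg not in ("median", "mean"):
        raise ValueError("agg must be 'median' or 'mean'")
    per_species = effects.groupby(["driver", "species"])["slope"].median()
    out = per_species.groupby(level=0).median() if agg == "median" else per_species.groupby(level=0).mean()
    return out.reindex(driver_names).to_numpy()


@dataclass
class LocalCauseMap:
    impact: np.ndarray             # (D, ny, nx) probability / year
    positive_rank: np.ndarray      # (depth, ny, nx) driver index, -1 = none
    negative_rank: np.ndarray      # (depth, ny, nx) driver index, -1 = none
    coverage: pd.DataFrame         # driver, sign, rank, coverage fraction
    driver_names: list[str]

    def coverage_of(self, driver: str, sign: str, rank: int = 1) -> float:
        sub = self.coverage[
            (self.coverage["driver"] == driver)
            & (self.coverage["sign"] == sign)
            & (self.coverage["rank"] == rank)
        ]
        return float(sub["coverage"].iloc[0]) if len(sub) else 0.0


def rank_local_causes(
    change_slopes: np.ndarray,
    effect_per_driver: np.ndarray,
    driver_names: list[str],
    depth: int = 3,
    land_mask: np.ndarray | None = None,
) -> LocalCauseMap:
    """Rank drivers per pixel by impact = change slope x community effect.

    A declining harmful driver has positive impact (sign of the product).
    Rank k positive cause is the driver with the k-th largest positive
    impact; pixels without any positive (negative) impact are 'none' (-1)
    for that map. Ties break by impact magnitude then stable driver order,
    so permuting driver input order never changes the maps.
    """
    impact = change_slopes * np.asarray(effect_per_driver, dtype=float)[:, None, None]
    D, ny, nx = impact.shape
    if land_mask is None:
        land_mask = np.ones((ny, nx), dtype=bool)
    flat = impact.reshape(D, -1)
    land = land_mask.ravel()
    n_land = int(land.sum())

    # stable descending order on impact per pixel
    order_desc = np.argsort(-flat, axis=0, kind="stable")
    order_asc = np.argsort(flat, axis=0, kind="stable")
    pos = np.full((depth, ny * nx), -1, dtype=int)
    neg = np.full((depth, ny * nx), -1, dtype=int)
    for k in range(min(depth, D)):
        cand = order_desc[k]
        ok = (flat[cand, np.arange(ny * nx)] > 0) & land
        pos[k, ok] = cand[ok]
        cand = order_asc[k]
        ok = (flat[cand, np.arange(ny * nx)] < 0) & land
        neg[k, ok] = cand[ok]

    rows = []
    for sign, ranks in (("positive", pos), ("negative", neg)):
        for k in range(depth):
            counts = np.bincount(ranks[k][ranks[k] >= 0], minlength=D)
            for j, name in enumerate(driver_names):
                rows.append(
                    {
                        "driver": name,
                        "sign": sign,
                        "rank": k + 1,
                        "coverage": counts[j] / n_land if n_land else 0.0,
                    }
                )
    return LocalCauseMap(
        impact=impact,
        positive_rank=pos.reshape(depth, ny, nx),
        negative_rank=neg.reshape(depth, ny, nx),
        coverage=pd.DataFrame(rows),
        driver_names=list(driver_names),
    )
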