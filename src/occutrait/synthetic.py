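"""Synthetic community worlds with known ground truth.

Generates the three ingredients every downstream stage consumes — gridded
environmental drivers, a species table with group-standardised traits, and
true occupancy probabilities — plus biased occurrence sampling, so that
driver effects and trait mediations implanted in the truth model can be
recovered end to end.

The truth model is logit-linear with product interactions:

    logit p_s(x, year) = baseline_s + sum_j (beta_j + sum_m gamma_jm * t_sm) * d_j(x, year)

where ``d_j`` are standardised driver fields, ``t_sm`` standardised trait
values, ``beta_j`` the community-wide (direct) driver coefficients and
``gamma_jm`` the trait-mediation coefficients. This is the minimal generative
structure under which "trait mediation" is a well-defined, recoverable
quantity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

__all__ = [
    "WorldConfig",
    "DriverStack",
    "SpeciesTable",
    "TruthTables",
    "generate_drivers",
    "generate_species",
    "compute_truth",
    "sample_records",
    "generate_world",
]

FULL_LIST = "full_list"
PRESENCE_ONLY = "presence_only"

# fixed stream indices so each generator draws from an independent,
# call-order-insensitive stream of the world seed
_STREAM_DRIVERS = 1
_STREAM_SPECIES = 2
_STREAM_SAMPLING = 3


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


@dataclass
class WorldConfig:
    """Full specification of a synthetic world.

    Spatial unit is one grid pixel (the analogue of a 1 km^2 cell); temporal
    unit is one year. ``driver_trend`` is expressed in driver standard
    deviations per year, added after the fields are standardised.
    """

    grid_size: int = 20
    years: int = 31                       # emulates 1990-2020
    first_year: int = 1990
    n_drivers: int = 6
    n_groups: int = 3
    species_per_group: int = 10
    n_traits: int = 3
    driver_trend: np.ndarray | None = None      # (n_drivers,) SD units / year
    smoothing_scale: float = 3.0                # pixels; spatial autocorrelation length
    temporal_persistence: float = 0.8           # share of variance from the static field
    beta: np.ndarray | None = None              # (n_drivers,) direct logit coefficients
    mediation_list: list[tuple[int, int, float]] = field(default_factory=list)
    baseline_mean: float = -1.0                 # logit scale; mean occupancy ~ 0.27
    baseline_sd: float = 1.0
    detection_prob: float = 0.9
    bias_south: float = 1.0                     # exp(bias_south * southness) site weighting
    bias_time: float = 0.04                     # exp(bias_time * year_index) effort growth
    visits_per_year: int = 120                  # expected visits (before temporal bias)
    n_fulllist_groups: int = 1                  # leading groups recorded as full lists
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("grid_size", "years", "n_drivers", "n_groups", "species_per_group"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_traits < 0:
            raise ValueError("n_traits must be >= 0")
        if not (0.0 < self.detection_prob <= 1.0):
            raise ValueError("detection_prob must lie in (0, 1]")
        if self.driver_trend is None:
            self.driver_trend = np.zeros(self.n_drivers)
        self.driver_trend = np.broadcast_to(
            np.asarray(self.driver_trend, dtype=float), (self.n_drivers,)
        ).copy()
        if self.beta is None:
            self.beta = np.zeros(self.n_drivers)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (self.n_drivers,):
            raise ValueError("beta must have one coefficient per driver")
        for j, m, _ in self.mediation_list:
            if not (0 <= j < self.n_drivers):
                raise ValueError(f"mediation references unknown driver {j}")
            if not (0 <= m < self.n_traits):
                raise ValueError(f"mediation references unknown trait {m}")
        if self.n_traits == 0 and self.mediation_list:
            raise ValueError("mediation_list requires n_traits >= 1")
        if not (0 <= self.n_fulllist_groups <= self.n_groups):
            raise ValueError("n_fulllist_groups out of range")

    @property
    def gamma(self) -> np.ndarray:
        """Mediation coefficients as an (n_drivers, n_traits) matrix."""
        g = np.zeros((self.n_drivers, max(self.n_traits, 1)))
        for j, m, strength in self.mediation_list:
            g[j, m] += strength
        return g[:, : self.n_traits] if self.n_traits else g[:, :0]

    def data_kind(self, group: int) -> str:
        return FULL_LIST if group < self.n_fulllist_groups else PRESENCE_ONLY


@dataclass
class DriverStack:
    """Gridded driver values over space and time.

    ``values`` has shape (n_drivers, n_years, ny, nx); pixel (x, y) uses
    x = column index (easting) and y = row index (northing, 0 = south edge).
    """

    values: np.ndarray
    years: np.ndarray
    driver_names: list[str]

    @property
    def n_drivers(self) -> int:
        return self.values.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[2], self.values.shape[3]

    def at(self, x: np.ndarray, y: np.ndarray, year: np.ndarray) -> np.ndarray:
        """Driver vectors (n, n_drivers) at pixel-year coordinates."""
        x = np.asarray(x, dtype=int)
        y = np.asarray(y, dtype=int)
        yi = np.searchsorted(self.years, np.asarray(year, dtype=int))
        if np.any(yi >= len(self.years)) or np.any(self.years[yi] != np.asarray(year)):
            raise ValueError("year outside the driver stack span")
        ny, nx = self.grid_shape
        if np.any((x < 0) | (x >= nx) | (y < 0) | (y >= ny)):
            raise ValueError("pixel coordinates off the driver grid")
        return self.values[:, yi, y, x].T

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: pixel_id, x, y, year, driver, value."""
        d, t, ny, nx = self.values.shape
        dd, tt, yy, xx = np.meshgrid(
            np.arange(d), self.years, np.arange(ny), np.arange(nx), indexing="ij"
        )
        return pd.DataFrame(
            {
                "pixel_id": (yy * nx + xx).ravel(),
                "x": xx.ravel(),
                "y": yy.ravel(),
                "year": tt.ravel(),
                "driver": np.asarray(self.driver_names)[dd.ravel()],
                "value": self.values.ravel(),
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DriverStack":
        names = list(pd.unique(frame["driver"]))
        years = np.sort(frame["year"].unique())
        ny = int(frame["y"].max()) + 1
        nx = int(frame["x"].max()) + 1
        values = np.full((len(names), len(years), ny, nx), np.nan)
        di = pd.Categorical(frame["driver"], categories=names).codes
        yi = np.searchsorted(years, frame["year"].to_numpy())
        values[di, yi, frame["y"].to_numpy(), frame["x"].to_numpy()] = frame["value"].to_numpy()
        return cls(values=values, years=years, driver_names=names)

    @classmethod
    def read_csv(cls, path: str | Path) -> "DriverStack":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class SpeciesTable:
    """Species-level table: group membership, standardised traits, a flattened
    taxonomy block (one-hot subclades), and true baseline logits."""

    frame: pd.DataFrame
    n_traits: int

    @property
    def species(self) -> list[str]:
        return list(self.frame["species"])

    @property
    def groups(self) -> np.ndarray:
        return self.frame["group"].to_numpy()

    @property
    def trait_names(self) -> list[str]:
        return [f"trait_{m}" for m in range(self.n_traits)]

    @property
    def taxonomy_names(self) -> list[str]:
        return [c for c in self.frame.columns if c.startswith("tax_")]

    def trait_matrix(self, include_taxonomy: bool = True) -> np.ndarray:
        cols = self.trait_names + (self.taxonomy_names if include_taxonomy else [])
        if not cols:
            return np.zeros((len(self.frame), 0))
        return self.frame[cols].to_numpy(dtype=float)

    @property
    def baseline(self) -> np.ndarray:
        return self.frame["baseline"].to_numpy(dtype=float)

    def write_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass
class TruthTables:
    """Ground truth attached to one world: the configured coefficients, the
    full probability hypercube and the true trait assemblages per region-year."""

    beta: np.ndarray                      # (n_drivers,)
    gamma: np.ndarray                     # (n_drivers, n_traits)
    baseline: np.ndarray                  # (n_species,)
    probability: np.ndarray               # (n_species, n_years, ny, nx)
    assemblage: pd.DataFrame              # trait, region, year, value
    region_cuts: np.ndarray               # northing cut values used

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.assemblage.to_csv(directory / "true_assemblage.csv", index=False)
        manifest = {
            "beta": self.beta.tolist(),
            "gamma": self.gamma.tolist(),
            "baseline": self.baseline.tolist(),
            "region_cuts": self.region_cuts.tolist(),
        }
        (directory / "truth_manifest.json").write_text(json.dumps(manifest, indent=2))


def generate_drivers(config: WorldConfig) -> DriverStack:
    """Spatially autocorrelated driver fields with linear temporal trends.

    Each driver is a mixture of a static smooth field and yearly smooth
    anomalies (share set by ``temporal_persistence``), standardised to zero
    mean and unit SD over all pixels and years, after which the configured
    per-driver trend (SD units/year) is added.
    """
    if config.smoothing_scale >= config.grid_size:
        raise ValueError(
            "smoothing_scale must be smaller than grid_size (field otherwise constant)"
        )
    rng = _rng(config.seed, _STREAM_DRIVERS)
    n = config.grid_size
    rho = float(np.clip(config.temporal_persistence, 0.0, 1.0))
    years = config.first_year + np.arange(config.years)
    values = np.empty((config.n_drivers, config.years, n, n))
    for j in range(config.n_drivers):
        base = gaussian_filter(rng.standard_normal((n, n)), config.smoothing_scale, mode="wrap")
        anomalies = gaussian_filter(
            rng.standard_normal((config.years, n, n)),
            (0, config.smoothing_scale, config.smoothing_scale),
            mode="wrap",
        )
        raw = np.sqrt(rho) * base[None] + np.sqrt(1.0 - rho) * anomalies
        raw = (raw - raw.mean()) / raw.std()
        values[j] = raw + config.driver_trend[j] * np.arange(config.years)[:, None, None]
    names = [f"driver_{j}" for j in range(config.n_drivers)]
    return DriverStack(values=values, years=years, driver_names=names)


def generate_species(config: WorldConfig) -> SpeciesTable:
    """Trait table with within-group standardisation and a taxonomy block.

    Raw traits are drawn with group-specific location and scale, then
    standardised to mean 0 / SD 1 within each group — the cross-group
    comparability convention for traits measured on unlike scales. A
    two-level synthetic taxonomy (random subclade within each group) is
    appended as one-hot columns.
    """
    if config.n_traits == 0 and config.mediation_list:
        raise ValueError("cannot mediate through traits when n_traits == 0")
    rng = _rng(config.seed, _STREAM_SPECIES)
    rows = []
    n_subclades = 2
    for g in range(config.n_groups):
        mu = rng.normal(0.0, 2.0, size=config.n_traits)
        scale = np.exp(rng.normal(0.0, 0.5, size=config.n_traits))
        raw = mu + scale * rng.standard_normal((config.species_per_group, config.n_traits))
        sd = raw.std(axis=0)
        if config.species_per_group == 1 or np.any(sd == 0):
            warnings.warn(
                f"group {g}: zero trait variance, standardised trait set to 0", stacklevel=2
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            std = np.where(sd > 0, (raw - raw.mean(axis=0)) / np.where(sd == 0, 1.0, sd), 0.0)
        if config.species_per_group == 1:
            std = np.zeros_like(raw)
        subclade = rng.integers(0, n_subclades, size=config.species_per_group)
        baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.species_per_group)
        for i in range(config.species_per_group):
            row = {"species": f"g{g}_s{i:02d}", "group": g, "baseline": baseline[i]}
            for m in range(config.n_traits):
                row[f"trait_{m}"] = std[i, m]
            for g2 in range(config.n_groups):
                for c in range(n_subclades):
                    row[f"tax_{g2}_{c}"] = float(g2 == g and c == subclade[i])
            rows.append(row)
    return SpeciesTable(frame=pd.DataFrame(rows), n_traits=config.n_traits)


def _region_cuts(config: WorldConfig) -> np.ndarray:
    """Default latitudinal slicing: thirds of the northing range."""
    return np.array([config.grid_size / 3.0, 2.0 * config.grid_size / 3.0])


def compute_truth(
    config: WorldConfig,
    drivers: DriverStack,
    species: SpeciesTable,
    region_cuts: np.ndarray | None = None,
) -> TruthTables:
    """True occupancy probabilities and true trait assemblages.

    The assemblage is the probability-weighted community mean trait per
    region-year over every pixel (skill weights all 1 — the truth model is a
    perfect predictor of itself).
    """
    beta = config.beta
    gamma = config.gamma
    traits = species.trait_matrix(include_taxonomy=False)
    # per-species, per-driver logit coefficient: beta_j + sum_m gamma_jm * t_sm
    coef = beta[None, :] + traits @ gamma.T            # (S, D)
    logit = np.einsum("sj,jtyx->styx", coef, drivers.values)
    logit += species.baseline[:, None, None, None]
    prob = expit(logit)

    cuts = _region_cuts(config) if region_cuts is None else np.asarray(region_cuts, float)
    ny = drivers.grid_shape[0]
    region_of_row = np.searchsorted(cuts, np.arange(ny), side="right")
    records = []
    for m in range(config.n_traits):
        t = traits[:, m]
        num = np.einsum("s,styx->tyx", t, prob)
        den = prob.sum(axis=0)
        per_pixel = num / den                          # (years, ny, nx)
        for r in range(len(cuts) + 1):
            rows = region_of_row == r
            if not rows.any():
                continue
            vals = per_pixel[:, rows, :].reshape(config.years, -1).mean(axis=1)
            for yi, year in enumerate(drivers.years):
                records.append(
                    {"trait": f"trait_{m}", "region": r, "year": int(year), "value": vals[yi]}
                )
    assemblage = pd.DataFrame(records, columns=["trait", "region", "year", "value"])
    return TruthTables(
        beta=beta.copy(),
        gamma=gamma.copy(),
        baseline=species.baseline.copy(),
        probability=prob,
        assemblage=assemblage,
        region_cuts=cuts,
    )


def sample_records(
    config: WorldConfig, species: SpeciesTable, truth: TruthTables
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Biased occurrence sampling from the truth model.

    Visits are (site, year) draws: yearly effort grows as exp(bias_time *
    year_index) and sites within a year are drawn without replacement with
    probability proportional to exp(bias_south * southness), southness being
    the inverted normalised northing. At a visited site each species'
    presence is a Bernoulli(true probability) realisation, thinned by
    ``detection_prob``. Full-list groups record every species as 1/0;
    presence-only groups record only the detected presences.

    Returns (records, visits): records has columns species, group, x, y,
    year, status, data_kind; visits logs every visited (x, y, year).
    """
    rng = _rng(config.seed, _STREAM_SAMPLING)
    n = config.grid_size
    n_pix = n * n
    year_idx = np.arange(config.years)
    year_w = np.exp(config.bias_time * year_idx)
    year_w /= year_w.sum()
    total_visits = config.visits_per_year * config.years
    n_per_year = rng.multinomial(total_visits, year_w)

    yy, xx = np.divmod(np.arange(n_pix), n)
    southness = 1.0 - yy / max(n - 1, 1)
    site_w = np.exp(config.bias_south * southness)
    site_w /= site_w.sum()

    groups = species.groups
    prob = truth.probability
    visit_rows: list[tuple[int, int, int]] = []
    rec: dict[str, list] = {"species": [], "group": [], "x": [], "y": [], "year": [], "status": []}
    for yi in range(config.years):
        k = min(int(n_per_year[yi]), n_pix)
        if k == 0:
            continue
        sites = rng.choice(n_pix, size=k, replace=False, p=site_w)
        year = int(config.first_year + yi)
        for site in sites:
            sy, sx = int(yy[site]), int(xx[site])
            visit_rows.append((sx, sy, year))
            p = prob[:, yi, sy, sx]
            present = rng.random(len(p)) < p
            detected = present & (rng.random(len(p)) < config.detection_prob)
            for s, name in enumerate(species.species):
                kind = config.data_kind(int(groups[s]))
                if kind == FULL_LIST:
                    rec["species"].append(name)
                    rec["group"].append(int(groups[s]))
                    rec["x"].append(sx)
                    rec["y"].append(sy)
                    rec["year"].append(year)
                    rec["status"].append(int(detected[s]))
                elif detected[s]:
                    rec["species"].append(name)
                    rec["group"].append(int(groups[s]))
                    rec["x"].append(sx)
                    rec["y"].append(sy)
                    rec["year"].append(year)
                    rec["status"].append(1)
    if not visit_rows:
        raise RuntimeError("sampling produced zero visits; increase visits_per_year")
    records = pd.DataFrame(rec)
    records["data_kind"] = [config.data_kind(g) for g in records["group"]]
    visits = pd.DataFrame(visit_rows, columns=["x", "y", "year"])
    return records, visits


def generate_world(config: WorldConfig):
    """Convenience: drivers, species, truth and records for one config."""
    drivers = generate_drivers(config)
    species = generate_species(config)
    truth = compute_truth(config, drivers, species)
    records, visits = sample_records(config, species, truth)
    return drivers, species, truth, records, visits
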