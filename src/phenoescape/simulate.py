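"""Synthetic herbarium-style data with the generative structure the model assumes.

The generator inverts the analysis model: event day-of-year for specimen
``i`` of species ``j`` is

    doy_i = beta0 + beta1 * SpringT_i + beta2 * Elevation_i + alpha_j + eps_i

with species offsets ``alpha_j ~ N(0, alpha_sd^2)`` drawn once per dataset
and residuals ``eps_i ~ N(0, sigma^2)``.  Spring temperatures carry a
latitudinal gradient, a weak secular warming trend, and continent-specific
interannual noise (North America noisier than Europe/Asia, mirroring the
higher interannual variability of North American springs).  Monthly
February–May temperatures are generated so that the March–April mean equals
each record's spring temperature exactly.

Everything is reproducible from the config seed; the true parameters and
the realised species offsets are returned in a manifest because they are
estimands for parameter-recovery tests, not nuisance values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd

from .grids import ClimateGrid
from .records import CONTINENTS, STRATA, HerbariumRecord, RecordSet

#: default interannual spring-temperature s.d. (°C) per continent;
#: North America is noisier than Europe/Asia.
INTERANNUAL_SD = {"NorthAmerica": 2.5, "Europe": 1.5, "Asia": 1.5}


def default_temp_mean(latitude: np.ndarray, year: np.ndarray) -> np.ndarray:
    """Expected March–April mean temperature (°C) by latitude and year.

    8 °C at 45° N, −0.4 °C per degree of latitude northwards, and a mild
    0.01 °C/yr warming trend from 1960.
    """
    return 8.0 - 0.4 * (np.asarray(latitude) - 45.0) + 0.01 * (
        np.asarray(year) - 1960.0
    )


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic specimen generator.

    beta0 : days — community DOY intercept.
    beta1 : days·°C⁻¹ — spring-temperature sensitivity (negative = earlier
        phenology in warmer springs).
    beta2 : days·m⁻¹ — elevation sensitivity.
    alpha_sd : days — s.d. of the per-species intercept offsets.
    sigma : days — residual s.d.
    """

    n_species: int = 6
    n_per_species: int = 200
    beta0: float = 145.0
    beta1: float = -3.5
    beta2: float = 0.02
    alpha_sd: float = 5.0
    sigma: float = 5.0
    stratum: str = "wildflower"
    continent: str = "NorthAmerica"
    temp_interannual_sd: float | None = None  # None → continent default
    temp_mean_fn: Callable[[np.ndarray, np.ndarray], np.ndarray] = default_temp_mean
    lat_range: tuple[float, float] = (35.0, 55.0)
    lon_range: tuple[float, float] = (-95.0, -65.0)
    elev_range: tuple[float, float] = (0.0, 1500.0)
    year_range: tuple[int, int] = (1901, 2020)
    # monthly structure: Mar/Apr split symmetrically about the spring mean,
    # Feb/May offset from it with independent noise
    month_spread_sd: float = 1.0
    flank_offset: dict = field(default_factory=lambda: {2: -3.0, 5: 5.0})
    flank_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.n_per_species < 1:
            raise ValueError("n_per_species must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.alpha_sd < 0:
            raise ValueError("alpha_sd must be >= 0")
        if self.stratum not in STRATA:
            raise ValueError(f"stratum {self.stratum!r} not in {STRATA}")
        if self.continent not in CONTINENTS:
            raise ValueError(f"continent {self.continent!r} not in {CONTINENTS}")

    @property
    def interannual_sd(self) -> float:
        if self.temp_interannual_sd is not None:
            return self.temp_interannual_sd
        return INTERANNUAL_SD[self.continent]


@dataclass
class MonthlyClimateSeries:
    """Per-record February–May monthly mean temperatures (°C).

    ``temps`` is indexed by record_id with integer month columns 2..5.
    """

    temps: pd.DataFrame

    MONTHS = (2, 3, 4, 5)

    def __post_init__(self) -> None:
        missing = [m for m in self.MONTHS if m not in self.temps.columns]
        if missing:
            raise ValueError(f"missing months: {missing}")

    def covers(self, recordset: RecordSet) -> bool:
        ids = {r.record_id for r in recordset}
        return ids <= set(self.temps.index)

    def window_mean(self, start_month: int, length: int) -> pd.Series:
        months = list(range(start_month, start_month + length))
        return self.temps[months].mean(axis=1)


def simulate_records(config: SyntheticConfig) -> tuple[RecordSet, dict]:
    """Draw a herbarium-style record set from the generative model.

    Returns the record set (integer-rounded DOY, round-half-even) and a
    manifest holding all true parameters, the realised species offsets, and
    the round-free real-valued DOY per record.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n = config.n_species * config.n_per_species
    species = [
        f"{config.stratum}_{config.continent}_sp{j:02d}"
        for j in range(1, config.n_species + 1)
    ]
    sp_idx = np.repeat(np.arange(config.n_species), config.n_per_species)

    lat = rng.uniform(*config.lat_range, size=n)
    lon = rng.uniform(*config.lon_range, size=n)
    elev = rng.uniform(*config.elev_range, size=n)
    year = rng.integers(config.year_range[0], config.year_range[1] + 1, size=n)

    temp = config.temp_mean_fn(lat, year) + rng.normal(
        0.0, config.interannual_sd, size=n
    )
    alpha = rng.normal(0.0, config.alpha_sd, size=config.n_species)
    eps = rng.normal(0.0, config.sigma, size=n)
    doy_real = (
        config.beta0
        + config.beta1 * temp
        + config.beta2 * elev
        + alpha[sp_idx]
        + eps
    )
    doy_int = np.clip(np.rint(doy_real), 1, 366).astype(int)  # rint = half-even

    # secondary drivers for model-comparison screens: winter temperature is
    # weakly tied to spring temperature; precipitation is pure noise
    winter = 0.3 * temp - 8.0 + rng.normal(0.0, 2.0, size=n)
    annual_precip = rng.normal(800.0, 150.0, size=n)
    spring_precip = rng.normal(200.0, 50.0, size=n)

    records = [
        HerbariumRecord(
            record_id=f"{config.stratum[:2]}-{config.continent[:2]}-{i:05d}",
            species=species[sp_idx[i]],
            stratum=config.stratum,
            continent=config.continent,
            latitude=float(lat[i]),
            longitude=float(lon[i]),
            elevation=float(elev[i]),
            year=int(year[i]),
            doy=int(doy_int[i]),
            spring_temp=float(temp[i]),
            extra={
                "winter_temp_c": float(winter[i]),
                "annual_precip_mm": float(annual_precip[i]),
                "spring_precip_mm": float(spring_precip[i]),
            },
        )
        for i in range(n)
    ]
    rs = RecordSet(records)
    manifest = {
        "beta0": config.beta0,
        "beta1": config.beta1,
        "beta2": config.beta2,
        "alpha_sd": config.alpha_sd,
        "sigma": config.sigma,
        "stratum": config.stratum,
        "continent": config.continent,
        "seed": config.seed,
        "n_records": n,
        "alpha": {sp: float(a) for sp, a in zip(species, alpha)},
        "doy_real": {r.record_id: float(d) for r, d in zip(records, doy_real)},
    }
    return rs, manifest


def simulate_monthly(
    config: SyntheticConfig, recordset: RecordSet
) -> MonthlyClimateSeries:
    """February–May monthly temperatures consistent with each record.

    March and April split symmetrically about the record's spring
    temperature, so their mean reproduces it exactly; February and May are
    offset flanks with independent noise (colder February, warmer May).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    ids = [r.record_id for r in recordset]
    spring = np.array([r.spring_temp for r in recordset])
    n = len(ids)
    half = rng.normal(0.0, config.month_spread_sd, size=n)
    mar = spring + half
    apr = spring - half
    feb = spring + config.flank_offset[2] + rng.normal(0, config.flank_noise_sd, n)
    may = spring + config.flank_offset[5] + rng.normal(0, config.flank_noise_sd, n)
    df = pd.DataFrame({2: feb, 3: mar, 4: apr, 5: may}, index=pd.Index(ids, name="record_id"))
    return MonthlyClimateSeries(df)


def simulate_study(
    seed: int = 0,
    continents: tuple[str, ...] = CONTINENTS,
    n_species: int = 6,
    n_per_species: int = 100,
    tree_beta1: dict | None = None,
    wildflower_beta1: float = -3.1,
    **overrides,
) -> tuple[RecordSet, dict]:
    """A full multi-continent, two-stratum dataset for pipeline runs.

    Tree sensitivity defaults differ by continent (North American canopy
    trees the most temperature-sensitive); wildflower sensitivity is shared.
    """
    tree_beta1 = tree_beta1 or {"NorthAmerica": -3.6, "Europe": -2.8, "Asia": -2.6}
    lon_ranges = {
        "NorthAmerica": (-95.0, -65.0),
        "Europe": (-5.0, 30.0),
        "Asia": (100.0, 130.0),
    }
    all_records: list[HerbariumRecord] = []
    manifest: dict = {"seed": seed, "groups": {}}
    sub = np.random.SeedSequence(seed).generate_state(12, dtype=np.uint32)
    k = 0
    for stratum in STRATA:
        for continent in continents:
            beta1 = tree_beta1[continent] if stratum == "tree" else wildflower_beta1
            cfg = SyntheticConfig(
                n_species=n_species,
                n_per_species=n_per_species,
                beta1=beta1,
                stratum=stratum,
                continent=continent,
                lon_range=lon_ranges[continent],
                seed=int(sub[k]) % (2**31),
                **overrides,
            )
            rs, man = simulate_records(cfg)
            man.pop("doy_real")
            all_records.extend(rs.records)
            manifest["groups"][f"{stratum}:{continent}"] = man
            k += 1
    return RecordSet(all_records), manifest


def simulate_grids(
    extent: tuple[float, float, float, float] = (-90.0, -70.0, 38.0, 52.0),
    resolution: float = 1.0,
    scenario_delta: float = 5.0,
) -> dict[str, ClimateGrid]:
    """Small aligned fixture grids: spring temperature (current and future),
    elevation, and deciduous-forest fraction.

    ``extent`` is (lon_min, lon_max, lat_min, lat_max); cells are
    ``resolution`` degrees, cell-centre registered, north-up.  The future
    scenario is the current field plus ``scenario_delta`` everywhere.  The
    forest-fraction field deliberately contains cells below the 1% masking
    threshold.
    """
    lon_min, lon_max, lat_min, lat_max = extent
    if lon_max <= lon_min or lat_max <= lat_min or resolution <= 0:
        raise ValueError("extent must be non-empty and resolution positive")
    nx = int(round((lon_max - lon_min) / resolution))
    ny = int(round((lat_max - lat_min) / resolution))
    transform = (
        lon_min + resolution / 2.0,
        lat_max - resolution / 2.0,
        resolution,
        -resolution,
    )
    lat = transform[1] + transform[3] * np.arange(ny)
    lon = transform[0] + transform[2] * np.arange(nx)
    LAT, LON = np.meshgrid(lat, lon, indexing="ij")

    current = 8.0 - 0.4 * (LAT - 45.0) + 0.5 * np.sin(np.radians(4.0 * LON))
    elevation = 400.0 + 350.0 * (1.0 + np.sin(np.radians(10.0 * LON)) * np.cos(np.radians(8.0 * LAT)))
    forest = np.clip(0.5 + 0.5 * np.sin(np.radians(9.0 * LON + 5.0 * LAT)), 0.0, 1.0)
    # guarantee sub-threshold and supra-threshold cells for mask tests
    forest.flat[:: max(forest.size // 10, 1)] = 0.005

    mk = lambda v, var, scen: ClimateGrid(
        values=v.astype(np.float32), transform=transform, variable=var, scenario=scen
    )
    return {
        "spring_temp_current": mk(current, "spring_temp", "current"),
        "spring_temp_future": mk(current + scenario_delta, "spring_temp", "future"),
        "elevation": mk(elevation, "elevation", "none"),
        "forest_fraction": mk(forest, "forest_fraction", "none"),
    }
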