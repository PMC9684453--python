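"""Specimen records: domain types, validation, and CSV readers/writers.

One :class:`HerbariumRecord` is a single scored specimen — a species, a
forest stratum (canopy tree vs. understory wildflower), a continent, a
georeferenced location, a collection year, the day-of-year (DOY) of the
scored phenological event (leaf-out for trees, first flowering for
wildflowers), and the average March–April temperature at that location and
year.  A :class:`RecordSet` is an ordered collection of records together
with a deterministic species index used to build the design matrix of the
hierarchical model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STRATA = ("tree", "wildflower")
CONTINENTS = ("Asia", "Europe", "NorthAmerica")

#: canonical CSV header
CANONICAL_COLUMNS = (
    "record_id",
    "species",
    "stratum",
    "continent",
    "lat",
    "lon",
    "elev_m",
    "year",
    "doy",
    "spring_temp_c",
)

#: optional extra driver columns recognised by model comparison
OPTIONAL_COLUMNS = ("winter_temp_c", "annual_precip_mm", "spring_precip_mm")

MIN_YEAR = 1901  # gridded climate estimates start in 1901; earlier specimens excluded


class SchemaError(ValueError):
    """A required column is missing from an input table."""


def spring_temperature(march_mean: float, april_mean: float) -> float:
    """Average March–April temperature (°C) from the two monthly means.

    This is the fixed spring forcing metric used throughout: the arithmetic
    mean of the March and April average monthly temperatures at a record's
    location and year.
    """
    if not (math.isfinite(march_mean) and math.isfinite(april_mean)):
        raise ValueError(
            f"monthly means must be finite, got ({march_mean}, {april_mean})"
        )
    return (march_mean + april_mean) / 2.0


@dataclass(frozen=True)
class HerbariumRecord:
    """A single scored specimen observation; the unit of likelihood."""

    record_id: str
    species: str
    stratum: str
    continent: str
    latitude: float
    longitude: float
    elevation: float
    year: int
    doy: int
    spring_temp: float
    extra: Mapping[str, float] = field(default_factory=dict, compare=False)

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if valid)."""
        problems = []
        if self.stratum not in STRATA:
            problems.append(f"stratum {self.stratum!r} not in {STRATA}")
        if self.continent not in CONTINENTS:
            problems.append(f"continent {self.continent!r} not in {CONTINENTS}")
        if not -90.0 <= self.latitude <= 90.0:
            problems.append(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            problems.append(f"longitude {self.longitude} outside [-180, 180]")
        if self.year < MIN_YEAR:
            problems.append(f"year {self.year} precedes {MIN_YEAR}")
        if not 1 <= self.doy <= 366:
            problems.append(f"doy {self.doy} outside [1, 366]")
        if not math.isfinite(self.spring_temp):
            problems.append("spring_temp not finite")
        if not math.isfinite(self.elevation):
            problems.append("elevation not finite")
        return problems


@dataclass
class RecordSet:
    """Ordered records plus a lexicographic species index (species → 1..J)."""

    records: list[HerbariumRecord]
    species_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.species_index:
            self.species_index = _build_species_index(self.records)
        missing = {r.species for r in self.records} - set(self.species_index)
        if missing:
            raise ValueError(f"records reference unindexed species: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def n_species(self) -> int:
        return len(self.species_index)

    @property
    def species(self) -> list[str]:
        """Species names ordered by index."""
        return sorted(self.species_index, key=self.species_index.__getitem__)

    def subset(self, stratum: str | None = None, continent: str | None = None,
               reindex_species: bool = True) -> "RecordSet":
        """Records matching the given stratum and/or continent.

        By default the species index is rebuilt for the subset (each
        stratum×continent fit indexes only its own species).
        """
        recs = [
            r for r in self.records
            if (stratum is None or r.stratum == stratum)
            and (continent is None or r.continent == continent)
        ]
        if reindex_species:
            return RecordSet(recs)
        return RecordSet(recs, dict(self.species_index))

    def groups(self) -> list[tuple[str, str]]:
        """Distinct (stratum, continent) pairs present, deterministic order."""
        present = {(r.stratum, r.continent) for r in self.records}
        return [
            (s, c) for s in STRATA for c in CONTINENTS if (s, c) in present
        ]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "record_id": r.record_id,
                "species": r.species,
                "stratum": r.stratum,
                "continent": r.continent,
                "lat": r.latitude,
                "lon": r.longitude,
                "elev_m": r.elevation,
                "year": r.year,
                "doy": r.doy,
                "spring_temp_c": r.spring_temp,
            }
            row.update(r.extra)
            rows.append(row)
        return pd.DataFrame(rows)


def _build_species_index(records: Iterable[HerbariumRecord]) -> dict[str, int]:
    return {sp: j + 1 for j, sp in enumerate(sorted({r.species for r in records}))}


@dataclass
class ReadReport:
    """Outcome of reading a records table: accepted set + per-row rejects."""

    recordset: RecordSet
    rejects: pd.DataFrame  # columns: row, record_id, reason
    n_input: int

    @property
    def n_accepted(self) -> int:
        return len(self.recordset)

    @property
    def n_rejected(self) -> int:
        return len(self.rejects)

    def write_rejects(self, path: str | Path) -> None:
        self.rejects.to_csv(path, index=False)


def read_records(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> ReadReport:
    """Read a specimen CSV into a validated :class:`RecordSet`.

    Parameters
    ----------
    path:
        CSV file with a header row.  The canonical header is
        ``record_id, species, stratum, continent, lat, lon, elev_m, year,
        doy, spring_temp_c``; foreign files are adapted via ``schema``.
    schema:
        Optional mapping from canonical column name to the file's column
        name, for files using different headers.

    Returns
    -------
    ReadReport
        Accepted records (with a lexicographic species index) plus a
        rejects table giving the 0-based data row and the reason for every
        rejected row; ``n_accepted + n_rejected == n_input``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    return records_from_dataframe(df, schema=schema)


def records_from_dataframe(
    df: pd.DataFrame, schema: Mapping[str, str] | None = None
) -> ReadReport:
    """Validate a specimen table already in memory; see :func:`read_records`."""
    if schema:
        rename = {v: k for k, v in schema.items()}
        df = df.rename(columns=rename)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")

    extra_cols = [c for c in OPTIONAL_COLUMNS if c in df.columns]
    accepted: list[HerbariumRecord] = []
    rejects: list[dict] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        try:
            rec = HerbariumRecord(
                record_id=str(row["record_id"]),
                species=str(row["species"]),
                stratum=str(row["stratum"]),
                continent=str(row["continent"]),
                latitude=float(row["lat"]),
                longitude=float(row["lon"]),
                elevation=float(row["elev_m"]),
                year=int(row["year"]),
                doy=int(row["doy"]),
                spring_temp=float(row["spring_temp_c"]),
                extra={c: float(row[c]) for c in extra_cols},
            )
        except (TypeError, ValueError) as exc:
            rejects.append(
                {"row": i, "record_id": str(row.get("record_id", "")),
                 "reason": f"unparseable: {exc}"}
            )
            continue
        problems = rec.validate()
        if problems:
            rejects.append(
                {"row": i, "record_id": rec.record_id, "reason": "; ".join(problems)}
            )
        else:
            accepted.append(rec)
    rej_df = pd.DataFrame(rejects, columns=["row", "record_id", "reason"])
    return ReadReport(RecordSet(accepted), rej_df, n_input=len(df))


def write_records(recordset: RecordSet, path: str | Path) -> None:
    """Write a RecordSet to the canonical CSV layout."""
    recordset.to_dataframe().to_csv(path, index=False)
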