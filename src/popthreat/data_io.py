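"""Reading, filtering and preparing LPD-style population time series.

The Living Planet Database (LPD) dialect handled here is a wide CSV: one row
per population, a block of metadata columns (identifiers, site coordinates,
system, taxon, binary threat flags) followed by one column per calendar year
whose header is the year integer.  Abundance cells may be blank (years with
no survey).

Series are prepared for modelling by log-transforming abundance and centering
both the log response and the year covariate at their within-series means, so
that every series has intercept zero and only slopes need to be modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The six broad threat categories (IUCN-style), in canonical order.
THREATS: tuple[str, ...] = (
    "climate_change",
    "disease",
    "exploitation",
    "habitat_loss",
    "invasive",
    "pollution",
)

SYSTEMS: tuple[str, ...] = ("freshwater", "marine", "terrestrial")
TAXA: tuple[str, ...] = ("amphibian", "bird", "fish", "mammal", "reptile")

#: Mandatory metadata columns of the wide CSV dialect.
METADATA_COLUMNS: tuple[str, ...] = (
    "population_id",
    "species_id",
    "latitude",
    "longitude",
    "system",
    "taxon",
) + THREATS


class DataFormatError(ValueError):
    """A table does not conform to the wide LPD dialect."""


class RecordError(ValueError):
    """A single row carries an unusable value; the message names the row."""


class UnusableSeriesError(ValueError):
    """A series cannot be prepared (e.g. all abundances are zero)."""


@dataclass(frozen=True)
class PopulationSeries:
    """One population's abundance time series with its metadata.

    ``observations`` is an ordered tuple of ``(year, abundance)`` pairs with
    strictly increasing years and nonnegative abundances.  ``threats`` is a
    frozenset of 0-3 of the six categories in :data:`THREATS`.
    """

    population_id: str
    species_id: str
    site: tuple[float, float]  # (latitude, longitude), degrees
    system: str
    taxon: str
    observations: tuple[tuple[int, float], ...]
    threats: frozenset[str] = field(default_factory=frozenset)
    threat_status_known: bool = True

    def __post_init__(self) -> None:
        years = [y for y, _ in self.observations]
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError(
                f"population {self.population_id}: years must be strictly increasing"
            )
        if any(a < 0 for _, a in self.observations):
            raise RecordError(
                f"population {self.population_id}: negative abundance"
            )
        if len(self.threats) > 3:
            raise ValueError(
                f"population {self.population_id}: more than 3 threats"
            )
        unknown = self.threats - set(THREATS)
        if unknown:
            raise ValueError(
                f"population {self.population_id}: unknown threat(s) {sorted(unknown)}"
            )
        lat, lon = self.site
        if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
            raise ValueError(
                f"population {self.population_id}: coordinates out of range"
            )

    @property
    def years(self) -> np.ndarray:
        return np.array([y for y, _ in self.observations], dtype=int)

    @property
    def abundances(self) -> np.ndarray:
        return np.array([a for _, a in self.observations], dtype=float)

    @property
    def span_years(self) -> int:
        """Inclusive calendar span (last - first + 1)."""
        ys = self.years
        return int(ys[-1] - ys[0] + 1) if ys.size else 0

    @property
    def n_observations(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class PreparedSeries:
    """Centered covariate and response vectors ready for the model."""

    population_id: str
    centered_year: np.ndarray
    centered_log_abundance: np.ndarray
    offset_applied: float = 0.0

    def __post_init__(self) -> None:
        if len(self.centered_year) != len(self.centered_log_abundance):
            raise ValueError("covariate/response length mismatch")


def read_lpd_table(path, *, sentinel_values: Sequence[str] = ("", "NA", "NULL")) -> list[PopulationSeries]:
    """Read a wide LPD-style CSV into a list of :class:`PopulationSeries`.

    Blank or sentinel year cells become missing observations.  Raises
    :class:`DataFormatError` when a mandatory metadata column is absent and
    :class:`RecordError` when an abundance cell is unparseable.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"missing mandatory column(s): {', '.join(missing)}")

    year_cols: list[tuple[int, str]] = []
    for col in df.columns:
        if col in METADATA_COLUMNS or col == "threat_status_known":
            continue
        try:
            year_cols.append((int(col), col))
        except ValueError as exc:
            raise DataFormatError(f"non-year extra column {col!r}") from exc
    year_cols.sort()

    sentinels = set(sentinel_values)
    out: list[PopulationSeries] = []
    for _, row in df.iterrows():
        pid = row["population_id"]
        obs: list[tuple[int, float]] = []
        for year, col in year_cols:
            cell = row[col].strip()
            if cell in sentinels:
                continue
            try:
                obs.append((year, float(cell)))
            except ValueError as exc:
                raise RecordError(
                    f"row {pid!r}: unparseable abundance {cell!r} in year {year}"
                ) from exc
        threats = frozenset(t for t in THREATS if _truthy(row[t]))
        known = True
        if "threat_status_known" in df.columns:
            known = _truthy(row["threat_status_known"], default=True)
        out.append(
            PopulationSeries(
                population_id=pid,
                species_id=row["species_id"],
                site=(float(row["latitude"]), float(row["longitude"])),
                system=row["system"],
                taxon=row["taxon"],
                observations=tuple(obs),
                threats=threats,
                threat_status_known=known,
            )
        )
    return out


def _truthy(cell: str, default: bool = False) -> bool:
    cell = str(cell).strip().lower()
    if cell in ("", "na"):
        return default
    return cell in ("1", "true", "yes", "t", "y", "1.0")


def write_lpd_table(series: Iterable[PopulationSeries], path) -> None:
    """Write series back to the wide CSV dialect read by :func:`read_lpd_table`."""
    series = list(series)
    all_years = sorted({int(y) for s in series for y in s.years})
    rows = []
    for s in series:
        row: dict[str, object] = {
            "population_id": s.population_id,
            "species_id": s.species_id,
            "latitude": s.site[0],
            "longitude": s.site[1],
            "system": s.system,
            "taxon": s.taxon,
        }
        for t in THREATS:
            row[t] = int(t in s.threats)
        row["threat_status_known"] = int(s.threat_status_known)
        lookup = dict(s.observations)
        for y in all_years:
            row[str(y)] = lookup.get(y, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_long_table(series: Iterable[PopulationSeries], path) -> None:
    """Tidy long export: population_id, year, abundance, semicolon-joined threats."""
    rows = [
        {
            "population_id": s.population_id,
            "year": y,
            "abundance": a,
            "threats": ";".join(sorted(s.threats)),
        }
        for s in series
        for y, a in s.observations
    ]
    pd.DataFrame(rows, columns=["population_id", "year", "abundance", "threats"]).to_csv(
        path, index=False
    )


def filter_series(
    series: Sequence[PopulationSeries],
    min_span_years: int = 10,
    min_points: int = 5,
    require_threat_status: bool = True,
) -> list[PopulationSeries]:
    """Apply the inclusion filters: calendar span, point count, known threat status.

    A series is retained when ``last_year - first_year + 1 >= min_span_years``,
    it has at least ``min_points`` observations, and (when required) its threat
    status is documented.  Order is preserved; the result may be empty.
    """
    return [
        s
        for s in series
        if s.span_years >= min_span_years
        and s.n_observations >= min_points
        and (s.threat_status_known or not require_threat_status)
    ]


def prepare_series(
    s: PopulationSeries,
    zero_policy: float = 0.01,
    centering: str = "log",
) -> PreparedSeries:
    """Center year and log abundance for one series.

    When any abundance is zero, ``zero_policy`` (a fraction of the series
    mean abundance) is added to *every* observation of that series before the
    log so the transform is defined; positive-only series get no offset.

    ``centering="log"`` (default) subtracts the mean of the log abundances;
    ``centering="raw"`` models the mean-centered raw abundance without a log
    transform (the alternative reading of centering-before-transforming).
    """
    if s.n_observations < 2:
        raise UnusableSeriesError(f"population {s.population_id}: fewer than 2 observations")
    a = s.abundances
    if not np.all(np.isfinite(a)):
        raise RecordError(f"population {s.population_id}: non-finite abundance")
    if np.any(a < 0):
        raise RecordError(f"population {s.population_id}: negative abundance")
    years = s.years.astype(float)
    cyear = years - years.mean()

    if centering == "raw":
        y = a - a.mean()
        return PreparedSeries(s.population_id, cyear, y, offset_applied=0.0)
    if centering != "log":
        raise ValueError(f"unknown centering {centering!r}")

    offset = 0.0
    if np.any(a == 0):
        if np.all(a == 0):
            raise UnusableSeriesError(
                f"population {s.population_id}: all abundances zero"
            )
        offset = float(zero_policy * a.mean())
    logs = np.log(a + offset)
    return PreparedSeries(s.population_id, cyear, logs - logs.mean(), offset_applied=offset)


def prepare_all(
    series: Sequence[PopulationSeries], zero_policy: float = 0.01, centering: str = "log"
) -> list[PreparedSeries]:
    return [prepare_series(s, zero_policy, centering) for s in series]
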