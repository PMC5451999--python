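"""Core data structures for station-network particulate-matter panels.

Measurements live in a station × day matrix (``MeasurementPanel``) on the
concentration scale (μg/m³) with NaN marking missing daily means.  Station
coordinates are stored both as WGS84 decimal degrees and as planar metres
under a local projection, because all variogram and kriging distances must
be metric.  Modelling happens on the natural-log scale; back-transform is
plain exponentiation (no lognormal bias correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Station",
    "LocalProjection",
    "MeasurementPanel",
    "CovariateTable",
    "PredictionResult",
    "PanelValidationError",
    "daily_average",
    "log_transform",
    "back_transform",
    "read_panel",
    "write_panel",
    "write_predictions",
    "read_predictions",
]

EARTH_RADIUS_M = 6_371_000.0


class PanelValidationError(ValueError):
    """Raised when measurement input violates a panel invariant."""


@dataclass(frozen=True)
class LocalProjection:
    """Planar projection centred on the network's bounding box.

    A transverse-Mercator-style local projection: metres east/north of the
    centre (``lon0``, ``lat0``), with east scaled by cos(lat0).  Adequate for
    a provincial extent (sub-0.5% distortion over a few hundred km), which is
    all kriging needs.
    """

    lon0: float
    lat0: float

    @classmethod
    def for_bbox(cls, lons, lats) -> "LocalProjection":
        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        return cls(lon0=float((lons.min() + lons.max()) / 2.0),
                   lat0=float((lats.min() + lats.max()) / 2.0))

    def forward(self, lon, lat):
        """(lon, lat) degrees -> (x, y) metres."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        k = math.cos(math.radians(self.lat0)) * EARTH_RADIUS_M
        x = np.radians(lon - self.lon0) * k
        y = np.radians(lat - self.lat0) * EARTH_RADIUS_M
        return x, y

    def inverse(self, x, y):
        """(x, y) metres -> (lon, lat) degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        k = math.cos(math.radians(self.lat0)) * EARTH_RADIUS_M
        lon = self.lon0 + np.degrees(x / k)
        lat = self.lat0 + np.degrees(y / EARTH_RADIUS_M)
        return lon, lat


@dataclass(frozen=True)
class Station:
    """A monitoring site: WGS84 position plus projected planar metres."""

    id: str
    lon: float
    lat: float
    x: float
    y: float

    @classmethod
    def from_lonlat(cls, id: str, lon: float, lat: float,
                    projection: LocalProjection) -> "Station":
        x, y = projection.forward(lon, lat)
        return cls(id=str(id), lon=float(lon), lat=float(lat),
                   x=float(x), y=float(y))


@dataclass
class MeasurementPanel:
    """Station × day matrix of daily mean concentrations.

    ``values[i, j]`` is the daily mean for ``stations[i]`` on ``days[j]``
    (1-based day-of-year indices, ascending).  NaN marks a missing daily
    mean.  ``scale`` is "concentration" (μg/m³) or "log".
    """

    stations: list[Station]
    days: np.ndarray
    values: np.ndarray
    pollutant: str = "PM25"
    scale: str = "concentration"
    projection: LocalProjection | None = None

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.stations), len(self.days)):
            raise PanelValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.stations)} stations × {len(self.days)} days")
        if len({s.id for s in self.stations}) != len(self.stations):
            raise PanelValidationError("station ids are not unique")
        if np.any(np.diff(self.days) <= 0):
            raise PanelValidationError("day indices must be strictly increasing")
        if self.scale == "concentration":
            bad = np.asarray(self.values <= 0) & ~np.isnan(self.values)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise PanelValidationError(
                    f"non-positive concentration at station "
                    f"{self.stations[i].id}, day {self.days[j]}")

    @property
    def n_stations(self) -> int:
        return len(self.stations)

    @property
    def n_days(self) -> int:
        return len(self.days)

    @property
    def station_ids(self) -> list[str]:
        return [s.id for s in self.stations]

    @property
    def coords(self) -> np.ndarray:
        """(n_stations, 2) projected coordinates in metres."""
        return np.array([[s.x, s.y] for s in self.stations], dtype=float)

    def missing_fraction(self) -> float:
        return float(np.isnan(self.values).mean())

    def copy_with(self, **kw) -> "MeasurementPanel":
        if "values" in kw:
            kw["values"] = np.array(kw["values"], dtype=float)
        return replace(self, **kw)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (station_id, lon, lat, day, value); drops missing."""
        rows = []
        for i, s in enumerate(self.stations):
            for j, d in enumerate(self.days):
                v = self.values[i, j]
                if not np.isnan(v):
                    rows.append((s.id, s.lon, s.lat, int(d), v))
        return pd.DataFrame(rows, columns=["station_id", "lon", "lat",
                                           "day", "value"])


@dataclass
class CovariateTable:
    """Predictor columns for the additive model.

    ``spatial`` is indexed by station id (site-level predictors p_k(s):
    traffic, land use, emission sources).  ``spatiotemporal`` has a
    (station_id, day) MultiIndex (daily predictors x_i(s,t): meteorology,
    AOT, NDVI, co-located PM10).  ``units`` records the unit per column.
    """

    spatial: pd.DataFrame
    spatiotemporal: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)

    def validate_against(self, panel: MeasurementPanel) -> None:
        ids = set(panel.station_ids)
        missing = set(self.spatial.index) - ids
        if missing:
            raise PanelValidationError(
                f"spatial covariates reference unknown stations: {sorted(missing)[:5]}")
        st_ids = set(self.spatiotemporal.index.get_level_values(0))
        if st_ids - ids:
            raise PanelValidationError(
                f"spatiotemporal covariates reference unknown stations: "
                f"{sorted(st_ids - ids)[:5]}")
        st_days = set(self.spatiotemporal.index.get_level_values(1))
        if st_days - set(panel.days.tolist()):
            raise PanelValidationError("spatiotemporal covariates reference unknown days")

    def constant_columns(self) -> list[str]:
        out = []
        for df in (self.spatial, self.spatiotemporal):
            for c in df.columns:
                if df[c].nunique(dropna=True) <= 1:
                    out.append(c)
        return out


@dataclass
class PredictionResult:
    """One estimate: log-scale mean, uncertainty SD, kriged residual term,
    and the back-transformed concentration."""

    x: float
    y: float
    day: int
    mean_log: float
    sd_log: float
    residual_log: float = 0.0

    def __post_init__(self):
        if self.sd_log < 0:
            raise PanelValidationError("sd_log must be non-negative")

    @property
    def concentration(self) -> float:
        return float(math.exp(self.mean_log + self.residual_log))

    def interval95_log(self) -> tuple[float, float]:
        half = 1.96 * self.sd_log
        return (self.mean_log - half, self.mean_log + half)


# ---------------------------------------------------------------------------
# Daily aggregation and the log transform
# ---------------------------------------------------------------------------

def daily_average(hourly_values, coverage: float = 0.75) -> float:
    """Daily mean of hourly measurements under a minimum-coverage rule.

    Returns the arithmetic mean of the present values when at least
    ``coverage`` of the 24 hourly slots are present (the 75% measurement
    standard by default), else NaN.  Missing hours are None or NaN.
    """
    if not 0 < coverage <= 1:
        raise ValueError(f"coverage must be in (0, 1], got {coverage}")
    vals = list(hourly_values)
    if len(vals) > 24:
        raise ValueError(f"at most 24 hourly values expected, got {len(vals)}")
    present = [float(v) for v in vals if v is not None and not np.isnan(v)]
    if any(v < 0 for v in present):
        raise PanelValidationError("negative hourly concentration")
    if len(present) / 24.0 >= coverage and present:
        return float(np.mean(present))
    return float("nan")


def log_transform(panel: MeasurementPanel) -> MeasurementPanel:
    """Natural log of every non-missing concentration."""
    if panel.scale != "concentration":
        raise ValueError("panel is already on the log scale")
    bad = np.asarray(panel.values <= 0) & ~np.isnan(panel.values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise PanelValidationError(
            f"cannot log-transform non-positive value at station "
            f"{panel.stations[i].id}, day {panel.days[j]}")
    with np.errstate(invalid="ignore"):
        logged = np.log(panel.values)
    return panel.copy_with(values=logged, scale="log")


def back_transform(values):
    """Log-scale values back to concentrations by plain exponentiation."""
    return np.exp(np.asarray(values, dtype=float))


# ---------------------------------------------------------------------------
# I/O — long-format CSV
# ---------------------------------------------------------------------------

def read_panel(path, pollutant: str = "PM25",
               projection: LocalProjection | None = None,
               unit_scale: float = 1.0) -> MeasurementPanel:
    """Read a long-format CSV (station_id, lon, lat, date, value).

    ``date`` may be an ISO date or a 1-based day-of-year integer.  Values are
    multiplied by ``unit_scale`` to convert into μg/m³.  Stations are ordered
    by id and days ascending, so the result is deterministic.
    """
    df = pd.read_csv(path, dtype={"station_id": str})
    required = {"station_id", "lon", "lat", "date", "value"}
    if not required.issubset(df.columns):
        raise PanelValidationError(
            f"missing columns: {sorted(required - set(df.columns))}")

    days = _parse_days(df["date"])
    df = df.assign(day=days, value=df["value"] * unit_scale)

    dup = df.duplicated(subset=["station_id", "day"], keep=False)
    if dup.any():
        keys = df.loc[dup, ["station_id", "day"]].drop_duplicates()
        raise PanelValidationError(
            "duplicate (station, date) rows: "
            + ", ".join(f"({r.station_id}, day {r.day})"
                        for r in keys.head(5).itertuples()))

    if projection is None:
        projection = LocalProjection.for_bbox(df["lon"], df["lat"])

    station_meta = (df.groupby("station_id")[["lon", "lat"]].first()
                    .sort_index())
    stations = [Station.from_lonlat(i, r.lon, r.lat, projection)
                for i, r in station_meta.iterrows()]
    day_list = np.sort(df["day"].unique())

    wide = df.pivot(index="station_id", columns="day", values="value")
    wide = wide.reindex(index=station_meta.index, columns=day_list)
    return MeasurementPanel(stations=stations, days=day_list,
                            values=wide.to_numpy(dtype=float),
                            pollutant=pollutant, projection=projection)


def _parse_days(date_col: pd.Series) -> np.ndarray:
    if pd.api.types.is_integer_dtype(date_col):
        return date_col.to_numpy()
    out = np.empty(len(date_col), dtype=int)
    for k, raw in enumerate(date_col):
        try:
            out[k] = int(raw)
            continue
        except (TypeError, ValueError):
            pass
        ts = pd.to_datetime(raw, errors="coerce")
        if pd.isna(ts):
            raise PanelValidationError(f"unparseable date {raw!r} at row {k}")
        out[k] = ts.dayofyear
    return out


def write_panel(panel: MeasurementPanel, path) -> None:
    """Write the long-format CSV consumed by :func:`read_panel`."""
    frame = panel.to_frame().rename(columns={"day": "date"})
    frame.to_csv(path, index=False)


def write_predictions(results, path) -> None:
    """Write predictions as CSV (x, y, day, mean_log, sd_log, residual_log,
    concentration)."""
    rows = [(r.x, r.y, r.day, r.mean_log, r.sd_log, r.residual_log,
             r.concentration) for r in results]
    pd.DataFrame(rows, columns=["x", "y", "day", "mean_log", "sd_log",
                                "residual_log", "concentration"]
                 ).to_csv(path, index=False)


def read_predictions(path) -> list[PredictionResult]:
    df = pd.read_csv(path)
    return [PredictionResult(x=r.x, y=r.y, day=int(r.day),
                             mean_log=r.mean_log, sd_log=r.sd_log,
                             residual_log=r.residual_log)
            for r in df.itertuples()]
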