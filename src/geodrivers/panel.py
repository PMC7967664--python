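"""City-panel containers and temporal aggregation of station records.

A *city panel* holds one row per areal unit (city) and time period, with a
response concentration, covariate columns and planar centroid coordinates.
Fine-grained station records (hourly or daily concentrations mapped to a
unit) can be aggregated up to daily, monthly, seasonal and annual unit means
under a configurable completeness rule.

Season convention: spring = March-May, summer = June-August, autumn =
September-November; winter groups December with January and February of the
following calendar year, and the season carries that following year's label
(so Dec 2015, Jan 2016, Feb 2016 form "2016-winter").
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import shape

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: canonical internal column names
_CORE_COLS = ("unit_id", "x", "y", "y_resp")

SEASONS = ("spring", "summer", "autumn", "winter")

_SEASON_OF_MONTH = {
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
    12: "winter", 1: "winter", 2: "winter",
}


def season_of(year: int, month: int) -> tuple[int, str]:
    """Return ``(season_year, season_name)`` for a calendar month.

    December is assigned to the *following* year's winter so that December,
    January and February of consecutive calendar years form one season.
    """
    if month not in range(1, 13):
        raise ValueError(f"month must be 1..12, got {month}")
    name = _SEASON_OF_MONTH[month]
    season_year = year + 1 if month == 12 else year
    return season_year, name


@dataclass
class CityPanel:
    """Areal units with coordinates, response and covariates.

    ``data`` is a long-format DataFrame with columns ``unit_id, x, y,
    y_resp``, one column per covariate, and optional ``group`` and ``time``
    columns. Coordinates are planar (km); the response is a concentration
    (µg/m³).
    """

    data: pd.DataFrame
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in _CORE_COLS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"panel missing mandatory columns: {missing}")
        if len(set(self.covariates)) != len(self.covariates):
            raise ValidationError("covariate names must be unique")
        for c in self.covariates:
            if c not in self.data.columns:
                raise SchemaError(f"covariate column {c!r} not in panel data")
        key = ["unit_id", "time"] if "time" in self.data.columns else ["unit_id"]
        if self.data.duplicated(subset=key).any():
            raise ValidationError(f"duplicate rows for key {key}")
        bad = ~np.isfinite(self.data[["x", "y", "y_resp"]].to_numpy(float)).all(axis=1)
        if bad.any():
            raise ValidationError(
                f"{int(bad.sum())} rows have non-finite response or coordinates"
            )

    # -- accessors ---------------------------------------------------------

    @property
    def n_units(self) -> int:
        return self.data["unit_id"].nunique()

    @property
    def times(self) -> list:
        if "time" not in self.data.columns:
            return []
        return sorted(self.data["time"].unique().tolist())

    @property
    def has_groups(self) -> bool:
        return "group" in self.data.columns

    def slice_time(self, label) -> "CityPanel":
        """Return the cross-section for one time label (sorted by unit_id)."""
        if "time" not in self.data.columns:
            raise ValidationError("panel has no time column")
        sub = self.data[self.data["time"] == label]
        if sub.empty:
            raise ValidationError(f"no rows for time label {label!r}")
        sub = sub.sort_values("unit_id").reset_index(drop=True)
        return CityPanel(sub, list(self.covariates))

    def coords(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(float)

    def response(self) -> np.ndarray:
        return self.data["y_resp"].to_numpy(float)

    def X(self, subset: list[str] | None = None) -> np.ndarray:
        cols = list(subset) if subset is not None else self.covariates
        return self.data[cols].to_numpy(float)

    def groups(self) -> np.ndarray:
        if not self.has_groups:
            raise ValidationError("panel has no group column")
        return self.data["group"].to_numpy()


@dataclass
class StationSeries:
    """Fine-grained monitoring records mapped to areal units.

    ``data`` columns: ``station_id, unit_id, timestamp, value`` with
    timestamps strictly increasing per station and values ≥ 0 or missing.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        needed = {"station_id", "unit_id", "timestamp", "value"}
        missing = needed - set(self.data.columns)
        if missing:
            raise SchemaError(f"station series missing columns: {sorted(missing)}")
        df = self.data
        if not pd.api.types.is_datetime64_any_dtype(df["timestamp"]):
            self.data = df = df.assign(timestamp=pd.to_datetime(df["timestamp"]))
        for sid, g in df.groupby("station_id"):
            if not g["timestamp"].is_monotonic_increasing or g["timestamp"].duplicated().any():
                raise ValidationError(f"timestamps not strictly increasing for station {sid}")
        vals = df["value"]
        if (vals.dropna() < 0).any():
            raise ValidationError("negative concentration values")


# ---------------------------------------------------------------------------
# panel I/O


_DEFAULT_SCHEMA = {
    "unit_id": "unit_id",
    "x": "x",
    "y": "y",
    "y_resp": "y_resp",
    "group": "group",
    "time": "time",
}


def read_panel(path, schema: dict | None = None,
               covariates: list[str] | None = None) -> CityPanel:
    """Read a long-format city-panel CSV.

    ``schema`` maps canonical roles (``unit_id, x, y, y_resp`` and optionally
    ``group, time``) to the file's column names. Columns not mapped to a role
    are treated as covariates unless an explicit ``covariates`` list is
    given. Rows with a missing response or coordinates are dropped with a
    logged count.
    """
    df = pd.read_csv(path)
    mapping = dict(_DEFAULT_SCHEMA)
    if schema:
        mapping.update(schema)
    rename = {}
    for role in ("unit_id", "x", "y", "y_resp"):
        col = mapping[role]
        if col not in df.columns:
            raise SchemaError(f"mandatory column {col!r} (role {role}) not in {path}")
        rename[col] = role
    for role in ("group", "time"):
        col = mapping.get(role)
        if col in df.columns:
            rename[col] = role
    df = df.rename(columns=rename)
    if covariates is None:
        reserved = set(rename.values())
        covariates = [c for c in df.columns if c not in reserved]
    bad = df[["x", "y", "y_resp"]].isna().any(axis=1)
    bad |= ~np.isfinite(df[["x", "y", "y_resp"]].astype(float).to_numpy()).all(axis=1)
    if bad.any():
        logger.warning("read_panel: dropping %d rows with missing response/coordinates",
                       int(bad.sum()))
        df = df[~bad]
    df = df.reset_index(drop=True)
    return CityPanel(df, covariates)


def write_panel(panel: CityPanel, path, float_format: str = "%.10g") -> None:
    """Write a panel back to CSV (numeric content stable at 10 significant digits)."""
    cols = ["unit_id"]
    if "time" in panel.data.columns:
        cols.append("time")
    if "group" in panel.data.columns:
        cols.append("group")
    cols += ["x", "y", "y_resp"] + panel.covariates
    panel.data[cols].to_csv(path, index=False, float_format=float_format)


def read_geojson(path, id_property: str = "unit_id") -> dict:
    """Read a GeoJSON FeatureCollection into ``{unit_id: shapely geometry}``."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise SchemaError("expected a GeoJSON FeatureCollection")
    geoms = {}
    for feat in gj["features"]:
        props = feat.get("properties") or {}
        if id_property not in props:
            raise SchemaError(f"feature missing property {id_property!r}")
        geoms[str(props[id_property])] = shape(feat["geometry"])
    return geoms


def write_geojson(geoms: dict, path, id_property: str = "unit_id") -> None:
    """Write ``{unit_id: shapely geometry}`` as a GeoJSON FeatureCollection."""
    from shapely.geometry import mapping

    features = [
        {"type": "Feature", "properties": {id_property: uid},
         "geometry": mapping(geom)}
        for uid, geom in geoms.items()
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


# ---------------------------------------------------------------------------
# temporal aggregation

_LEVELS = ("daily", "monthly", "seasonal", "annual")


def _period_keys(ts: pd.Series, level: str) -> pd.Series:
    if level == "daily":
        return ts.dt.strftime("%Y-%m-%d")
    if level == "monthly":
        return ts.dt.strftime("%Y-%m")
    raise ValueError(level)


def _complete_mean(g: pd.DataFrame, expected: int, completeness: float):
    vals = g["value"].dropna()
    if expected <= 0 or len(vals) / expected < completeness:
        return np.nan
    return vals.mean()


def aggregate_series(series: StationSeries, level: str = "annual",
                     completeness: float = 0.75) -> pd.DataFrame:
    """Aggregate station records to unit-level period means.

    The chain is hourly → daily → monthly → seasonal/annual. At each step a
    period is reported only when the fraction of non-missing sub-periods is
    at least ``completeness`` (days need ≥ ``completeness`` of 24 hours,
    months ≥ that fraction of calendar days, seasons/years that fraction of
    their 3/12 months). Unit means are unweighted means of station means;
    annual and seasonal means average monthly means so months weigh equally.

    Returns a DataFrame ``unit_id, time, y_resp`` (empty, with a warning,
    for empty input).
    """
    if level not in _LEVELS:
        raise ValueError(f"level must be one of {_LEVELS}")
    if not 0 < completeness <= 1:
        raise ValueError("completeness must be in (0, 1]")
    df = series.data
    if df.empty:
        logger.warning("aggregate_series: empty input, returning empty panel")
        return pd.DataFrame(columns=["unit_id", "time", "y_resp"])
    if df["unit_id"].isna().any():
        raise ValidationError("station rows with unknown unit mapping")

    df = df.copy()
    ts = df["timestamp"]
    df["day"] = _period_keys(ts, "daily")
    # station daily means under hourly completeness
    daily = (
        df.groupby(["station_id", "unit_id", "day"])
        .apply(_complete_mean, expected=24, completeness=completeness,
               include_groups=False)
        .rename("value")
        .reset_index()
        .dropna(subset=["value"])
    )
    if level == "daily":
        out = daily.groupby(["unit_id", "day"])["value"].mean().reset_index()
        return out.rename(columns={"day": "time", "value": "y_resp"})

    daily["date"] = pd.to_datetime(daily["day"])
    daily["month"] = daily["date"].dt.strftime("%Y-%m")
    daily["days_in_month"] = daily["date"].dt.days_in_month
    monthly = (
        daily.groupby(["station_id", "unit_id", "month"])
        .apply(lambda g: _complete_mean(g, int(g["days_in_month"].iloc[0]), completeness),
               include_groups=False)
        .rename("value")
        .reset_index()
        .dropna(subset=["value"])
    )
    unit_monthly = monthly.groupby(["unit_id", "month"])["value"].mean().reset_index()
    if level == "monthly":
        return unit_monthly.rename(columns={"month": "time", "value": "y_resp"})

    md = pd.to_datetime(unit_monthly["month"])
    if level == "annual":
        unit_monthly["period"] = md.dt.year.astype(str)
        expected = 12
    else:  # seasonal
        sy_sn = [season_of(d.year, d.month) for d in md]
        unit_monthly["period"] = [f"{sy}-{sn}" for sy, sn in sy_sn]
        expected = 3
    out = (
        unit_monthly.groupby(["unit_id", "period"])
        .apply(_complete_mean, expected=expected, completeness=completeness,
               include_groups=False)
        .rename("y_resp")
        .reset_index()
        .dropna(subset=["y_resp"])
    )
    return out.rename(columns={"period": "time"})
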