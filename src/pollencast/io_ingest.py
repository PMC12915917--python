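"""Reading, writing and slicing daily pollen and meteorological series.

Pollen series are CSV tables with columns ``date,taxon,concentration``
(ISO-8601 dates, grains/m3 per 24 h).  Meteorological series follow the
ECA&D blended-station conventions: integer values in tenths units (0.1 degC,
0.1 h, 0.1 m/s, 0.1 hPa), one file per variable with a quality flag column
(0 valid, 1 suspect, 9 missing), or — for fixtures and synthetic exports — a
combined wide CSV ``date,tg,tn,tx,hu,cc,ss,fg,pp,qq,sd``.

The readers never impute: flagged-missing values become NA and stay NA.
Tenths-unit integers are preserved as stored; :func:`meteo_to_si` converts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StationMeta",
    "METEO_VARIABLES",
    "METEO_TENTHS",
    "read_pollen_table",
    "write_pollen_table",
    "read_meteo_table",
    "read_ecad_file",
    "write_meteo_table",
    "meteo_to_si",
    "extract_seasons",
    "SeasonSlice",
    "station_distance_km",
]

logger = logging.getLogger(__name__)

#: canonical short names for the ten daily meteorological variables
#: (ECA&D element codes): mean/min/max temperature, relative humidity,
#: cloud cover, sunshine duration, mean wind speed, sea-level pressure,
#: global radiation, snow depth.
METEO_VARIABLES = ("tg", "tn", "tx", "hu", "cc", "ss", "fg", "pp", "qq", "sd")

#: variables stored in tenths of the SI-ish unit; the rest are whole units
#: (% for hu, okta for cc, W/m2 for qq, cm for sd).
METEO_TENTHS = {"tg": 0.1, "tn": 0.1, "tx": 0.1, "ss": 0.1, "fg": 0.1, "pp": 0.1}

EARTH_RADIUS_KM = 6371.0088  # IUGG mean radius


class ValidationError(ValueError):
    """Raised when an input file violates the documented dialect."""


@dataclass(frozen=True)
class StationMeta:
    """Geographic metadata for a monitoring station."""

    station_id: str
    latitude: float
    longitude: float
    elevation: float = 0.0

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(f"latitude out of range: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(f"longitude out of range: {self.longitude}")


@dataclass(frozen=True)
class SeasonSlice:
    """One pollen season: first to last non-zero day of a calendar year.

    ``records`` is a DataFrame with columns ``date, taxon, concentration``,
    daily-contiguous, whose first and last rows have concentration > 0.
    Interior zero days are retained.
    """

    year: int
    taxon: str
    records: pd.DataFrame

    def __len__(self) -> int:
        return len(self.records)


def read_pollen_table(path: str | Path, taxon: str | None = None) -> pd.DataFrame:
    """Read a pollen CSV into a date-sorted DataFrame.

    Parameters
    ----------
    path
        CSV with header ``date,taxon,concentration`` (the ``taxon`` column
        may be absent if `taxon` is given).
    taxon
        If given, rows are filtered to this taxon (or the column is filled
        with it when absent).

    Returns
    -------
    DataFrame with columns ``date`` (datetime64), ``taxon`` (str),
    ``concentration`` (float), sorted by date.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if "date" not in df.columns or "concentration" not in df.columns:
        raise ValidationError(f"{path}: expected 'date' and 'concentration' columns")
    if "taxon" not in df.columns:
        if taxon is None:
            raise ValidationError(f"{path}: no taxon column and no taxon given")
        df["taxon"] = taxon
    if taxon is not None:
        df = df[df["taxon"] == taxon].copy()
    if df.empty:
        logger.warning("%s: empty data section", path)
        return pd.DataFrame(columns=["date", "taxon", "concentration"])
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except ValueError as e:
        raise ValidationError(f"{path}: malformed date ({e})") from None
    conc = pd.to_numeric(df["concentration"], errors="coerce")
    if conc.isna().any():
        bad = df.loc[conc.isna(), "concentration"].iloc[0]
        raise ValidationError(f"{path}: non-numeric concentration {bad!r}")
    if (conc < 0).any():
        bad = df.loc[conc < 0].iloc[0]
        raise ValidationError(f"{path}: negative concentration on {bad['date'].date()}")
    df["concentration"] = conc.astype(float)
    dup = df.duplicated(subset=["date", "taxon"])
    if dup.any():
        raise ValidationError(f"{path}: duplicate date {df.loc[dup, 'date'].iloc[0].date()}")
    return df.sort_values("date", kind="stable").reset_index(drop=True)[
        ["date", "taxon", "concentration"]
    ]


def write_pollen_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a pollen DataFrame as the canonical CSV dialect (ISO dates)."""
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out["concentration"] = out["concentration"].map(
        lambda v: ("%g" % v) if float(v) != int(v) else str(int(v))
    )
    out[["date", "taxon", "concentration"]].to_csv(path, index=False)


def _parse_dates(raw: pd.Series) -> pd.Series:
    """Accept ISO-8601 or compact YYYYMMDD dates."""
    s = raw.astype(str).str.strip()
    if s.str.fullmatch(r"\d{8}").all():
        return pd.to_datetime(s, format="%Y%m%d")
    try:
        return pd.to_datetime(s, format="ISO8601")
    except ValueError as e:
        raise ValidationError(f"malformed date ({e})") from None


def read_ecad_file(path: str | Path, variable: str) -> pd.DataFrame:
    """Read a single-variable ECA&D-style blended file.

    Expected columns (case-insensitive, extra columns ignored): ``DATE``
    (YYYYMMDD), the value column (named after the variable or ``VALUE``),
    and a quality flag ``Q`` / ``Q_<VAR>`` with 0 = valid, 1 = suspect,
    9 = missing.  Flagged-missing values become NA; suspect values are kept.

    Returns a DataFrame ``date, <variable>`` with a nullable integer column.
    """
    variable = variable.lower()
    if variable not in METEO_VARIABLES:
        raise ValidationError(f"unknown meteorological variable {variable!r}")
    df = pd.read_csv(path, skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    if "date" not in df.columns:
        raise ValidationError(f"{path}: no DATE column")
    value_col = variable if variable in df.columns else "value"
    if value_col not in df.columns:
        raise ValidationError(f"{path}: no value column for {variable!r}")
    qcol = next((c for c in (f"q_{variable}", "q") if c in df.columns), None)
    dates = _parse_dates(df["date"])
    values = pd.to_numeric(df[value_col], errors="coerce").astype("Int64")
    if qcol is not None:
        q = pd.to_numeric(df[qcol], errors="coerce")
        bad = ~q.isin([0, 1, 9])
        if bad.any():
            raise ValidationError(f"{path}: unknown quality flag {q[bad].iloc[0]}")
        values = values.mask(q == 9)
    return pd.DataFrame({"date": dates, variable: values}).sort_values(
        "date", kind="stable"
    ).reset_index(drop=True)


def read_meteo_table(path: str | Path) -> pd.DataFrame:
    """Read the combined wide meteorological CSV (fixture/synthetic dialect).

    Header ``date,tg,tn,tx,hu,cc,ss,fg,pp,qq,sd``; empty cells are missing.
    Values are kept as stored (tenths-unit integers where applicable) in
    nullable ``Int64`` columns; use :func:`meteo_to_si` for SI floats.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in ("date",) + METEO_VARIABLES if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    df["date"] = _parse_dates(df["date"])
    for v in METEO_VARIABLES:
        df[v] = pd.to_numeric(df[v], errors="coerce").round().astype("Int64")
    cc_bad = df["cc"].dropna()
    if ((cc_bad < 0) | (cc_bad > 8)).any():
        raise ValidationError(f"{path}: cloud cover outside 0-8 okta")
    hu_bad = df["hu"].dropna()
    if ((hu_bad < 0) | (hu_bad > 100)).any():
        raise ValidationError(f"{path}: humidity outside 0-100%")
    return df.sort_values("date", kind="stable").reset_index(drop=True)[
        ["date"] + list(METEO_VARIABLES)
    ]


def write_meteo_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write the wide meteorological CSV (ISO dates, stored integers)."""
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out[["date"] + list(METEO_VARIABLES)].to_csv(path, index=False)


def meteo_to_si(df: pd.DataFrame) -> pd.DataFrame:
    """Convert stored meteorological integers to SI-unit floats.

    Tenths-unit variables are scaled by 0.1 (degC, hours, m/s, hPa); the
    remaining columns (%, okta, W/m2, cm) are returned as floats unchanged.
    Missing values become NaN.
    """
    out = df.copy()
    for v in METEO_VARIABLES:
        out[v] = out[v].astype(float) * METEO_TENTHS.get(v, 1.0)
    return out


def extract_seasons(records: pd.DataFrame) -> list[SeasonSlice]:
    """Slice a pollen series into per-year seasons.

    A season runs from the first to the last day with non-zero concentration
    within a calendar year; interior zero days are retained.  Years with no
    pollen yield no slice.  Input gaps inside a season are an error (the
    daily series must be contiguous over the season span).
    """
    if records.empty:
        return []
    records = records.sort_values("date", kind="stable").reset_index(drop=True)
    slices: list[SeasonSlice] = []
    for (year, taxon), grp in records.groupby(
        [records["date"].dt.year, "taxon"], sort=True
    ):
        nz = grp.index[grp["concentration"] > 0]
        if len(nz) == 0:
            continue
        season = grp.loc[nz[0] : nz[-1]].reset_index(drop=True)
        deltas = season["date"].diff().dropna()
        if not (deltas == pd.Timedelta(days=1)).all():
            raise ValidationError(
                f"{taxon} {year}: season span is not daily-contiguous"
            )
        slices.append(SeasonSlice(year=int(year), taxon=str(taxon), records=season))
    return slices


def station_distance_km(a: StationMeta, b: StationMeta) -> float:
    """Great-circle (haversine) distance between two stations, km."""
    la1, lo1, la2, lo2 = map(
        math.radians, (a.latitude, a.longitude, b.latitude, b.longitude)
    )
    h = (
        math.sin((la2 - la1) / 2) ** 2
        + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def dms(degrees: float, minutes: float = 0.0, seconds: float = 0.0) -> float:
    """Convert degrees/minutes/seconds to decimal degrees."""
    return degrees + minutes / 60.0 + seconds / 3600.0
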