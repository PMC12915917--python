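"""EMA-derived tabular features and lagged sequence windows.

Two input-preparation strategies feed the model families:

* tabular — for each base feature (pollen plus the ten meteorological
  variables) the raw lagged value and six exponential-moving-average
  features: ema3, ema7, ema20 over trailing windows of 3, 7 and 20 days,
  and the ratio features ema1/3 = x_i / ema3, ema3/7 = ema3 / ema7,
  ema7/20 = ema7 / ema20.
* sequence — raw lag windows for recurrent models: a pollen-lag vector of
  length w ending n days before the target, and a meteorological matrix
  covering the target day and the preceding n + w days (forecast
  simulation: recorded values stand in for a weather forecast).

The forecast horizon n separates the last usable pollen observation from
the target day; pollen-derived inputs never postdate target - n days, while
meteorological "forecast" columns may reach the target day itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_ingest import METEO_VARIABLES, SeasonSlice, meteo_to_si
from .metrics import CategoryScheme, categorize

__all__ = [
    "EmaSpec",
    "WindowSpec",
    "ema",
    "ema_series",
    "ema_feature_block",
    "lag_indices",
    "build_tabular_dataset",
    "build_sequence_dataset",
    "SequenceDataset",
    "EMA_WINDOWS",
]

logger = logging.getLogger(__name__)

#: the three trailing EMA window lengths
EMA_WINDOWS = (3, 7, 20)


@dataclass(frozen=True)
class EmaSpec:
    """EMA window size ``t`` (days) and smoothing factor ``alpha``.

    By convention ``alpha`` defaults to 2 / (t + 1).
    """

    t: int
    alpha: float | None = None

    def __post_init__(self):
        if self.t < 1:
            raise ValueError("window size t must be >= 1")
        a = self.effective_alpha
        if not 0.0 < a <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")

    @property
    def effective_alpha(self) -> float:
        return 2.0 / (self.t + 1.0) if self.alpha is None else self.alpha


@dataclass(frozen=True)
class WindowSpec:
    """Lag-window geometry: window length ``w``, forecast horizon ``n``."""

    w: int
    n: int

    def __post_init__(self):
        if self.w < 1 or self.n < 1:
            raise ValueError("w and n must be >= 1")


def ema(values, alpha: float) -> float:
    """Exponential moving average of a trailing window (newest value last).

    Computed as the geometrically weighted mean
    ``sum_k (1-alpha)^k x_{t-k} / sum_k (1-alpha)^k`` with k = 0 over the
    newest value; weights decay toward the oldest observation.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    weights = (1.0 - alpha) ** np.arange(x.size)  # newest first
    return float(np.dot(weights, x[::-1]) / weights.sum())


def ema_series(values, t: int, alpha: float | None = None) -> np.ndarray:
    """Trailing-window EMA at every index with >= t observations available.

    Returns an array aligned with ``values``; the first t-1 entries are NaN.
    Vectorized over all windows of length t (the dot of the reversed weight
    vector with a sliding view).
    """
    spec = EmaSpec(t=t, alpha=alpha)
    a = spec.effective_alpha
    x = np.asarray(values, dtype=float)
    out = np.full(x.size, np.nan)
    if x.size < t:
        return out
    weights = (1.0 - a) ** np.arange(t)
    weights = weights[::-1] / weights.sum()  # oldest ... newest
    windows = np.lib.stride_tricks.sliding_window_view(x, t)
    out[t - 1 :] = windows @ weights
    return out


def _safe_ratio(num: np.ndarray, den: np.ndarray, name: str) -> np.ndarray:
    """Elementwise num/den; a zero denominator yields the neutral ratio 1."""
    zero = den == 0
    if np.any(zero & ~np.isnan(den)):
        logger.warning("%s: %d zero-denominator ratios emitted as 1", name, int(zero.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / den
    r = np.where(zero, 1.0, r)
    return r


def ema_feature_block(values, i: int, alpha: float | None = None) -> tuple[float, ...]:
    """Six EMA features of a series at index ``i``.

    Returns (ema3, ema7, ema20, ema1/3, ema3/7, ema7/20).  Requires at
    least 20 observations up to and including ``i``.  Zero-denominator
    ratios are emitted as the neutral value 1 with a logged warning.
    """
    x = np.asarray(values, dtype=float)
    if i + 1 < max(EMA_WINDOWS):
        raise ValueError(f"index {i} has fewer than {max(EMA_WINDOWS)} observations")
    emas = [ema(x[i + 1 - t : i + 1], EmaSpec(t, alpha).effective_alpha) for t in EMA_WINDOWS]
    e3, e7, e20 = emas
    r13 = float(_safe_ratio(np.array([x[i]]), np.array([e3]), "ema1/3")[0])
    r37 = float(_safe_ratio(np.array([e3]), np.array([e7]), "ema3/7")[0])
    r720 = float(_safe_ratio(np.array([e7]), np.array([e20]), "ema7/20")[0])
    return (e3, e7, e20, r13, r37, r720)


def lag_indices(spec: WindowSpec) -> list[int]:
    """Day-lags of the tabular/time-series input window, newest last.

    For window w and horizon n the usable past interval runs from n + w to
    n days before the target (w + 1 lags) — e.g. w=14, n=4 uses days 18
    through 4 in the past.
    """
    return list(range(spec.n + spec.w, spec.n - 1, -1))


def _ema_columns(series: np.ndarray, name: str, alpha: float | None) -> dict[str, np.ndarray]:
    """All six EMA feature columns of a daily series, aligned with it."""
    e3 = ema_series(series, 3, alpha)
    e7 = ema_series(series, 7, alpha)
    e20 = ema_series(series, 20, alpha)
    return {
        f"{name}__ema3": e3,
        f"{name}__ema7": e7,
        f"{name}__ema20": e20,
        f"{name}__ratio1_3": _safe_ratio(series, e3, f"{name} ema1/3"),
        f"{name}__ratio3_7": _safe_ratio(e3, e7, f"{name} ema3/7"),
        f"{name}__ratio7_20": _safe_ratio(e7, e20, f"{name} ema7/20"),
    }


def _daily_panel(
    seasons: list[SeasonSlice], meteo: pd.DataFrame, max_ffill: int = 3
) -> pd.DataFrame:
    """Join pollen seasons onto the daily meteorological panel.

    Produces one row per meteorological day with SI-unit meteo columns, the
    pollen concentration (zero outside seasons, NaN before the first /
    after the last season of the series has no meaning and is kept 0), and
    an ``in_season`` flag.  Missing meteo values are carried forward at
    most ``max_ffill`` days; rows still missing are dropped.
    """
    met = meteo_to_si(meteo).sort_values("date").reset_index(drop=True)
    full = pd.date_range(met["date"].min(), met["date"].max(), freq="D")
    met = met.set_index("date").reindex(full)
    met[list(METEO_VARIABLES)] = met[list(METEO_VARIABLES)].ffill(limit=max_ffill)
    met = met.dropna(subset=list(METEO_VARIABLES))

    pollen = pd.Series(0.0, index=met.index)
    in_season = pd.Series(False, index=met.index)
    for s in seasons:
        dates = pd.DatetimeIndex(s.records["date"])
        if not dates.isin(met.index).all():
            missing = dates[~dates.isin(met.index)]
            raise ValueError(f"meteorology does not cover season days, e.g. {missing[0].date()}")
        pollen.loc[dates] = s.records["concentration"].to_numpy(dtype=float)
        in_season.loc[dates] = True
    panel = met.copy()
    panel["pollen"] = pollen
    panel["in_season"] = in_season
    panel.index.name = "date"
    return panel.reset_index()


def build_tabular_dataset(
    seasons: list[SeasonSlice],
    meteo: pd.DataFrame,
    spec: WindowSpec,
    scheme: CategoryScheme,
    alpha: float | None = None,
) -> pd.DataFrame:
    """Build the EMA feature table for horizon ``spec.n``.

    One row per within-season target date with enough history.  Pollen
    columns (``pollen__lag<n>`` raw value plus its six EMA features) are
    taken at the last usable day, n days before the target.  Meteorological
    columns simulate a perfect forecast: the raw value on the target day,
    the raw value n days before, and the six EMA features ending on the
    target day.  Each row carries the target concentration, class and year.

    Rows lacking a full 20-day EMA history (or any required panel day) are
    skipped; the count is logged.
    """
    panel = _daily_panel(seasons, meteo)
    n = spec.n
    dates = pd.DatetimeIndex(panel["date"])
    if len(panel) > 1 and not (np.diff(dates.values).astype("timedelta64[D]") == 1).all():
        # gaps arise only when meteo rows were dropped for missing values
        logger.warning("daily panel has gaps after missing-value handling")

    cols: dict[str, np.ndarray] = {}
    pol = panel["pollen"].to_numpy(dtype=float)
    cols[f"pollen__lag{n}"] = pol
    cols.update(_ema_columns(pol, "pollen", alpha))
    for v in METEO_VARIABLES:
        s = panel[v].to_numpy(dtype=float)
        cols[f"{v}__lag0"] = s
        cols[f"{v}__lag{n}"] = s
        cols.update(_ema_columns(s, v, alpha))

    min_hist = max(EMA_WINDOWS) - 1  # index of first computable EMA row
    rows, skipped = [], 0
    in_season = panel["in_season"].to_numpy()
    for i in range(len(panel)):
        if not in_season[i]:
            continue
        ref = i - n  # last usable pollen index
        if ref < min_hist or i < min_hist:
            skipped += 1
            continue
        if i >= 1 and (dates[i] - dates[ref]).days != n:
            skipped += 1  # panel gap inside the window
            continue
        row: dict[str, object] = {"date": dates[i], "year": int(dates[i].year)}
        for name, arr in cols.items():
            if name.startswith("pollen"):
                row[name] = arr[ref]
            elif name.endswith(f"__lag{n}") and n != 0:
                row[name] = arr[ref]
            else:
                row[name] = arr[i]  # forecast columns end on the target day
        row["target"] = pol[i]
        row["target_class"] = categorize(pol[i], scheme)
        rows.append(row)
    if skipped:
        logger.info("build_tabular_dataset: skipped %d rows with insufficient history", skipped)
    table = pd.DataFrame(rows)
    if not table.empty and table.drop(columns=["target_class"]).isna().any().any():
        raise AssertionError("feature table contains missing values")
    return table


@dataclass
class SequenceDataset:
    """Sequence samples for recurrent models.

    ``pollen`` has shape (N, w): raw concentrations ending n days before
    each target.  ``meteo`` has shape (N, w + n + 1, 10): SI-unit values
    from w + n days before the target through the target day.  ``target``
    and ``target_class`` align row-wise; ``date``/``year`` index the rows.
    """

    pollen: np.ndarray
    meteo: np.ndarray
    target: np.ndarray
    target_class: np.ndarray
    date: pd.DatetimeIndex
    year: np.ndarray
    spec: WindowSpec

    def __len__(self) -> int:
        return len(self.target)


def build_sequence_dataset(
    seasons: list[SeasonSlice],
    meteo: pd.DataFrame,
    spec: WindowSpec,
    scheme: CategoryScheme,
) -> SequenceDataset:
    """Build lagged sequence samples for horizon ``spec.n``.

    Pollen lags run from n + w - 1 to n days before the target (w values,
    oldest first); the meteorological matrix covers the target day and the
    preceding n + w days (w + n + 1 rows, oldest first) — the recorded
    values standing in for a weather forecast.
    """
    panel = _daily_panel(seasons, meteo)
    w, n = spec.w, spec.n
    span = w + n  # oldest day used, relative to target
    dates = pd.DatetimeIndex(panel["date"])
    pol = panel["pollen"].to_numpy(dtype=float)
    met = panel[list(METEO_VARIABLES)].to_numpy(dtype=float)
    in_season = panel["in_season"].to_numpy()

    P, M, y, d = [], [], [], []
    for i in range(len(panel)):
        if not in_season[i] or i < span:
            continue
        if (dates[i] - dates[i - span]).days != span:
            continue  # gap inside the window
        P.append(pol[i - span + 1 : i - n + 1])  # lags n+w-1 .. n
        M.append(met[i - span : i + 1])  # lags n+w .. 0
        y.append(pol[i])
        d.append(dates[i])
    y = np.asarray(y, dtype=float)
    d = pd.DatetimeIndex(d)
    return SequenceDataset(
        pollen=np.asarray(P, dtype=float).reshape(len(y), w),
        meteo=np.asarray(M, dtype=float).reshape(len(y), span + 1, len(METEO_VARIABLES)),
        target=y,
        target_class=np.asarray([categorize(v, scheme) for v in y], dtype=object),
        date=d,
        year=d.year.to_numpy() if len(d) else np.array([], dtype=int),
        spec=spec,
    )
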