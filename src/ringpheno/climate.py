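"""Monthly climate matrix: temperature, precipitation, drought code, freezing days.

The drought code (DC) is the deep-soil moisture component of the Canadian
Forest Fire Weather Index system: a daily bookkeeping of evapotranspiration
(temperature- and day-length-driven) against effective rainfall, unitless,
roughly 0-800, reset at the start of each snow-free season. Monthly values of
every variable are then linearly detrended over calendar years and arranged
into the 16-month window running from June of the year before ring formation
(lower-case labels, e.g. ``jun(t-1)``) through September of the ring year
(capital labels, e.g. ``JUL(t)``).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "DAY_LENGTH_FACTOR",
    "daily_drought_code",
    "monthly_aggregate",
    "detrend_climate",
    "build_window_matrix",
    "window_labels",
    "VARIABLES",
]

VARIABLES = ("temp", "prec", "dc", "freeze")

# Canadian FWI drought-code day-length factors L_f, Jan..Dec.
DAY_LENGTH_FACTOR = np.array(
    [-1.6, -1.6, -1.6, 0.9, 3.8, 5.8, 6.4, 5.0, 2.4, 0.4, -1.6, -1.6]
)

DEFAULT_SEASON = (5, 10)  # snow-free period, c. May-October
DEFAULT_STARTUP_DC = 15.0  # CFFDRS overwintering default


def daily_drought_code(
    daily: pd.DataFrame,
    season_start_month: int = DEFAULT_SEASON[0],
    season_end_month: int = DEFAULT_SEASON[1],
    startup_dc: float = DEFAULT_STARTUP_DC,
) -> pd.Series:
    """Daily drought code over the snow-free season.

    `daily` needs columns ``date`` (datetime-like), ``tmean_C`` and
    ``prec_mm``. Returns a Series indexed like `daily`, NaN outside the
    season. Recursion per day: the rain phase (when prec > 2.8 mm) recharges
    the moisture store Q = 800*exp(-DC/400) by 3.937 * (0.83*P - 1.27); the
    dry phase adds 0.5*V with V = 0.36*(max(T, -2.8) + 2.8) + L_f(month),
    V floored at 0. DC is reset to `startup_dc` at the season start each year.
    """
    dates = pd.to_datetime(daily["date"])
    t = np.asarray(daily["tmean_C"], dtype=float)
    p = np.asarray(daily["prec_mm"], dtype=float)
    if np.any(p < 0):
        raise ValueError("negative precipitation")
    months = dates.dt.month.to_numpy()
    years = dates.dt.year.to_numpy()
    out = np.full(len(daily), np.nan)
    dc = np.nan
    prev_year = None
    for i in range(len(daily)):
        m = months[i]
        if not (season_start_month <= m <= season_end_month):
            dc = np.nan
            continue
        if np.isnan(dc) or years[i] != prev_year:
            dc = float(startup_dc)
        prev_year = years[i]
        if p[i] > 2.8:
            rd = 0.83 * p[i] - 1.27
            q = 800.0 * np.exp(-dc / 400.0)
            qr = q + 3.937 * rd
            dc = max(0.0, 400.0 * np.log(800.0 / qr))
        v = 0.36 * (max(t[i], -2.8) + 2.8) + DAY_LENGTH_FACTOR[m - 1]
        v = max(v, 0.0)
        dc = dc + 0.5 * v
        out[i] = dc
    return pd.Series(out, index=daily.index, name="dc")


def monthly_aggregate(
    daily: pd.DataFrame,
    dc_daily: pd.Series | None = None,
    prec_total: bool = False,
) -> pd.DataFrame:
    """Aggregate daily records into the monthly climate table.

    temp and (by default) prec are means of the daily quantities; pass
    ``prec_total=True`` for conventional monthly precipitation totals.
    dc is the mean of in-season daily DC (NaN for off-season months);
    freeze_days counts days with tmin < 0 degC.
    """
    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"])
    if "tmean_C" not in df.columns:
        df["tmean_C"] = (df["tmin_C"] + df["tmax_C"]) / 2.0
    if "tmin_C" not in df.columns:
        raise ValueError("daily climate needs a tmin_C column for freezing days")
    df["year"] = df["date"].dt.year
    df["month"] = df["date"].dt.month
    if dc_daily is not None:
        df["dc"] = np.asarray(dc_daily, dtype=float)
    rows = []
    for (year, month), grp in df.groupby(["year", "month"], sort=True):
        ndays = pd.Period(f"{year}-{month:02d}").days_in_month
        if len(grp) != ndays:
            raise ValueError(
                f"month {year}-{month:02d} only partially covered "
                f"({len(grp)}/{ndays} days)"
            )
        rec = {
            "year": int(year),
            "month": int(month),
            "temp_C": float(grp["tmean_C"].mean()),
            "prec": float(grp["prec_mm"].sum() if prec_total else grp["prec_mm"].mean()),
            "freeze_days": int((grp["tmin_C"] < 0).sum()),
        }
        if "dc" in grp.columns:
            rec["dc"] = float(grp["dc"].mean()) if grp["dc"].notna().all() else np.nan
        else:
            rec["dc"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def detrend_climate(monthly: pd.DataFrame, variables=VARIABLES) -> pd.DataFrame:
    """Residuals of each (variable, month) series after an OLS trend on year.

    Removes long-term trends (warming, station drift) so the correlation
    phenotypes reflect interannual variability only.
    """
    out = monthly.copy()
    colmap = {"temp": "temp_C", "prec": "prec", "dc": "dc", "freeze": "freeze_days"}
    for var in variables:
        col = colmap.get(var, var)
        if col not in out.columns:
            continue
        vals = out[col].astype(float).to_numpy(copy=True)
        for month in range(1, 13):
            m = (out["month"] == month).to_numpy() & np.isfinite(vals)
            if m.sum() < 5:
                continue
            yr = out.loc[m, "year"].to_numpy(dtype=float)
            y = vals[m]
            if np.ptp(y) == 0:
                vals[m] = 0.0
                continue
            slope, intercept = np.polyfit(yr, y, 1)
            vals[m] = y - (intercept + slope * yr)
        out[col] = vals
    return out


def window_labels() -> list[str]:
    """The 16 month labels: jun(t-1)..dec(t-1) then JAN(t)..SEP(t).

    Capital labels denote the year concurrent with ring formation.
    """
    prev = ["jun", "jul", "aug", "sep", "oct", "nov", "dec"]
    curr = ["JAN", "FEB", "MAR", "APR", "MAY", "JUN", "JUL", "AUG", "SEP"]
    return [f"{m}(t-1)" for m in prev] + [f"{M}(t)" for M in curr]


_LABEL_TO_MONTH = dict(
    zip(
        window_labels(),
        [(-1, m) for m in range(6, 13)] + [(0, m) for m in range(1, 10)],
    )
)


def month_of_label(label: str) -> tuple[int, int]:
    """(year offset, month number) for a window label."""
    return _LABEL_TO_MONTH[label]


def in_season_label(label: str, season=(5, 10)) -> bool:
    _, m = month_of_label(label)
    return season[0] <= m <= season[1]


def build_window_matrix(
    monthly: pd.DataFrame,
    variable: str,
    years,
    drop_offseason_dc: bool = True,
) -> pd.DataFrame:
    """Lagged 16-month matrix for one variable: rows = ring years, columns =
    month labels. Rows with any missing month are dropped with a warning.
    For the drought code, off-season (Nov-Apr) labels are removed entirely
    since DC is undefined under snow.
    """
    colmap = {"temp": "temp_C", "prec": "prec", "dc": "dc", "freeze": "freeze_days"}
    col = colmap.get(variable, variable)
    if col not in monthly.columns:
        raise ValueError(f"variable {variable!r} not in monthly table")
    lut = {(int(r.year), int(r.month)): getattr(r, col) for r in monthly.itertuples()}
    labels = window_labels()
    if variable == "dc" and drop_offseason_dc:
        labels = [lab for lab in labels if in_season_label(lab)]
    rows, kept_years = [], []
    for t in years:
        vals = []
        for lab in labels:
            off, m = month_of_label(lab)
            v = lut.get((int(t) + off, m), np.nan)
            vals.append(v)
        if np.all(np.isfinite(vals)):
            rows.append(vals)
            kept_years.append(int(t))
        else:
            warnings.warn(f"window row for year {t} dropped: missing months")
    return pd.DataFrame(rows, index=pd.Index(kept_years, name="year"), columns=labels)
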