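"""Site driver tables: reading, writing, validation and aggregation.

Daily driver CSV schema (one row per calendar day):

    date (YYYY-MM-DD), rg_mj_m2 OR par_mol_m2, tmax_c, tmin_c,
    rh_pct OR vpd_pa, lai, gpp_obs_gc_m2 (optional)

Site metadata JSON: site_id, lat, vegetation_type (ENF|DBF|GRA|EBF), omega,
lai_max, vcmax25 (optional).  Unknown extra CSV columns are preserved.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .solar_env import DailyDrivers, derive_day
from .two_leaf import OMEGA_BY_VEGTYPE

__all__ = [
    "SiteYear", "SiteMeta", "SiteDataError",
    "read_site_year", "write_site_year",
    "aggregate_halfhourly", "rescale_lai",
    "REQUIRED_ANY", "OUTPUT_COLUMNS",
]

VEGETATION_TYPES = tuple(OMEGA_BY_VEGTYPE)

#: groups of alternative driver columns: at least one per group must be present
REQUIRED_ANY = (("rg_mj_m2", "par_mol_m2"), ("tmax_c",), ("tmin_c",),
                ("rh_pct", "vpd_pa"), ("lai",))

OUTPUT_COLUMNS = ["date", "gpp_sine", "gpp_sinesine", "gpp_actual_sine",
                  "gpp_actual_sinesine", "f_vpd", "lai_sunlit", "lai_shaded",
                  "tp", "daylength"]

HALFHOUR_S = 1800.0


class SiteDataError(ValueError):
    """Malformed or inconsistent site data."""


@dataclass(frozen=True)
class SiteMeta:
    site_id: str
    lat: float
    vegetation_type: str
    omega: float | None = None
    lai_max: float | None = None
    vcmax25: float | None = None

    def __post_init__(self) -> None:
        if self.vegetation_type not in VEGETATION_TYPES:
            raise SiteDataError(
                f"unknown vegetation type {self.vegetation_type!r}; "
                f"expected one of {VEGETATION_TYPES}")
        if abs(self.lat) > 90:
            raise SiteDataError(f"latitude out of range: {self.lat}")

    @property
    def omega_effective(self) -> float:
        return self.omega if self.omega is not None else OMEGA_BY_VEGTYPE[self.vegetation_type]


@dataclass
class SiteYear:
    """A site's metadata plus one contiguous run of daily driver rows."""

    meta: SiteMeta
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        _validate_table(self.table)

    @property
    def site_id(self) -> str:
        return self.meta.site_id

    @property
    def lat(self) -> float:
        return self.meta.lat

    @property
    def doys(self) -> list[int]:
        return [int(d.dayofyear) for d in self.table["date"]]

    def days(self, derive: bool = True, tp_method: str = "sine") -> list[DailyDrivers]:
        """Rows as :class:`DailyDrivers`, derived fields filled by default."""
        out = []
        for _, row in self.table.iterrows():
            day = DailyDrivers(
                date=row["date"],
                tmax=float(row["tmax_c"]), tmin=float(row["tmin_c"]),
                lai=float(row["lai"]),
                rg_daily=float(row.get("rg_mj_m2", float("nan"))),
                rh_mean=float(row.get("rh_pct", float("nan"))),
                vpd=float(row.get("vpd_pa", float("nan"))),
                par_daily=float(row.get("par_mol_m2", float("nan"))),
                gpp_obs=float(row.get("gpp_obs_gc_m2", float("nan"))),
            )
            if derive:
                derive_day(day, self.meta.lat, int(row["date"].dayofyear),
                           tp_method=tp_method)
            out.append(day)
        return out

    @property
    def measured_gpp(self) -> np.ndarray | None:
        if "gpp_obs_gc_m2" not in self.table.columns:
            return None
        return self.table["gpp_obs_gc_m2"].to_numpy(dtype=float)


def _validate_table(df: pd.DataFrame) -> None:
    if "date" not in df.columns:
        raise SiteDataError("driver table lacks a 'date' column")
    for group in REQUIRED_ANY:
        if not any(c in df.columns for c in group):
            raise SiteDataError(f"driver table needs one of columns {group}")
    dates = pd.to_datetime(df["date"])
    if dates.duplicated().any():
        dup = dates[dates.duplicated()].iloc[0]
        raise SiteDataError(f"duplicate date {dup.date()} in driver table")
    if not dates.is_monotonic_increasing:
        raise SiteDataError("driver rows must be in ascending date order")
    gaps = dates.diff().dropna()
    if len(gaps) and (gaps != pd.Timedelta(days=1)).any():
        bad = gaps[gaps != pd.Timedelta(days=1)].index[0]
        raise SiteDataError(f"dates are not contiguous around row {bad}")
    for group in REQUIRED_ANY:
        present = [c for c in group if c in df.columns]
        ok = np.zeros(len(df), dtype=bool)
        for c in present:
            ok |= pd.to_numeric(df[c], errors="coerce").notna().to_numpy()
        if not ok.all():
            row = int(np.flatnonzero(~ok)[0])
            raise SiteDataError(
                f"row {row + 2} ({dates.iloc[row].date()}): missing value for "
                f"required column(s) {present}")  # +2: header + 1-based
    bad_t = df["tmax_c"].astype(float) < df["tmin_c"].astype(float)
    if bad_t.any():
        row = int(np.flatnonzero(bad_t.to_numpy())[0])
        raise SiteDataError(f"row {row + 2}: tmax_c < tmin_c")


def read_site_year(csv_path, meta) -> SiteYear:
    """Load a daily driver CSV plus metadata (path to JSON or SiteMeta)."""
    if not isinstance(meta, SiteMeta):
        raw = json.loads(Path(meta).read_text())
        meta = SiteMeta(**raw)
    df = pd.read_csv(csv_path, float_precision="round_trip")
    _validate_table(df)
    df = df.copy()
    df["date"] = pd.to_datetime(df["date"])
    return SiteYear(meta=meta, table=df)


def write_site_year(site_year: SiteYear, csv_path, meta_path=None) -> None:
    """Write the driver CSV (and optionally the metadata JSON).

    Floats are written in shortest round-trip representation, so a
    write -> read cycle reproduces every numeric field bit-exactly.
    """
    df = site_year.table.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    df.to_csv(csv_path, index=False, float_format="%.17g")
    if meta_path is not None:
        m = site_year.meta
        Path(meta_path).write_text(json.dumps({
            "site_id": m.site_id, "lat": m.lat,
            "vegetation_type": m.vegetation_type, "omega": m.omega,
            "lai_max": m.lai_max, "vcmax25": m.vcmax25}, indent=2))


def aggregate_halfhourly(hh: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a half-hourly table to daily driver rows.

    Expected columns: datetime, ppfd (umol photons m-2 s-1 incident PAR),
    t_air (degC), rh (%).  Produces date, par_mol_m2 (time-step-weighted sum),
    tmax_c/tmin_c (extrema), rh_pct (mean).
    """
    for col in ("datetime", "ppfd", "t_air", "rh"):
        if col not in hh.columns:
            raise SiteDataError(f"half-hourly table lacks column {col!r}")
    ts = pd.to_datetime(hh["datetime"])
    g = hh.assign(date=ts.dt.normalize()).groupby("date", sort=True)
    daily = pd.DataFrame({
        "par_mol_m2": g["ppfd"].sum() * HALFHOUR_S * 1e-6,
        "tmax_c": g["t_air"].max(),
        "tmin_c": g["t_air"].min(),
        "rh_pct": g["rh"].mean(),
    }).reset_index()
    counts = g.size()
    if (counts != 48).any():
        bad = counts[counts != 48].index[0]
        raise SiteDataError(f"day {bad.date()} has {counts[bad]} half-hours, expected 48")
    return daily


def rescale_lai(series, lai_max_measured: float) -> np.ndarray:
    """Rescale a coarse LAI series so its maximum equals the measured maximum."""
    series = np.asarray(series, dtype=float)
    if np.any(series < 0):
        raise ValueError("LAI series must be non-negative")
    peak = float(series.max(initial=0.0))
    if peak <= 0:
        raise SiteDataError("cannot rescale an all-zero LAI series")
    if lai_max_measured <= 0:
        raise ValueError(f"lai_max_measured must be positive, got {lai_max_measured}")
    return series * (lai_max_measured / peak)
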