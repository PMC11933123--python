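"""Solar geometry and daily environmental derivations.

Covers the astronomical quantities the daily model needs (declination,
daylength, top-of-atmosphere radiation, representative solar zenith), the
radiation conversions (shortwave -> PAR photons, diffuse fraction from the
clearness index), and the meteorological derivations (daytime mean air
temperature Tp, vapour-pressure deficit, and the VPD downregulation scalar).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SOLAR_CONSTANT", "PAR_FRACTION", "PHOTONS_PER_J",
    "solar_declination", "sunset_hour_angle", "daylength",
    "toa_daily_radiation", "par_from_shortwave", "cos_zenith",
    "mean_daytime_zenith", "daytime_temperature",
    "esat_pa", "vpd_from", "VPDScalarParams", "f_vpd",
    "diffuse_fraction", "DIFFUSE_POLY", "DIFFUSE_CLIP",
    "DailyDrivers", "derive_day",
]

SOLAR_CONSTANT = 1367.0  # W m-2
PAR_FRACTION = 0.47  # PAR energy / global shortwave energy
PHOTONS_PER_J = 4.55e-6  # mol photons per J of PAR
SECONDS_PER_DAY = 86400.0

#: Daily diffuse-to-global ratio as a polynomial in the clearness index
#: (Chen et al. 1999 form, as used in two-leaf canopy models), evaluated
#: lowest order first, and clipped to DIFFUSE_CLIP.
DIFFUSE_POLY = (0.943, 0.734, -4.9, 1.796, 2.058)
DIFFUSE_CLIP = (0.13, 1.0)


# -- solar geometry ----------------------------------------------------------

def solar_declination(doy) -> float:
    """Solar declination (radians) for day of year 1-366."""
    return math.radians(23.45) * math.sin(2.0 * math.pi * (284 + doy) / 365.0)


def sunset_hour_angle(lat_deg: float, doy: int) -> float:
    """Sunset hour angle (radians), clipped for polar day/night."""
    if abs(lat_deg) > 90:
        raise ValueError(f"latitude must lie in [-90, 90], got {lat_deg}")
    phi = math.radians(lat_deg)
    delta = solar_declination(doy)
    x = -math.tan(phi) * math.tan(delta)
    return math.acos(min(1.0, max(-1.0, x)))


def daylength(lat_deg: float, doy: int) -> float:
    """Time between sunrise and sunset (seconds), in [0, 86400]."""
    return 2.0 * sunset_hour_angle(lat_deg, doy) / (2.0 * math.pi) * SECONDS_PER_DAY


def toa_daily_radiation(lat_deg: float, doy: int) -> float:
    """Daily extraterrestrial shortwave on a horizontal surface (MJ m-2)."""
    phi = math.radians(lat_deg)
    delta = solar_declination(doy)
    ws = sunset_hour_angle(lat_deg, doy)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    h0 = (SECONDS_PER_DAY / math.pi) * SOLAR_CONSTANT * dr * (
        math.cos(phi) * math.cos(delta) * math.sin(ws)
        + ws * math.sin(phi) * math.sin(delta))
    return max(h0, 0.0) * 1e-6


def par_from_shortwave(rg_mj) -> float:
    """Daily PAR photons (mol m-2 day-1) from global shortwave (MJ m-2 day-1)."""
    return np.asarray(rg_mj, dtype=float) * 1e6 * PAR_FRACTION * PHOTONS_PER_J


def cos_zenith(lat_deg: float, doy: int, hour: float) -> float:
    """Cosine of the solar zenith at local solar ``hour`` (0-24), floored at 0."""
    phi = math.radians(lat_deg)
    delta = solar_declination(doy)
    h = math.radians(15.0 * (hour - 12.0))
    return max(math.sin(phi) * math.sin(delta)
               + math.cos(phi) * math.cos(delta) * math.cos(h), 0.0)


def mean_daytime_zenith(lat_deg: float, doy: int) -> float:
    """Cosine-weighted daytime mean solar zenith (degrees).

    cos(theta_rep) = integral(cos^2) / integral(cos) over the daylight hour
    angles, so hours contributing more radiation weigh more.  Used as the
    single representative angle for the daily sunlit/shaded partition.
    """
    phi = math.radians(lat_deg)
    delta = solar_declination(doy)
    ws = sunset_hour_angle(lat_deg, doy)
    if ws <= 0.0:
        return 90.0
    a = math.sin(phi) * math.sin(delta)
    b = math.cos(phi) * math.cos(delta)
    int_cos = a * ws + b * math.sin(ws)
    int_cos2 = (a * a * ws + 2.0 * a * b * math.sin(ws)
                + b * b * (ws / 2.0 + math.sin(2.0 * ws) / 4.0))
    if int_cos <= 0.0:
        return 90.0
    mu = min(int_cos2 / int_cos, 1.0)
    return math.degrees(math.acos(mu))


# -- daytime temperature -----------------------------------------------------

def daytime_temperature(tmax: float, tmin: float, daylength_s: float,
                        method: str = "sine", peak_lag_s: float = 1.8 * 3600.0
                        ) -> float:
    """Mean air temperature over the daylight window (degC).

    ``method="sine"`` reconstructs the diurnal course as
    T(t) = tmin + (tmax - tmin) * sin(pi t / (D + 2 p)) for t since sunrise,
    which puts the minimum at sunrise and the maximum ``p`` seconds after
    solar noon (Parton-Logan form), and averages it analytically over the
    daylight window.  ``method="mean"`` returns (tmax + tmin) / 2.
    """
    if tmax < tmin:
        raise ValueError(f"tmax ({tmax}) must be >= tmin ({tmin})")
    if method == "mean":
        return 0.5 * (tmax + tmin)
    if method != "sine":
        raise ValueError(f"unknown method {method!r}")
    if daylength_s <= 0:
        return 0.5 * (tmax + tmin)
    period = daylength_s + 2.0 * peak_lag_s
    # (1/D) * integral_0^D sin(pi t / period) dt
    mean_shape = (period / (math.pi * daylength_s)) * (
        1.0 - math.cos(math.pi * daylength_s / period))
    return tmin + (tmax - tmin) * mean_shape


# -- humidity ----------------------------------------------------------------

def esat_pa(t_c) -> float:
    """Saturation vapour pressure over water (Pa), Tetens formula."""
    t_c = np.asarray(t_c, dtype=float)
    return 610.78 * np.exp(17.27 * t_c / (t_c + 237.3))


def vpd_from(t_c, rh_pct) -> float:
    """Vapour-pressure deficit (Pa) from temperature (degC) and RH (%)."""
    rh = np.asarray(rh_pct, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError(f"relative humidity must lie in [0, 100] %, got {rh_pct}")
    return esat_pa(t_c) * (1.0 - rh / 100.0)


@dataclass(frozen=True)
class VPDScalarParams:
    """Breakpoints of the linear VPD downregulation ramp (Pa).

    Defaults are the calibrated values shared by all four vegetation types.
    """

    vpd_max: float = 4500.0
    vpd_min: float = 650.0

    def __post_init__(self) -> None:
        if not self.vpd_max > self.vpd_min > 0:
            raise ValueError(
                f"need vpd_max > vpd_min > 0, got ({self.vpd_max}, {self.vpd_min})")


def f_vpd(vpd, p: VPDScalarParams = VPDScalarParams()):
    """VPD scalar: 1 below vpd_min, 0 above vpd_max, linear ramp between."""
    vpd = np.asarray(vpd, dtype=float)
    ramp = (p.vpd_max - vpd) / (p.vpd_max - p.vpd_min)
    out = np.clip(ramp, 0.0, 1.0)
    return out if out.shape else float(out)


# -- radiation partitioning --------------------------------------------------

def diffuse_fraction(rg_daily: float, lat_deg: float, doy: int) -> float:
    """Daily diffuse fraction of global shortwave from the clearness index.

    Clearness = Rg / TOA radiation; the diffuse ratio is the documented
    polynomial :data:`DIFFUSE_POLY` in clearness, clipped to
    :data:`DIFFUSE_CLIP`.  Zero radiation returns the overcast limit 1.
    """
    if rg_daily < 0:
        raise ValueError(f"rg_daily must be non-negative, got {rg_daily}")
    toa = toa_daily_radiation(lat_deg, doy)
    if rg_daily == 0.0 or toa <= 0.0:
        return 1.0
    clearness = min(rg_daily / toa, 1.0)
    ratio = sum(c * clearness ** i for i, c in enumerate(DIFFUSE_POLY))
    return float(min(max(ratio, DIFFUSE_CLIP[0]), DIFFUSE_CLIP[1]))


# -- per-day driver bundle ---------------------------------------------------

@dataclass
class DailyDrivers:
    """One day of model drivers, raw plus derived quantities.

    Raw: date (any hashable label), rg_daily (MJ m-2; may be NaN when
    par_daily given directly), tmax/tmin (degC), rh_mean (%), lai (m2 m-2).
    Derived (filled by :func:`derive_day`): daylength (s), tp (degC),
    vpd (Pa), par_daily (mol photons m-2 day-1), diffuse_fraction.
    """

    date: object
    tmax: float
    tmin: float
    lai: float
    rg_daily: float = float("nan")
    rh_mean: float = float("nan")
    vpd: float = float("nan")
    par_daily: float = float("nan")
    daylength: float = float("nan")
    tp: float = float("nan")
    diffuse_fraction: float = float("nan")
    gpp_obs: float = float("nan")


def derive_day(day: DailyDrivers, lat_deg: float, doy: int,
               tp_method: str = "sine") -> DailyDrivers:
    """Fill the derived fields of a day in place (and return it).

    VPD precedence: an explicitly provided VPD wins; otherwise it is computed
    from (Tp, rh_mean).  PAR precedence: provided par_daily wins; otherwise
    converted from shortwave.  The diffuse fraction needs shortwave; when only
    PAR is given the equivalent shortwave 'par / (0.47 * 4.55 umol/J)' is used
    for the clearness index.
    """
    if day.tmax < day.tmin:
        raise ValueError(f"tmax < tmin on {day.date}")
    day.daylength = daylength(lat_deg, doy)
    day.tp = daytime_temperature(day.tmax, day.tmin, day.daylength, method=tp_method)
    if math.isnan(day.par_daily):
        if math.isnan(day.rg_daily):
            raise ValueError(f"day {day.date}: need rg_daily or par_daily")
        day.par_daily = float(par_from_shortwave(day.rg_daily))
    rg_equiv = day.rg_daily
    if math.isnan(rg_equiv):
        rg_equiv = day.par_daily / (PAR_FRACTION * PHOTONS_PER_J) * 1e-6
    if math.isnan(day.vpd):
        if math.isnan(day.rh_mean):
            raise ValueError(f"day {day.date}: need vpd or rh_mean")
        day.vpd = float(vpd_from(day.tp, day.rh_mean))
    day.diffuse_fraction = diffuse_fraction(rg_equiv, lat_deg, doy)
    return day
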