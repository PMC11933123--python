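"""Sunlit/shaded canopy upscaling of the daily leaf model.

The canopy is split into a sunlit and a shaded leaf class at a single
representative solar zenith for the day (Chen-type two-leaf separation):

    LAI_sun = 2 cos(theta) (1 - exp(-0.5 Omega LAI / cos(theta)))
    LAI_sh  = LAI - LAI_sun

Shaded leaves receive the per-leaf-area diffuse irradiance plus a multiple-
scattering term; sunlit leaves receive the same plus the direct beam projected
with a mean leaf-sun angle of 60 degrees.  Each class's daily absorbed PAR is
fed through the closed-form daily leaf model with the class sharing a single
(alpha, Pm) pair looked up at (Tp, Vcmax25), and canopy GPP is the
LAI-weighted sum, finally downregulated by the VPD scalar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import daily_core, solar_env
from .rhm_surface import ParameterSurface
from .solar_env import DailyDrivers, VPDScalarParams

__all__ = [
    "OMEGA_BY_VEGTYPE", "LEAF_ABSORPTANCE", "MEAN_LEAF_SUN_COS",
    "CanopyPartition", "CanopyResult",
    "partition_lai", "partition_apar", "canopy_gpp_daily",
    "DayEnvironment", "prepare_environment", "canopy_gpp_series",
]

#: Default foliage clumping index per vegetation type.
OMEGA_BY_VEGTYPE = {"ENF": 0.6, "DBF": 0.8, "GRA": 0.9, "EBF": 0.8}

LEAF_ABSORPTANCE = 0.9  # fraction of incident PAR absorbed by a leaf
MEAN_LEAF_SUN_COS = 0.5  # cos(60 deg): mean projection of leaves onto the beam


@dataclass(frozen=True)
class CanopyPartition:
    """Daily sunlit/shaded split: leaf areas (m2 m-2) and per-leaf-area daily
    absorbed PAR (mol photons m-2 leaf day-1)."""

    lai_sunlit: float
    lai_shaded: float
    apar_sunlit: float
    apar_shaded: float
    theta_rep: float
    omega: float


@dataclass(frozen=True)
class CanopyResult:
    """Per-day canopy outcome, g C m-2 ground day-1.

    gpp_sunlit / gpp_shaded are the per-leaf-area daily totals of each class;
    gpp_canopy is their LAI-weighted sum; gpp_actual applies the VPD scalar.
    """

    gpp_sunlit: float
    gpp_shaded: float
    gpp_canopy: float
    gpp_actual: float
    f_vpd: float
    form: str
    partition: CanopyPartition


def partition_lai(lai: float, omega: float, theta_rep_deg: float):
    """Split total LAI into (sunlit, shaded) at representative zenith."""
    if lai < 0:
        raise ValueError(f"lai must be non-negative, got {lai}")
    if not 0 < omega <= 1:
        raise ValueError(f"clumping index must lie in (0, 1], got {omega}")
    if not 0 <= theta_rep_deg < 90:
        raise ValueError(f"theta_rep must lie in [0, 90) degrees, got {theta_rep_deg}")
    if lai == 0.0:
        return 0.0, 0.0
    mu = math.cos(math.radians(theta_rep_deg))
    lai_sun = 2.0 * mu * (1.0 - math.exp(-0.5 * omega * lai / mu))
    lai_sun = min(lai_sun, lai)
    return lai_sun, lai - lai_sun


def partition_apar(par_daily: float, diffuse_fraction: float, lai: float,
                   theta_rep_deg: float, omega: float,
                   leaf_absorptance: float = LEAF_ABSORPTANCE,
                   multiple_scattering: bool = True):
    """Per-leaf-area daily absorbed PAR of the sunlit and shaded classes.

    ``par_daily`` is incident PAR above the canopy (mol photons m-2 ground
    day-1).  Shaded leaves absorb the canopy-intercepted diffuse flux spread
    over the total leaf area plus a multiple-scattering contribution from the
    beam; sunlit leaves absorb that plus the direct beam projected with the
    mean leaf-sun geometry.  Returns (apar_sunlit, apar_shaded) in
    mol photons m-2 leaf day-1.
    """
    if par_daily < 0:
        raise ValueError(f"par_daily must be non-negative, got {par_daily}")
    if not 0.0 <= diffuse_fraction <= 1.0:
        raise ValueError(f"diffuse_fraction must lie in [0, 1], got {diffuse_fraction}")
    if par_daily == 0.0 or lai <= 0.0:
        return 0.0, 0.0
    mu = math.cos(math.radians(theta_rep_deg))
    par_dif = diffuse_fraction * par_daily
    par_dir = par_daily - par_dif

    # representative transmission angle for diffuse light (cosine increases
    # slightly with LAI as deeper canopies see a more zenith-weighted sky)
    mu_dif = 0.537 + 0.025 * lai
    dif_under = par_dif * math.exp(-0.5 * omega * lai / mu_dif)
    scatter = 0.0
    if multiple_scattering:
        scatter = max(0.07 * omega * par_dir * (1.1 - 0.1 * lai), 0.0) * math.exp(-mu)
    apar_shaded = leaf_absorptance * ((par_dif - dif_under) / lai + scatter)
    apar_sunlit = leaf_absorptance * MEAN_LEAF_SUN_COS * par_dir / mu + apar_shaded
    return apar_sunlit, apar_shaded


def _partition_day(day: DailyDrivers, lat_deg: float, doy: int, omega: float,
                   leaf_absorptance: float = LEAF_ABSORPTANCE,
                   multiple_scattering: bool = True) -> CanopyPartition:
    theta = solar_env.mean_daytime_zenith(lat_deg, doy)
    theta = min(theta, 89.0)
    lai_sun, lai_sh = partition_lai(day.lai, omega, theta)
    apar_sun, apar_sh = partition_apar(
        day.par_daily, day.diffuse_fraction, day.lai, theta, omega,
        leaf_absorptance=leaf_absorptance, multiple_scattering=multiple_scattering)
    return CanopyPartition(lai_sunlit=lai_sun, lai_shaded=lai_sh,
                           apar_sunlit=apar_sun, apar_shaded=apar_sh,
                           theta_rep=theta, omega=omega)


def canopy_gpp_daily(day: DailyDrivers, lat_deg: float, doy: int,
                     surface: ParameterSurface, vcmax25: float,
                     form: str = daily_core.SINE,
                     vpd_params: VPDScalarParams = VPDScalarParams(),
                     omega: float = 0.8,
                     leaf_absorptance: float = LEAF_ABSORPTANCE,
                     multiple_scattering: bool = True) -> CanopyResult:
    """Daily canopy GPP for one day of drivers (g C m-2 day-1).

    Requires the derived driver fields (run :func:`tlrhm.solar_env.derive_day`
    first).  Days whose daytime temperature falls below the parameter
    surface's grid are treated as photosynthetically inactive; temperatures
    above the grid are clamped to its upper edge.
    """
    missing = [f for f in ("daylength", "tp", "vpd", "par_daily", "diffuse_fraction")
               if math.isnan(getattr(day, f))]
    if missing:
        raise ValueError(f"day {day.date}: derived driver fields missing: {missing}")

    part = _partition_day(day, lat_deg, doy, omega,
                          leaf_absorptance=leaf_absorptance,
                          multiple_scattering=multiple_scattering)
    fv = float(solar_env.f_vpd(day.vpd, vpd_params))
    cold = day.tp < surface.t_grid[0]
    if day.lai <= 0.0 or day.daylength <= 0.0 or cold or day.par_daily <= 0.0:
        return CanopyResult(0.0, 0.0, 0.0, 0.0, fv, form, part)

    t_query = min(day.tp, float(surface.t_grid[-1]))
    rhm = surface.lookup(t_query, vcmax25)
    gpp_sun = daily_core.gpp_daily(rhm.alpha, rhm.pm, part.apar_sunlit,
                                   day.daylength, form)
    gpp_sh = daily_core.gpp_daily(rhm.alpha, rhm.pm, part.apar_shaded,
                                  day.daylength, form)
    gpp_sun_gc = float(daily_core.umol_to_gc(gpp_sun))
    gpp_sh_gc = float(daily_core.umol_to_gc(gpp_sh))
    canopy = gpp_sun_gc * part.lai_sunlit + gpp_sh_gc * part.lai_shaded
    return CanopyResult(gpp_sunlit=gpp_sun_gc, gpp_shaded=gpp_sh_gc,
                        gpp_canopy=canopy, gpp_actual=canopy * fv,
                        f_vpd=fv, form=form, partition=part)


# -- vectorised path (ensemble runs over a whole site-year) ------------------

@dataclass
class DayEnvironment:
    """Vcmax-independent per-day arrays for a site-year.

    Precomputed once, then reused across ensemble candidates: only the
    (alpha, Pm) lookup and the closed-form integral depend on Vcmax,25.
    """

    doy: np.ndarray
    daylength: np.ndarray
    tp: np.ndarray
    f_vpd: np.ndarray
    lai: np.ndarray
    lai_sunlit: np.ndarray
    lai_shaded: np.ndarray
    apar_sunlit: np.ndarray
    apar_shaded: np.ndarray
    theta_rep: np.ndarray


def prepare_environment(days: list[DailyDrivers], lat_deg: float,
                        doys: list[int], omega: float,
                        vpd_params: VPDScalarParams = VPDScalarParams(),
                        leaf_absorptance: float = LEAF_ABSORPTANCE,
                        multiple_scattering: bool = True) -> DayEnvironment:
    n = len(days)
    env = DayEnvironment(*(np.zeros(n) for _ in range(10)))
    for i, (day, doy) in enumerate(zip(days, doys)):
        part = _partition_day(day, lat_deg, doy, omega,
                              leaf_absorptance=leaf_absorptance,
                              multiple_scattering=multiple_scattering)
        env.doy[i] = doy
        env.daylength[i] = day.daylength
        env.tp[i] = day.tp
        env.f_vpd[i] = solar_env.f_vpd(day.vpd, vpd_params)
        env.lai[i] = day.lai
        env.lai_sunlit[i] = part.lai_sunlit
        env.lai_shaded[i] = part.lai_shaded
        env.apar_sunlit[i] = part.apar_sunlit
        env.apar_shaded[i] = part.apar_shaded
        env.theta_rep[i] = part.theta_rep
    return env


def canopy_gpp_series(env: DayEnvironment, surface: ParameterSurface,
                      vcmax25: float, form: str = daily_core.SINE):
    """(gpp_canopy, gpp_actual) arrays in g C m-2 day-1 for one candidate."""
    active = ((env.tp >= surface.t_grid[0]) & (env.daylength > 0)
              & (env.lai > 0) & (env.apar_sunlit + env.apar_shaded > 0))
    canopy = np.zeros(env.tp.shape)
    if np.any(active):
        t_query = np.minimum(env.tp[active], surface.t_grid[-1])
        alpha, pm = surface.lookup_arrays(t_query, vcmax25)
        d = env.daylength[active]
        gpp_sun = daily_core.gpp_daily(alpha, pm, env.apar_sunlit[active], d, form)
        gpp_sh = daily_core.gpp_daily(alpha, pm, env.apar_shaded[active], d, form)
        canopy[active] = daily_core.umol_to_gc(
            gpp_sun * env.lai_sunlit[active] + gpp_sh * env.lai_shaded[active])
    return canopy, canopy * env.f_vpd
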