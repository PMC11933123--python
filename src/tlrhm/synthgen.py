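"""Synthetic site-years: daily drivers, matching half-hourly meteorology, and
a half-hourly process-model "truth" GPP series.

The generator emulates a mid-latitude flux site: seasonal and diurnal
temperature sinusoids, top-of-atmosphere radiation modulated by a stochastic
daily clearness factor (bounded beta draw), a double-logistic LAI phenology
peaking at ``lai_max``, and a constant-within-day relative humidity.  The
within-day radiation shape is deterministic (sine or squared sine) unless the
``unstable`` switch injects blockwise cloud modulation, which is the regime
where a fixed diurnal-shape assumption is known to break.

The daily driver table is produced by aggregating the half-hourly table, so
the two are exactly consistent by construction.

The "truth" series runs the sunlit/shaded partition and the instantaneous
enzyme-kinetic leaf model every half hour at the configured true Vcmax,25 and
sums to daily totals.  By default the truth shares the daily
representative-zenith canopy partition with the daily model ("matched" mode),
so that comparing the two isolates exactly the approximations the daily model
makes: the hyperbola compression and the assumed diurnal shape.  A fully
instantaneous per-time-step partition is available as ``partition="instantaneous"``.
The emitted observations are truth times the daily VPD scalar, i.e. the
synthetic ecosystem responds to humidity exactly as the daily model assumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import daily_core, solar_env
from .leaf_ek import LeafEKParams, gross_assimilation
from .site_io import SiteMeta, SiteYear, aggregate_halfhourly
from .solar_env import VPDScalarParams
from .two_leaf import (LEAF_ABSORPTANCE, MEAN_LEAF_SUN_COS, OMEGA_BY_VEGTYPE,
                       partition_apar, partition_lai)

__all__ = ["SynthConfig", "generate_site_year", "truth_gpp_halfhourly",
           "lai_phenology"]

#: winter LAI as a fraction of lai_max, per vegetation type
LAI_WINTER_FRACTION = {"ENF": 0.75, "EBF": 0.85, "DBF": 0.08, "GRA": 0.10}


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of one synthetic site-year.

    Defaults describe a humid temperate deciduous-forest site at 45 N: annual
    mean 8 degC with 12 degC seasonal amplitude and 9 degC diurnal range,
    daily clearness drawn in [0.25, 0.75] with a beta(4, 2) shape (mean 0.58),
    LAI peaking at 5 m2 m-2, mean RH 65%.
    """

    lat: float = 45.0
    vegetation_type: str = "DBF"
    true_vcmax25: float = 60.0
    lai_max: float = 5.0
    t_annual_mean: float = 8.0
    t_seasonal_amplitude: float = 12.0
    t_diurnal_range: float = 9.0
    t_noise_sd: float = 1.5
    rh_mean: float = 65.0
    rh_noise_sd: float = 8.0
    clearness_range: tuple = (0.25, 0.75)
    clearness_beta: tuple = (4.0, 2.0)
    profile: str = daily_core.SINE
    clear_sky: bool = False  # fixed clearness 0.75, no temperature noise
    constant_temperature: bool = False  # flat diurnal course at the day mean
    unstable: bool = False  # blockwise within-day cloud modulation
    n_days: int = 365
    year: int = 2003
    seed: int = 0
    ek_template: LeafEKParams = field(default_factory=LeafEKParams)

    def ek_params(self) -> LeafEKParams:
        return self.ek_template.replace(vcmax25=self.true_vcmax25)

    @property
    def omega(self) -> float:
        return OMEGA_BY_VEGTYPE[self.vegetation_type]


def lai_phenology(cfg: SynthConfig) -> np.ndarray:
    """Deterministic LAI course over the year, peaking at ``lai_max``.

    Double-logistic green-up/senescence curve, renormalised so its annual
    maximum is exactly 1, scaled between the vegetation type's winter floor
    and ``lai_max``.
    """
    doy = np.arange(1, cfg.n_days + 1, dtype=float)
    raw = (1.0 / (1.0 + np.exp(-0.10 * (doy - 120.0)))
           * 1.0 / (1.0 + np.exp(0.10 * (doy - 280.0))))
    raw /= raw.max()
    lai_min = LAI_WINTER_FRACTION[cfg.vegetation_type] * cfg.lai_max
    return lai_min + (cfg.lai_max - lai_min) * raw


def _halfhour_hours() -> np.ndarray:
    """Mid-points of the 48 half-hours, in local solar hours."""
    return (np.arange(48) + 0.5) * 0.5


def _day_shape(cfg: SynthConfig, doy: int, hours: np.ndarray) -> np.ndarray:
    """Dimensionless diurnal radiation shape at the half-hour mid-points."""
    d_s = solar_env.daylength(cfg.lat, doy)
    if d_s <= 0:
        return np.zeros_like(hours)
    d_h = d_s / 3600.0
    trise = 12.0 - d_h / 2.0
    x = (hours - trise) / d_h
    shape = np.where((x > 0) & (x < 1), np.sin(np.pi * np.clip(x, 0, 1)), 0.0)
    if cfg.profile == daily_core.SQUARED_SINE:
        shape = shape * shape
    return shape


def generate_site_year(cfg: SynthConfig):
    """Build one synthetic site-year.

    Returns ``(site_year, halfhourly)``: the daily :class:`SiteYear` (driver
    table aggregated from the half-hourly data, plus LAI and observed GPP) and
    the half-hourly DataFrame (datetime, ppfd, t_air, rh).
    """
    rng = np.random.default_rng(cfg.seed)
    hours = _halfhour_hours()
    kmin, kmax = cfg.clearness_range
    a_b, b_b = cfg.clearness_beta
    dates = pd.date_range(f"{cfg.year}-01-01", periods=cfg.n_days, freq="D")

    frames = []
    for i, date in enumerate(dates):
        doy = i + 1
        if cfg.clear_sky:
            clearness = kmax
            t_mean_noise = 0.0
            rh_day = cfg.rh_mean
        else:
            clearness = kmin + (kmax - kmin) * rng.beta(a_b, b_b)
            t_mean_noise = rng.normal(0.0, cfg.t_noise_sd)
            rh_day = float(np.clip(rng.normal(cfg.rh_mean, cfg.rh_noise_sd),
                                   20.0, 100.0))
        rg = clearness * solar_env.toa_daily_radiation(cfg.lat, doy)
        par_target = float(solar_env.par_from_shortwave(rg))  # mol m-2 day-1
        d_s = solar_env.daylength(cfg.lat, doy)
        shape = _day_shape(cfg, doy, hours)
        if d_s > 0 and shape.sum() > 0:
            noon = daily_core.NOON_COEFF[cfg.profile] * par_target * 1e6 / d_s
            ppfd = noon * shape
        else:
            ppfd = np.zeros_like(hours)
        if cfg.unstable:
            # 3-hour cloud blocks break the smooth diurnal shape
            factors = rng.uniform(0.25, 1.0, size=8)
            ppfd = ppfd * np.repeat(factors, 6)

        t_mean = (cfg.t_annual_mean
                  - cfg.t_seasonal_amplitude * math.cos(2.0 * math.pi * (doy - 15) / 365.0)
                  + t_mean_noise)
        if cfg.constant_temperature:
            t_air = np.full_like(hours, t_mean)
        else:
            # minimum near 03:00, maximum near 15:00
            t_air = t_mean + 0.5 * cfg.t_diurnal_range * np.sin(
                2.0 * math.pi * (hours - 9.0) / 24.0)

        frames.append(pd.DataFrame({
            "datetime": date + pd.to_timedelta(hours, unit="h"),
            "ppfd": ppfd, "t_air": t_air, "rh": rh_day}))

    hh = pd.concat(frames, ignore_index=True)
    daily = aggregate_halfhourly(hh)
    daily["lai"] = lai_phenology(cfg)

    meta = SiteMeta(site_id=f"SYN-{cfg.vegetation_type}-{cfg.seed}", lat=cfg.lat,
                    vegetation_type=cfg.vegetation_type, lai_max=cfg.lai_max,
                    vcmax25=cfg.true_vcmax25)
    site_year = SiteYear(meta=meta, table=daily)

    truth = truth_gpp_halfhourly(cfg, cfg.ek_params(), hh)
    fv = np.array([solar_env.f_vpd(day.vpd) for day in site_year.days()])
    daily = daily.assign(gpp_obs_gc_m2=truth * fv)
    site_year = SiteYear(meta=meta, table=daily)
    return site_year, hh


def truth_gpp_halfhourly(cfg: SynthConfig, ek_params: LeafEKParams,
                         hh: pd.DataFrame, lai=None,
                         partition: str = "matched") -> np.ndarray:
    """Daily GPP (g C m-2 day-1) from half-hourly enzyme-kinetic canopy runs.

    ``partition="matched"``: a single daily representative-zenith sunlit/shaded
    split; each class's daily absorbed PAR is distributed over the half hours
    proportionally to the observed incident-PPFD course, and the leaf model is
    evaluated at every lit half hour and summed.  ``"instantaneous"``
    recomputes the canopy partition at each half hour's solar zenith.
    """
    if partition not in ("matched", "instantaneous"):
        raise ValueError(f"unknown partition mode {partition!r}")
    ts = pd.to_datetime(hh["datetime"])
    days = hh.assign(_date=ts.dt.normalize(), _hour=ts.dt.hour + ts.dt.minute / 60.0)
    groups = list(days.groupby("_date", sort=True))
    if lai is None:
        lai = lai_phenology(cfg)
    lai = np.asarray(lai, dtype=float)
    if lai.size != len(groups):
        raise ValueError(f"LAI series length {lai.size} != {len(groups)} days")

    out = np.zeros(len(groups))
    step_s = 1800.0
    for i, (date, grp) in enumerate(groups):
        doy = int(pd.Timestamp(date).dayofyear)
        ppfd = grp["ppfd"].to_numpy(dtype=float)
        t_air = grp["t_air"].to_numpy(dtype=float)
        par_day = float(ppfd.sum() * step_s * 1e-6)  # mol m-2 day-1
        lai_d = float(lai[i])
        if par_day <= 0.0 or lai_d <= 0.0:
            continue
        rg_equiv = par_day / (solar_env.PAR_FRACTION * solar_env.PHOTONS_PER_J) * 1e-6
        fd = solar_env.diffuse_fraction(rg_equiv, cfg.lat, doy)
        lit = ppfd > 0
        t_lit = np.clip(t_air[lit], 0.0, 50.0)

        if partition == "matched":
            theta = min(solar_env.mean_daytime_zenith(cfg.lat, doy), 89.0)
            lai_sun, lai_sh = partition_lai(lai_d, cfg.omega, theta)
            apar_sun, apar_sh = partition_apar(par_day, fd, lai_d, theta, cfg.omega)
            # distribute each class's daily absorbed PAR along the observed course
            weights = ppfd[lit] / (ppfd[lit].sum() * step_s)  # s-1
            total = 0.0
            for cls_apar, cls_lai in ((apar_sun, lai_sun), (apar_sh, lai_sh)):
                if cls_lai <= 0.0 or cls_apar <= 0.0:
                    continue
                flux = cls_apar * 1e6 * weights  # umol m-2 leaf s-1
                g = sum(gross_assimilation(ek_params, float(q), float(t))
                        for q, t in zip(flux, t_lit))
                total += g * cls_lai * step_s
            out[i] = total * daily_core.GC_PER_UMOL
        else:
            hour = grp["_hour"].to_numpy(dtype=float)[lit]
            total = 0.0
            for q, t, h in zip(ppfd[lit], t_lit, hour):
                mu = solar_env.cos_zenith(cfg.lat, doy, float(h + 0.25))
                if mu <= 1e-3:
                    continue
                theta = math.degrees(math.acos(min(mu, 1.0)))
                lai_sun, lai_sh = partition_lai(lai_d, cfg.omega, min(theta, 89.0))
                q_dif = fd * q
                q_dir = q - q_dif
                mu_dif = 0.537 + 0.025 * lai_d
                dif_under = q_dif * math.exp(-0.5 * cfg.omega * lai_d / mu_dif)
                scatter = max(0.07 * cfg.omega * q_dir * (1.1 - 0.1 * lai_d), 0.0) \
                    * math.exp(-mu)
                q_sh = LEAF_ABSORPTANCE * ((q_dif - dif_under) / lai_d + scatter)
                q_sun = LEAF_ABSORPTANCE * MEAN_LEAF_SUN_COS * q_dir / mu + q_sh
                total += (gross_assimilation(ek_params, q_sun, float(t)) * lai_sun
                          + gross_assimilation(ek_params, q_sh, float(t)) * lai_sh
                          ) * step_s
            out[i] = total * daily_core.GC_PER_UMOL
    return out
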