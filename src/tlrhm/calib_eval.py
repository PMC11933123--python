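"""Ensemble-run calibration of Vcmax,25 and evaluation metrics.

The canopy model is run over all pooled site-years once per candidate
Vcmax,25; the candidate minimising the pooled RMSE against measured daily GPP
is selected (R2 is reported alongside).  The run over candidates reuses a
precomputed per-day environment, since only the (alpha, Pm) lookup and the
closed-form integral depend on Vcmax,25.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import daily_core
from .rhm_surface import ParameterSurface
from .site_io import SiteYear
from .solar_env import VPDScalarParams
from .two_leaf import canopy_gpp_series, prepare_environment

__all__ = [
    "MetricSet", "CalibrationResult", "metrics", "calibrate_vcmax",
    "simulate_site_year", "default_vcmax_candidates",
]


def default_vcmax_candidates() -> np.ndarray:
    """20-180 umol m-2 s-1 step 1, matching the parameter-surface range."""
    return np.arange(20.0, 181.0, 1.0)


@dataclass(frozen=True)
class MetricSet:
    """Agreement between modelled and measured daily GPP.

    r2: squared Pearson correlation (or coefficient of determination, by
    request); rmse and bias in g C m-2 day-1; n = pairs actually compared.
    """

    r2: float
    rmse: float
    bias: float
    n: int


def metrics(modeled, measured, r2_method: str = "pearson") -> MetricSet:
    """RMSE, bias and R2 over paired series; incomplete pairs are dropped."""
    modeled = np.asarray(modeled, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if modeled.shape != measured.shape:
        raise ValueError(f"series lengths differ: {modeled.shape} vs {measured.shape}")
    ok = np.isfinite(modeled) & np.isfinite(measured)
    m, o = modeled[ok], measured[ok]
    n = int(ok.sum())
    if n < 2:
        raise ValueError(f"need at least 2 complete pairs, got {n}")
    err = m - o
    rmse = float(np.sqrt(np.mean(err ** 2)))
    bias = float(np.mean(err))
    if np.ptp(o) == 0.0 or np.ptp(m) == 0.0:
        raise ValueError("R2 undefined: a series has zero variance")
    if r2_method == "pearson":
        r2 = float(np.corrcoef(m, o)[0, 1] ** 2)
    elif r2_method == "cod":
        r2 = float(1.0 - np.sum(err ** 2) / np.sum((o - o.mean()) ** 2))
    else:
        raise ValueError(f"unknown r2_method {r2_method!r}")
    return MetricSet(r2=r2, rmse=rmse, bias=bias, n=n)


@dataclass
class CalibrationResult:
    """Outcome of an ensemble run over candidate Vcmax,25 values."""

    vcmax25_opt: float
    grid: np.ndarray
    rmse_profile: np.ndarray
    r2_profile: np.ndarray
    r2_at_opt: float
    n_days: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"vcmax25": self.grid, "rmse": self.rmse_profile,
                             "r2": self.r2_profile})


def _pooled_environment(site_years, vpd_params):
    envs, observed = [], []
    for sy in site_years:
        obs = sy.measured_gpp
        if obs is None:
            raise ValueError(f"site {sy.site_id}: no measured GPP to calibrate against")
        envs.append(prepare_environment(sy.days(), sy.lat, sy.doys,
                                        sy.meta.omega_effective, vpd_params))
        observed.append(np.asarray(obs, dtype=float))
    return envs, observed


def calibrate_vcmax(site_years: list[SiteYear], surface: ParameterSurface,
                    grid=None, form: str = daily_core.SINE,
                    vpd_params: VPDScalarParams = VPDScalarParams()
                    ) -> CalibrationResult:
    """Select the Vcmax,25 minimising pooled RMSE across the site-years.

    Ties break toward the smaller candidate (argmin on an ascending grid).
    """
    grid = np.asarray(grid if grid is not None else default_vcmax_candidates(),
                      dtype=float)
    if grid.size == 0:
        raise ValueError("candidate grid is empty")
    if (grid.min() < surface.vcmax_grid[0]) or (grid.max() > surface.vcmax_grid[-1]):
        raise ValueError("candidate grid extends beyond the parameter surface")
    if not site_years:
        raise ValueError("need at least one site-year")

    envs, observed = _pooled_environment(site_years, vpd_params)
    obs_all = np.concatenate(observed)
    rmse_profile = np.empty(grid.size)
    r2_profile = np.empty(grid.size)
    for k, vc in enumerate(grid):
        mod_all = np.concatenate([
            canopy_gpp_series(env, surface, float(vc), form)[1] for env in envs])
        ms = metrics(mod_all, obs_all)
        rmse_profile[k] = ms.rmse
        r2_profile[k] = ms.r2
    best = int(np.argmin(rmse_profile))
    return CalibrationResult(
        vcmax25_opt=float(grid[best]), grid=grid, rmse_profile=rmse_profile,
        r2_profile=r2_profile, r2_at_opt=float(r2_profile[best]),
        n_days=int(obs_all.size))


def simulate_site_year(site_year: SiteYear, surface: ParameterSurface,
                       vcmax25: float,
                       vpd_params: VPDScalarParams = VPDScalarParams()
                       ) -> pd.DataFrame:
    """Per-day outputs for both diurnal forms (the output CSV schema)."""
    env = prepare_environment(site_year.days(), site_year.lat, site_year.doys,
                              site_year.meta.omega_effective, vpd_params)
    out = pd.DataFrame({"date": pd.to_datetime(site_year.table["date"]).dt.date})
    for form in (daily_core.SINE, daily_core.SQUARED_SINE):
        canopy, actual = canopy_gpp_series(env, surface, vcmax25, form)
        out[f"gpp_{form}"] = canopy
        out[f"gpp_actual_{form}"] = actual
    out["f_vpd"] = env.f_vpd
    out["lai_sunlit"] = env.lai_sunlit
    out["lai_shaded"] = env.lai_shaded
    out["tp"] = env.tp
    out["daylength"] = env.daylength
    return out
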