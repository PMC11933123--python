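# Methods

## Overview

`tlrhm` computes daily canopy gross primary productivity in four stages:

1. **Leaf process model → parameter surfaces.**  A coupled enzyme-kinetic /
   stomatal-conductance leaf model generates light-response curves of gross
   assimilation for every (temperature, V_cmax,25) combination on a grid;
   each curve is compressed into the two parameters (α, P_m) of a rectangular
   hyperbola by least squares.  The surfaces are built once and queried by
   bilinear interpolation.
2. **Analytical daily integration.**  The hyperbola is integrated in closed
   form over the daylight period under a sine or squared-sine diurnal
   radiation shape.
3. **Two-leaf canopy upscaling.**  LAI and absorbed PAR are partitioned into
   sunlit and shaded classes at a representative daily solar zenith; the
   daily integral is evaluated once per class and summed with LAI weights.
4. **VPD downregulation.**  The canopy total is scaled by a piecewise-linear
   scalar of daily vapour-pressure deficit.

V_cmax,25 — the single vegetation-type parameter — is calibrated by ensemble
runs over a candidate grid against measured daily GPP.

## Leaf model

Gross carboxylation is the co-limited minimum of the Rubisco-limited rate
W_c = V_cmax (C_i − Γ*)/(C_i + K_c(1 + O/K_o)) and the RuBP-regeneration
limited rate W_j = J (C_i − Γ*)/(4C_i + 8Γ*), with electron transport
J = α_q·I·J_max/(α_q·I + 2.1·J_max) (α_q = 0.385 on a quanta basis).  Net
assimilation A_n = A_gross − R_d couples to Ball–Woodrow–Berry conductance
g_s = m·A_n·rh/C_a + b (m = 10, b = 0.01 mol m⁻² s⁻¹, floored at b so
stomata never close beyond the residual conductance) through the diffusive
supply A_n = (C_a − C_i)·g_s/1.6.  C_i is solved by Brent's method on the
supply–demand residual (tolerance 1e-4 µmol mol⁻¹); the bracket extends
beyond C_a because in deep shade A_n < 0 and C_i > C_a.  Kinetic constants
and activation energies are Bernacchi values; V_cmax and J_max use peaked
Arrhenius functions (H_d = 200 kJ mol⁻¹, S_v = 650 J mol⁻¹ K⁻¹);
J_max,25 = 1.67·V_cmax,25, R_d,25 = 0.015·V_cmax,25.  Ambient CO₂ is fixed at
380 µmol mol⁻¹ and leaf-surface humidity at 0.7 during surface generation
(humidity variability enters later through f(VPD); CO₂ effects are out of
scope).  Leaf temperature equals air temperature throughout.

**Co-limitation curvature.**  The transition between W_c and W_j uses the
smaller root of θA² − (W_c + W_j)A + W_c·W_j = 0 with θ = 0.83, the curvature
used by the JULES land-surface model.  A hard minimum (θ = 1, also available)
produces Blackman-kinked light responses at cold or hot low-V_cmax
conditions that no two-parameter hyperbola can track (fit r² as low as
0.81), which would break the premise of the whole compression; with θ = 0.83
the worst cell on the default grid fits at r² = 0.992.

## Surface fitting

Light responses are sampled over 50–2000 µmol m⁻² s⁻¹, by default at step 10
below 200 µmol m⁻² s⁻¹ and step 50 above.  The denser low-light sampling
matters: with a uniform step-50 grid the equal-weight least-squares fit is
dominated by the saturated region and overshoots the leaf model by 3–5 % in
the 20–200 µmol band where shaded leaves and morning/evening hours operate.
That residual integrates to a ~1.5 % high bias in daily canopy GPP and pulls
the calibrated V_cmax,25 about 2 µmol m⁻² s⁻¹ low; the default sampling
reduces the pull to under 1 µmol m⁻² s⁻¹.  A `uniform_ppfd_grid` helper
provides the evenly spaced alternative.

Fits start from (initial slope, max response) with one restart from
(0.04, 1.2·max); r² is computed unweighted against the fitted points.
`build_surface` enforces r² ≥ 0.99 in every cell and raises naming the
offending cell otherwise.  Surfaces persist as a CSV trio (α, P_m, r²) with
grid headers plus a JSON sidecar carrying the leaf-model configuration; the
round trip is bit-exact (17-significant-digit formatting).

## Daily integrals

With a = P_m/(α·APAR_noon), both closed forms were re-derived symbolically
(Weierstrass substitution) and are accepted only because they agree with
adaptive quadrature of the defining integral to better than 1e-6 relative
over 10⁴ random parameter draws:

- sine: f(a) = 1 − (2a/π)·g(s) with g = arctan(s)/s for s = √(a²−1) (a > 1)
  and g = artanh(s)/s for s = √(1−a²) (a < 1); both branches share the limit
  g → 1, so f is continuous at a = 1 with value 1 − 2/π.  The branch switch
  uses |a − 1| < 1e-9.
- squared sine: f(a) = 1 − √(a/(a+1)).

GPP_daily = P_m·D·f(a), bounded by [0, P_m·D].  Noon amplitudes follow from
conserving the daily total: APAR_noon = (π/2)·APAR_daily/D (sine) and
2·APAR_daily/D (squared sine).  Because π/2 < 2, the sine shape delivers more
radiation away from noon where the light response is still steep, so the
sine-form GPP is never below the squared-sine form for identical inputs.
Outputs are converted to g C with 12.011e-6 g µmol⁻¹ at the reporting
boundary only.

## Solar geometry and drivers

Daylength uses the Cooper declination and standard hour-angle formula,
clipped for polar day/night.  Daytime mean temperature T_p reconstructs the
diurnal course as T(t) = T_min + (T_max − T_min)·sin(πt/(D + 2p)) from
sunrise, with the maximum lagging solar noon by p = 1.8 h (Parton–Logan
form), averaged analytically over the daylight window; `(T_max + T_min)/2`
is available as a configuration fallback.  VPD uses Tetens saturation over
water; an explicitly supplied VPD column takes precedence over (T_p, RH).
PAR from shortwave uses 0.47 (energy fraction) × 4.55 µmol J⁻¹.  The daily
diffuse fraction is the quartic clearness-index polynomial
0.943 + 0.734k − 4.9k² + 1.796k³ + 2.058k⁴ used in two-leaf canopy
modelling, clipped to [0.13, 1].

## Two-leaf partition

LAI_sunlit = 2cosθ·(1 − exp(−0.5·Ω·LAI/cosθ)); LAI is conserved exactly.
The representative zenith θ is the cosine-weighted daytime mean
(cosθ_rep = ∫cos²/∫cos over daylight hour angles) rather than the noon
value, so hours contributing more radiation weigh more.  Shaded leaves
absorb the intercepted diffuse flux spread over total LAI plus a
multiple-scattering term 0.07·Ω·PAR_dir·(1.1 − 0.1·LAI)·e^(−cosθ)
(switchable); sunlit leaves add the direct beam projected with a mean
leaf–sun angle of 60°.  Leaf absorptance is 0.9.  Both classes share one
(α, P_m) pair looked up at (T_p, V_cmax,25); only their APAR differs, and
each class's daily APAR is assumed to follow the same diurnal shape as the
canopy total.  Clumping-index defaults per vegetation type: ENF 0.6,
DBF 0.8, GRA 0.9, EBF 0.8.

Days whose T_p falls below the surface grid (1 °C) are treated as
photosynthetically inactive; T_p above 40 °C is clamped to the grid edge.
Out-of-range surface queries otherwise raise rather than silently clamp.

## Calibration

Ensemble runs over candidate V_cmax,25 (default 20–180, step 1) pool all
days across the supplied site-years and minimise RMSE against measured GPP;
ties break toward the smaller candidate and the procedure is deterministic.
R² is reported as squared Pearson correlation (coefficient-of-determination
variant by flag).  The per-day canopy environment (partitions, T_p, f(VPD))
is V_cmax-independent and precomputed once, so each candidate costs only a
vectorised surface lookup and closed-form evaluation.

## Synthetic site-years

The generator emulates a mid-latitude flux site under the model's own
assumptions: top-of-atmosphere radiation scaled by a daily clearness factor
drawn from a bounded beta distribution (0.25–0.75, beta(4,2)), deterministic
within-day sine or squared-sine radiation, seasonal + diurnal temperature
sinusoids with Gaussian day-to-day noise, constant-within-day RH, and a
double-logistic LAI phenology peaking at lai_max.  Daily drivers are
produced by aggregating the half-hourly table, so the two are consistent by
construction, and a single seeded generator makes every output bit
reproducible.  An `unstable` switch injects 3-hour cloud blocks to emulate
the broken-sky regime where any fixed diurnal-shape assumption degrades, and
`clear_sky` / `constant_temperature` switches produce the idealised days
used for fidelity checks.

The "truth" series runs the instantaneous leaf model every half hour at the
configured true V_cmax,25 and sums to daily totals.  By default it shares
the daily representative-zenith partition with the daily model, distributing
each class's daily absorbed PAR along the observed half-hourly PPFD course;
this isolates exactly the approximations the daily model makes — the
hyperbola compression and the assumed diurnal shape — rather than mixing in
differences of radiative-transfer geometry.  A fully instantaneous
per-time-step partition is available (`partition="instantaneous"`).
Emitted observations are truth × f(VPD), i.e. the synthetic ecosystem
responds to humidity exactly as the model assumes.  What passing tests on
these data do *not* show: robustness to measurement noise and gap structure
of real eddy-covariance data, to canopies violating the clumped-turbid-medium
partition, to days whose radiation departs from the assumed shapes, or to
soil-water and CO₂ effects — none of which the model represents.

## Problem sizes and numerical choices

The default surface (40 × 17 cells, 62-point light responses) builds in a
few seconds; closed-form agreement is checked against 10⁴ quadrature
evaluations; ordering and recovery experiments use 3 × 365 synthetic days
and 10 single-year calibrations respectively.  Quadrature uses adaptive
Gauss–Kronrod (eps 1e-12) or composite Simpson (≥100 panels) for the
fixed-step oracle.  Degenerate inputs are defined: zero APAR or zero LAI
give zero GPP; all-zero light responses and all-zero LAI series raise
degenerate-input errors; tmax < tmin raises.

## Known limitations

- Parameter surfaces are per vegetation type, not per site, and carry no
  seasonal V_cmax phenology.
- The diurnal-shape assumption fails on broken-sky days (overestimation,
  reproduced qualitatively by the `unstable` generator switch).
- No energy balance (leaf = air temperature), no mesophyll conductance, no
  C4 pathway, no soil-water or CO₂ response.
- The absolute (α, P_m) values depend on the leaf-model parameterization;
  a different parameterization rescales them, and calibration of V_cmax,25
  absorbs the difference.
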