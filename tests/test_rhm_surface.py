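"""Hyperbola fitting and parameter-surface tests, including the 2-D
grid-search least-squares oracle and the persistence round trip."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tlrhm.leaf_ek import LeafEKParams, gross_assimilation, light_response_curve
from tlrhm.rhm_surface import (DegenerateFitError, ParameterSurface,
                               build_surface, default_ppfd_grid,
                               fit_hyperbola, rectangular_hyperbola,
                               uniform_ppfd_grid)


def grid_search_fit(ppfd, a_gross, alpha_hi=0.12, pm_hi=60.0, rounds=4):
    """Independent oracle: zooming 2-D grid search minimising the SSE of the
    rectangular hyperbola over alpha in (0, alpha_hi], Pm in (0, pm_hi]."""
    a_lo, a_hi, p_lo, p_hi = 1e-4, alpha_hi, 1e-2, pm_hi
    best = None
    for _ in range(rounds):
        alphas = np.linspace(a_lo, a_hi, 81)
        pms = np.linspace(p_lo, p_hi, 81)
        sse = np.array([
            [float(np.sum((a_gross - rectangular_hyperbola(ppfd, a, p)) ** 2))
             for p in pms] for a in alphas])
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        best = (alphas[i], pms[j])
        da, dp = alphas[1] - alphas[0], pms[1] - pms[0]
        a_lo, a_hi = max(best[0] - 2 * da, 1e-5), best[0] + 2 * da
        p_lo, p_hi = max(best[1] - 2 * dp, 1e-3), best[1] + 2 * dp
    return best


def test_recovers_exact_hyperbola():
    ppfd = np.arange(50.0, 2001.0, 50.0)
    y = rectangular_hyperbola(ppfd, 0.05, 20.0)
    fit = fit_hyperbola(ppfd, y)
    assert fit.alpha == pytest.approx(0.05, rel=1e-6)
    assert fit.pm == pytest.approx(20.0, rel=1e-6)
    assert fit.r2 == pytest.approx(1.0, abs=1e-12)


def test_fit_of_leaf_model_curve_is_high_fidelity():
    """At 25 degC / Vcmax 52 the hyperbola tracks the leaf model at r2 >= 0.99."""
    params = LeafEKParams(vcmax25=52.0)
    ppfd = default_ppfd_grid()
    fit = fit_hyperbola(ppfd, light_response_curve(params, ppfd, 25.0))
    assert fit.r2 >= 0.99


def test_fit_matches_grid_search_oracle():
    params = LeafEKParams(vcmax25=100.0)
    ppfd = default_ppfd_grid()
    curve = light_response_curve(params, ppfd, 10.0)
    fit = fit_hyperbola(ppfd, curve)
    alpha_o, pm_o = grid_search_fit(ppfd, curve)
    assert fit.alpha == pytest.approx(alpha_o, rel=0.01)
    assert fit.pm == pytest.approx(pm_o, rel=0.01)


@given(scale=st.floats(0.2, 5.0))
@settings(deadline=None, max_examples=20)
def test_fit_is_scale_consistent(scale):
    """Scaling the response by c scales both fitted parameters by c."""
    ppfd = np.arange(50.0, 2001.0, 50.0)
    y = rectangular_hyperbola(ppfd, 0.04, 15.0)
    fit = fit_hyperbola(ppfd, scale * y)
    assert fit.alpha == pytest.approx(scale * 0.04, rel=1e-5)
    assert fit.pm == pytest.approx(scale * 15.0, rel=1e-5)


def test_fit_input_validation():
    ppfd = np.arange(50.0, 2001.0, 50.0)
    with pytest.raises(DegenerateFitError):
        fit_hyperbola(ppfd, np.zeros_like(ppfd))
    with pytest.raises(ValueError):
        fit_hyperbola(ppfd[:4], np.ones(4))
    with pytest.raises(ValueError):
        fit_hyperbola(ppfd[::-1], np.ones_like(ppfd))


def test_single_cell_surface_matches_direct_fit():
    params = LeafEKParams(vcmax25=52.0)
    surface = build_surface(params, t_grid=[25.0], vcmax_grid=[52.0])
    ppfd = default_ppfd_grid()
    fit = fit_hyperbola(ppfd, light_response_curve(params, ppfd, 25.0))
    assert surface.alpha_map[0, 0] == pytest.approx(fit.alpha, rel=1e-12)
    assert surface.pm_map[0, 0] == pytest.approx(fit.pm, rel=1e-12)


def test_surface_maps_positive_finite_and_smooth(default_surface):
    s = default_surface
    for m in (s.alpha_map, s.pm_map):
        assert np.all(np.isfinite(m)) and np.all(m > 0)
        # continuity along temperature (step 1 degC): jumps below 25 %
        dj_t = np.abs(np.diff(m, axis=0)) / m[:-1, :]
        assert dj_t.max() < 0.25
        # along Vcmax the maps scale near-proportionally with the grid (Pm is
        # roughly linear in Vcmax), so smoothness is a bound on the relative
        # curvature rather than on the raw jump
        curv = np.abs(np.diff(m, n=2, axis=1)) / m[:, 1:-1]
        assert curv.max() < 0.25


def test_pm_increases_with_vcmax_at_25c(default_surface):
    """More carboxylation capacity means a higher light-saturated rate,
    consistent with direct leaf-model evaluations at saturating light."""
    s = default_surface
    i = int(np.flatnonzero(s.t_grid == 25.0)[0])
    assert np.all(np.diff(s.pm_map[i, :]) > 0)
    sat = [gross_assimilation(LeafEKParams(vcmax25=float(v)), 2000.0, 25.0)
           for v in s.vcmax_grid[::4]]
    assert np.all(np.diff(sat) > 0)


def test_lookup_node_identity_and_midpoint(default_surface):
    s = default_surface
    got = s.lookup(25.0, 60.0)
    i = int(np.flatnonzero(s.t_grid == 25.0)[0])
    j = int(np.flatnonzero(s.vcmax_grid == 60.0)[0])
    assert got.alpha == pytest.approx(s.alpha_map[i, j], rel=1e-14)
    assert got.pm == pytest.approx(s.pm_map[i, j], rel=1e-14)
    mid = s.lookup(25.5, 65.0)
    quad = s.alpha_map[i:i + 2, j:j + 2]
    assert mid.alpha == pytest.approx(quad.mean(), rel=1e-12)


def test_lookup_off_grid_matches_fresh_fit(default_surface):
    """Bilinear interpolation agrees with a hyperbola refitted exactly at the
    off-grid condition to within 2 %."""
    t, vc = 22.3, 63.0
    got = default_surface.lookup(t, vc)
    ppfd = default_ppfd_grid()
    fresh = fit_hyperbola(ppfd, light_response_curve(
        LeafEKParams(vcmax25=vc), ppfd, t))
    assert got.alpha == pytest.approx(fresh.alpha, rel=0.02)
    assert got.pm == pytest.approx(fresh.pm, rel=0.02)


def test_lookup_out_of_range_raises_unless_clamped(default_surface):
    with pytest.raises(ValueError):
        default_surface.lookup(0.2, 60.0)
    with pytest.raises(ValueError):
        default_surface.lookup(25.0, 300.0)
    clamped = default_surface.lookup(0.2, 60.0, clamp=True)
    edge = default_surface.lookup(1.0, 60.0)
    assert clamped.alpha == edge.alpha and clamped.pm == edge.pm


def test_surface_round_trip_is_bit_exact(tmp_path, coarse_surface):
    coarse_surface.save(tmp_path)
    loaded = ParameterSurface.load(tmp_path)
    assert np.array_equal(loaded.t_grid, coarse_surface.t_grid)
    assert np.array_equal(loaded.vcmax_grid, coarse_surface.vcmax_grid)
    assert np.array_equal(loaded.alpha_map, coarse_surface.alpha_map)
    assert np.array_equal(loaded.pm_map, coarse_surface.pm_map)
    assert np.array_equal(loaded.r2_map, coarse_surface.r2_map)
    assert loaded.ek_config["vcmax25"] == coarse_surface.ek_config["vcmax25"]


def test_uniform_grid_spans_stated_range():
    g = uniform_ppfd_grid()
    assert g[0] == 50.0 and g[-1] == 2000.0 and np.all(np.diff(g) == 50.0)
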