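"""Hydraulic closed forms, atmospheric forcing, and unit conversions."""

import numpy as np
import pytest

from hydroniche.soilwater import (
    CLAY_SOIL,
    FEDDES_ALFALFA,
    FeddesParams,
    SiteConfig,
    VanGenuchtenParams,
    compare_vwc,
    conductivity_K,
    feddes_alpha,
    head_to_mpa,
    interpolate_root_density,
    mpa_to_head,
    partition_et,
    penman_monteith_et0,
    retention_theta,
    tracer_profile_to_roots,
    vwc_from_sensor,
    water_capacity,
)

LOAM = VanGenuchtenParams(theta_r=0.05, theta_s=0.45, alpha=0.01, n=2.0, Ks=10.0, l=0.5)


class TestRetention:
    def test_saturation_limit_exact(self):
        assert retention_theta(0.0, LOAM) == LOAM.theta_s
        assert retention_theta(5.0, LOAM) == LOAM.theta_s

    def test_dry_limit(self):
        assert retention_theta(-1e9, LOAM) == pytest.approx(LOAM.theta_r, abs=1e-6)

    def test_half_power_point(self):
        # |alpha h| = 1 -> Se = 2^(-1/2) for n = 2
        theta = retention_theta(-100.0, LOAM)
        expected = 0.05 + 0.40 / np.sqrt(2.0)
        assert theta == pytest.approx(expected, abs=1e-12)
        assert theta == pytest.approx(0.3328, abs=2e-4)

    def test_strictly_increasing_in_h(self):
        h = -np.logspace(-1, 6, 200)[::-1]  # ascending from very dry to wet
        th = retention_theta(h, CLAY_SOIL)
        assert np.all(np.diff(th) >= 0)

    def test_capacity_is_derivative(self):
        h = np.array([-10.0, -100.0, -1000.0])
        eps = 1e-4
        num = (retention_theta(h + eps, LOAM) - retention_theta(h - eps, LOAM)) / (2 * eps)
        np.testing.assert_allclose(water_capacity(h, LOAM), num, rtol=1e-5)


class TestConductivity:
    def test_saturated_limit(self):
        assert conductivity_K(0.0, LOAM) == LOAM.Ks
        assert conductivity_K(3.0, LOAM) == LOAM.Ks

    def test_dry_limit_vanishes(self):
        assert conductivity_K(-1e9, LOAM) == pytest.approx(0.0, abs=1e-12)

    def test_half_saturation_closed_form(self):
        # Se = 2^(-1/2): K/Ks = Se^0.5 (1-(1-Se^2)^0.5)^2
        se = 2.0 ** -0.5
        expected = se**0.5 * (1.0 - (1.0 - se**2) ** 0.5) ** 2
        assert conductivity_K(-100.0, LOAM) / LOAM.Ks == pytest.approx(expected, abs=1e-12)

    def test_monotone_nondecreasing_in_h(self):
        h = np.linspace(-5000, 0, 300)
        k = conductivity_K(h, CLAY_SOIL)
        assert np.all(np.diff(k) >= -1e-15)


class TestFeddes:
    def test_plateau_and_cutoffs(self):
        fp = FEDDES_ALFALFA
        assert feddes_alpha(-100.0, fp) == 1.0  # inside [h3, h2]
        assert feddes_alpha(fp.h4, fp) == 0.0
        assert feddes_alpha(-5.0, fp) == 0.0  # wetter than h1
        assert feddes_alpha(-9000.0, fp) == 0.0

    def test_ramp_midpoints(self):
        fp = FEDDES_ALFALFA
        mid_dry = 0.5 * (fp.h3 + fp.h4)
        assert feddes_alpha(mid_dry, fp) == pytest.approx(0.5)
        mid_wet = 0.5 * (fp.h1 + fp.h2)
        assert feddes_alpha(mid_wet, fp) == pytest.approx(0.5)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            FeddesParams(h1=-25.0, h2=-10.0, h3=-200.0, h4=-8000.0)


class TestPenmanMonteith:
    def test_zero_forcing_gives_zero(self):
        # saturated air (vpd = 0) and no radiation
        et0 = penman_monteith_et0(20.0, 20.0, 100.0, 0.0, 0.0, 180)
        assert et0 == 0.0

    def test_monotone_in_radiation(self):
        rs = np.array([5.0, 10.0, 20.0, 30.0])
        et0 = penman_monteith_et0(15.0, 28.0, 55.0, 2.0, rs, 20)
        assert np.all(np.diff(et0) > 0)

    def test_against_independent_recipe_evaluation(self):
        """Cross-check against a step-by-step evaluation of the standard
        daily reference-ET recipe at high precision (sympy)."""
        import sympy as sp

        tmin, tmax, rh, u2, rs, doy = 12.3, 21.5, 70.55, 2.78, 22.07, 187
        lat, elev = 50.80, 100.0
        T = sp.Rational(1, 2) * (sp.Float(tmax) + sp.Float(tmin))
        e0 = lambda t: sp.Float("0.6108") * sp.exp(sp.Float("17.27") * t / (t + sp.Float("237.3")))
        delta = 4098 * e0(T) / (T + sp.Float("237.3")) ** 2
        P = sp.Float("101.3") * ((293 - sp.Float("0.0065") * elev) / 293) ** sp.Float("5.26")
        gamma = sp.Float("0.000665") * P
        es = (e0(sp.Float(tmax)) + e0(sp.Float(tmin))) / 2
        ea = sp.Float(rh) / 100 * es
        J = sp.Float(doy)
        phi = sp.rad(sp.Float(lat))
        dr = 1 + sp.Float("0.033") * sp.cos(2 * sp.pi * J / 365)
        dec = sp.Float("0.409") * sp.sin(2 * sp.pi * J / 365 - sp.Float("1.39"))
        ws = sp.acos(-sp.tan(phi) * sp.tan(dec))
        Ra = (24 * 60 / sp.pi) * sp.Float("0.0820") * dr * (
            ws * sp.sin(phi) * sp.sin(dec) + sp.cos(phi) * sp.cos(dec) * sp.sin(ws)
        )
        Rso = (sp.Float("0.75") + 2 * sp.Float("1e-5") * elev) * Ra
        Rns = (1 - sp.Float("0.23")) * sp.Float(rs)
        tk4 = ((sp.Float(tmax) + sp.Float("273.16")) ** 4 + (sp.Float(tmin) + sp.Float("273.16")) ** 4) / 2
        rel = sp.Float(rs) / Rso
        Rnl = sp.Float("4.903e-9") * tk4 * (sp.Float("0.34") - sp.Float("0.14") * sp.sqrt(ea)) * (
            sp.Float("1.35") * rel - sp.Float("0.35")
        )
        Rn = Rns - Rnl
        num = sp.Float("0.408") * delta * Rn + gamma * 900 / (T + 273) * sp.Float(u2) * (es - ea)
        expected_mm = float(num / (delta + gamma * (1 + sp.Float("0.34") * sp.Float(u2))))

        site = SiteConfig(latitude_deg=lat, elevation_m=elev)
        et0_cm = penman_monteith_et0(tmin, tmax, rh, u2, rs, doy, site)
        assert et0_cm * 10 == pytest.approx(expected_mm, rel=0.02)

    def test_impossible_humidity_rejected(self):
        with pytest.raises(ValueError):
            penman_monteith_et0(15.0, 28.0, 120.0, 2.0, 20.0, 100)


class TestPartition:
    def test_bare_soil_all_evaporation(self):
        tp, ep = partition_et(0.5, 0.0)
        assert tp == 0.0 and ep == 0.5

    def test_dense_canopy_all_transpiration(self):
        tp, ep = partition_et(0.5, 100.0)
        assert tp == pytest.approx(0.5, abs=1e-12)

    def test_reference_extinction_value(self):
        tp, ep = partition_et(1.0, 2.0, k_ext=0.463)
        assert tp == pytest.approx(1.0 - np.exp(-0.926), abs=1e-12)
        assert tp + ep == pytest.approx(1.0)


class TestConversions:
    def test_mpa_head_round_trip(self):
        assert mpa_to_head(0.0) == 0.0
        assert mpa_to_head(-1.5) == pytest.approx(-15295.74, abs=0.5)
        x = -0.7354
        assert head_to_mpa(mpa_to_head(x)) == pytest.approx(x, abs=1e-12)

    def test_sensor_to_vwc_via_retention(self):
        theta = vwc_from_sensor(-0.01, LOAM)
        assert theta == pytest.approx(retention_theta(mpa_to_head(-0.01), LOAM))


class TestCompareVwc:
    def test_perfect_prediction(self):
        x = np.linspace(0.1, 0.4, 20)
        out = compare_vwc(x, x)
        assert out["slope"] == pytest.approx(1.0)
        assert out["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert out["r2"] == pytest.approx(1.0)
        assert out["rmse"] == pytest.approx(0.0, abs=1e-12)

    def test_noise_level_recovered(self):
        rng = np.random.default_rng(5)
        pred = np.linspace(0.1, 0.4, 400)
        obs = pred + rng.normal(0, 0.02, pred.size)
        out = compare_vwc(obs, pred)
        assert out["rmse"] == pytest.approx(0.02, rel=0.15)

    def test_r2_equals_squared_correlation(self):
        pred = np.array([0.1, 0.2, 0.3, 0.4, 0.35])
        obs = np.array([0.35, 0.30, 0.22, 0.15, 0.18])  # anti-correlated
        out = compare_vwc(obs, pred)
        r = np.corrcoef(pred, obs)[0, 1]
        assert out["r2"] == pytest.approx(r**2, abs=1e-12)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            compare_vwc([0.1, 0.2, 0.3], [0.2, 0.2, 0.2])


class TestRootAssembly:
    def test_single_campaign_is_time_constant(self):
        roots = tracer_profile_to_roots(
            [(30.0, [10.0, 30.0, 60.0], [0.5, 0.3, 0.2])], n_days=100
        )
        np.testing.assert_allclose(roots.density_at(0.0), roots.density_at(99.0))

    def test_identical_campaigns_idempotent(self):
        prof = (np.array([10.0, 30.0, 60.0]), np.array([0.5, 0.3, 0.2]))
        one = tracer_profile_to_roots([(30.0, *prof)], 100)
        two = tracer_profile_to_roots([(20.0, *prof), (80.0, *prof)], 100)
        np.testing.assert_allclose(two.density_at(10.0), one.density_at(10.0))
        np.testing.assert_allclose(two.density_at(90.0), one.density_at(90.0))

    def test_switch_at_campaign_midpoint_and_mean_between(self):
        from hydroniche.profiles import depth50
        from hydroniche.synthetic import generate_true_roots

        shallow = generate_true_roots(10.0)
        deep = generate_true_roots(30.0)
        roots = tracer_profile_to_roots([(20.0, shallow), (80.0, deep)], 100)
        np.testing.assert_allclose(roots.density_at(49.9), shallow)
        np.testing.assert_allclose(roots.density_at(50.1), deep)
        season_d50 = depth50(roots.season_mean(100))
        assert 10 < season_d50 < 30

    def test_every_slice_normalized(self):
        roots = tracer_profile_to_roots(
            [(10.0, [10.0, 50.0], [0.9, 0.1]), (60.0, [10.0, 50.0], [0.2, 0.8])], 90
        )
        for t in (0.0, 40.0, 80.0):
            assert roots.density_at(t).sum() == pytest.approx(1.0, abs=1e-9)

    def test_interpolation_respects_point_values(self):
        dens = interpolate_root_density([10.0, 50.0], [0.8, 0.2])
        assert dens[5] == dens[0]  # constant continuation above shallowest
        assert dens[124] < dens[60]  # decays toward the bottom
        assert dens.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            tracer_profile_to_roots([], 100)
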