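"""Vulnerability-curve computation and Pammenter fitting."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import grid_search_sse
from vitivc import vcfit
from vitivc.vcfit import (
    ConductivitySweep,
    FitError,
    UnusableSweepError,
    aggregate_variety,
    compare_groups,
    compute_hvs,
    compute_plc,
    derive_thresholds,
    fit_pammenter,
    pammenter,
)


def make_sweep(k, psi=None, **kw):
    psi = psi if psi is not None else -0.8 - 0.5 * np.arange(len(k))
    return ConductivitySweep(plant_id="p", psi=psi, k=np.asarray(k, float), **kw)


class TestComputePLC:
    @pytest.mark.parametrize(
        "k, expected",
        [
            ([2.0, 2.0], [0.0, 0.0]),
            ([2.0, 1.0, 0.0], [0.0, 50.0, 100.0]),
            ([2.0, 2.2], [0.0, -10.0]),  # noise above reference: retained, flagged
        ],
    )
    def test_formula(self, k, expected):
        curve = compute_plc(make_sweep(k))
        np.testing.assert_allclose(curve.plc, expected, atol=1e-12)

    def test_negative_plc_flagged(self):
        assert compute_plc(make_sweep([2.0, 2.2])).has_negative
        assert not compute_plc(make_sweep([2.0, 1.0])).has_negative

    def test_reference_is_first_pressure_not_max(self):
        # k_max is the -0.8 MPa reading even when a later reading is larger
        curve = compute_plc(make_sweep([2.0, 2.5, 1.0]))
        np.testing.assert_allclose(curve.plc, [0.0, -25.0, 50.0])

    def test_zero_reference_rejected(self):
        with pytest.raises(UnusableSweepError):
            compute_plc(make_sweep([0.0, 1.0]))

    def test_non_monotone_pressures_rejected(self):
        with pytest.raises(ValueError, match="decreasing"):
            make_sweep([2.0, 1.0], psi=np.array([-0.8, -0.8]))


class TestDeriveThresholds:
    @pytest.mark.parametrize(
        "psi50, slope, expected",
        [((-2.0), 50.0, (-1.0, -3.0)), ((-3.0), 25.0, (-1.0, -5.0))],
    )
    def test_formula(self, psi50, slope, expected):
        assert derive_thresholds(psi50, slope) == pytest.approx(expected)

    def test_sigmoid_value_at_thresholds(self):
        # at psi12 the sigmoid is 100/(1+e^2), at psi88 100/(1+e^-2)
        psi12, psi88 = derive_thresholds(-2.5, 60.0)
        assert pammenter(psi12, -2.5, 60.0) == pytest.approx(100 / (1 + math.e**2))
        assert pammenter(psi88, -2.5, 60.0) == pytest.approx(100 / (1 + math.e**-2))

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            derive_thresholds(-2.0, 0.0)

    @given(
        psi50=st.floats(-8.0, -0.5),
        slope=st.floats(5.0, 300.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_ordering_invariant(self, psi50, slope):
        psi12, psi88 = derive_thresholds(psi50, slope)
        assert psi88 < psi50 < psi12


class TestFitPammenter:
    def test_noiseless_points_recover_parameters(self):
        psi = np.linspace(-0.5, -5.0, 10)
        plc = pammenter(psi, -2.5, 50.0)
        fit = fit_pammenter(psi=psi, plc=plc)
        assert fit.converged
        assert fit.psi50 == pytest.approx(-2.5, abs=1e-6)
        assert fit.slope == pytest.approx(50.0, abs=1e-4)

    def test_noiseless_sweep_roundtrip(self, sharp_truth):
        # sweep -> PLC -> fit inverts generation when the curve is intact
        # at the -0.8 MPa reference pressure
        from vitivc import gen_sweep

        sweep, rec = gen_sweep(sharp_truth, noise_cv=0.0, seed=3)
        fit = fit_pammenter(compute_plc(sweep))
        assert fit.psi50 == pytest.approx(rec["psi50"], abs=1e-4)
        assert fit.slope == pytest.approx(rec["slope"], rel=1e-4)

    def test_fit_at_psi50_gives_half_loss(self):
        psi = np.linspace(-0.5, -5.0, 8)
        fit = fit_pammenter(psi=psi, plc=pammenter(psi, -3.0, 80.0))
        assert fit.predict(fit.psi50) == pytest.approx(50.0)

    def test_sse_not_worse_than_grid_search(self):
        rng = np.random.default_rng(42)
        psi = -0.8 - 0.5 * np.arange(10)
        for _ in range(10):
            p50 = rng.uniform(-4.5, -1.5)
            s = rng.uniform(20, 150)
            plc = pammenter(psi, p50, s) + rng.normal(0, 3, size=psi.size)
            fit = fit_pammenter(psi=psi, plc=plc)
            grid_sse, _, _ = grid_search_sse(psi, plc)
            assert fit.sse <= grid_sse + 1e-9

    def test_scale_invariance_of_plc(self):
        # PLC is dimensionless: rescaling conductivity units changes nothing
        k = np.array([2.0, 1.9, 1.5, 0.9, 0.4, 0.1])
        f1 = fit_pammenter(compute_plc(make_sweep(k)))
        f2 = fit_pammenter(compute_plc(make_sweep(k * 1e3)))
        assert f1.psi50 == pytest.approx(f2.psi50, abs=1e-9)
        assert f1.slope == pytest.approx(f2.slope, rel=1e-9)

    def test_too_few_points_refused(self):
        psi = np.array([-1.0, -2.0, -3.0])
        with pytest.raises(FitError, match="at least 4"):
            fit_pammenter(psi=psi, plc=pammenter(psi, -2.0, 50.0))

    def test_flat_curve_refused(self):
        psi = np.linspace(-0.5, -5.0, 6)
        with pytest.raises(FitError, match="span"):
            fit_pammenter(psi=psi, plc=np.full(6, 3.0))

    def test_parameter_recovery_under_noise(self):
        # 200 synthetic plants at cv = 0.05 on the default grid: the median
        # psi50 error stays within 0.1 MPa
        from vitivc import VarietyTruth, gen_cohort

        varieties = [VarietyTruth(f"v{i}", p50, s, 0.0, 0.0)
                     for i, (p50, s) in enumerate([(-2.0, 80), (-2.5, 100),
                                                   (-3.0, 110), (-3.5, 90)])]
        sweeps, truth = gen_cohort(varieties, n_plants_per_variety=50,
                                   noise_cv=0.05, seed=123)
        errors = []
        for sweep, (_, rec) in zip(sweeps, truth.iterrows()):
            fit = fit_pammenter(compute_plc(sweep))
            if fit.converged:
                errors.append(abs(fit.psi50 - rec["psi50"]))
        assert len(errors) >= 190
        assert np.median(errors) <= 0.1


class TestModelShape:
    @given(
        psi50=st.floats(-6.0, -1.0),
        slope=st.floats(10.0, 200.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_monotone_increasing_as_psi_decreases(self, psi50, slope):
        psi = np.linspace(0.0, -8.0, 50)
        plc = pammenter(psi, psi50, slope)
        assert np.all(np.diff(plc) >= 0)
        assert pammenter(psi50, psi50, slope) == pytest.approx(50.0)


class TestAggregation:
    def make_fit(self, psi50, slope, **kw):
        psi12, psi88 = derive_thresholds(psi50, slope)
        return vcfit.VulnerabilityFit(psi50=psi50, slope=slope, psi12=psi12,
                                      psi88=psi88, sse=0.0, converged=True,
                                      n_points=10, **kw)

    def test_single_fit_mean_is_fit_and_se_absent(self):
        out = aggregate_variety([self.make_fit(-2.5, 50, variety="A", season="summer")])
        assert out["psi50_mean"].iloc[0] == pytest.approx(-2.5)
        assert np.isnan(out["psi50_sem"].iloc[0])
        assert out["n_plants"].iloc[0] == 1

    def test_identical_fits_have_zero_se(self):
        fits = [self.make_fit(-2.5, 50, variety="A") for _ in range(3)]
        out = aggregate_variety(fits)
        assert out["psi50_sem"].iloc[0] == pytest.approx(0.0)

    def test_means_match_hand_arithmetic(self):
        fits = [self.make_fit(p, 50, variety="A") for p in (-2.0, -2.5, -3.0)]
        out = aggregate_variety(fits)
        assert out["psi50_mean"].iloc[0] == pytest.approx(-2.5)
        # SE = sd/sqrt(n) = 0.5/sqrt(3)
        assert out["psi50_sem"].iloc[0] == pytest.approx(0.5 / math.sqrt(3))

    def test_unconverged_fits_excluded(self):
        good = self.make_fit(-2.0, 50, variety="A")
        bad = self.make_fit(-9.0, 50, variety="A")
        bad.converged = False
        out = aggregate_variety([good, bad])
        assert out["n_plants"].iloc[0] == 1
        assert out["psi50_mean"].iloc[0] == pytest.approx(-2.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            aggregate_variety(pd.DataFrame(columns=["variety", "psi50", "converged"]))


class TestCompareGroups:
    def test_identical_groups(self):
        delta, t, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert delta == 0.0 and p == pytest.approx(1.0)

    def test_delta_sign_matches_mean_difference(self):
        delta, t, _ = compare_groups([-3.0, -3.1], [-2.0, -2.1])
        assert delta > 0 and t > 0

    def test_t_matches_textbook_formula(self):
        # a=(1,2,3), b=(2,4,6): delta=2, pooled var=(2*1+2*4)/4=2.5,
        # t = 2/sqrt(2.5*(1/3+1/3)) = 2*sqrt(3/5)
        delta, t, p = compare_groups([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert delta == pytest.approx(2.0)
        assert t == pytest.approx(2.0 * math.sqrt(3.0 / 5.0))
        from scipy import stats

        assert p == pytest.approx(2 * stats.t.sf(t, df=4))

    def test_degenerate_distinct_constants(self):
        delta, t, p = compare_groups([1.0, 1.0], [2.0, 2.0])
        assert delta == 1.0 and math.isinf(t) and p == 0.0

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0])


class TestHVS:
    def row(self, variety, season, psi12, psi50):
        return dict(variety=variety, season=season, psi12_mean=psi12, psi50_mean=psi50)

    def test_leaf_minus_stem(self):
        res = compute_hvs(self.row("Syrah", "summer", -1.2, -1.8),
                          self.row("Syrah", "summer", -2.0, -2.6))
        assert res.hvs_psi50 == pytest.approx(0.8)
        assert res.hvs_psi12 == pytest.approx(0.8)

    def test_equal_organs_give_zero(self):
        r = self.row("Syrah", "spring", -1.5, -2.2)
        res = compute_hvs(r, dict(r))
        assert res.hvs_psi12 == 0.0 and res.hvs_psi50 == 0.0

    def test_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            compute_hvs(self.row("Syrah", "summer", -1, -2),
                        self.row("Syrah", "spring", -1, -2))

    def test_grapevine_scale_means_fall_in_observed_band(self):
        # leaves ~0.6-1.0 MPa less negative than stems at psi50 is the
        # magnitude reported for grapevine; subtraction must land inside it
        res = compute_hvs(self.row("Cabernet Sauvignon", "summer", -1.4, -1.9),
                          self.row("Cabernet Sauvignon", "summer", -2.2, -2.7))
        assert 0.62 <= res.hvs_psi50 <= 1.02
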