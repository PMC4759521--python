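"""Regression forms, AICc selection, global z, area correction, model averaging."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from elevdiv import (
    RichnessProfile,
    area_correct,
    compare_models,
    fit_form,
    global_z,
    latitude_models,
    sar_models,
    tri_models,
)
from elevdiv.gradient_stats import RegressionFit


def ols_oracle(X, y):
    """From-scratch OLS via the normal equations: coefficients, F, p, AICc.

    Independent of statsmodels: matrix algebra + Gaussian log-likelihood with
    the error variance counted as a parameter.
    """
    X, y = np.asarray(X, float), np.asarray(y, float)
    n, p = X.shape
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    df1, df2 = p - 1, n - p
    F = ((tss - rss) / df1) / (rss / df2)
    pval = float(scipy.stats.f.sf(F, df1, df2))
    r2 = 1 - rss / tss
    adj = 1 - (1 - r2) * (n - 1) / (n - p)
    sigma2 = rss / n  # ML estimate
    llf = -n / 2 * (np.log(2 * np.pi * sigma2) + 1)
    k = p + 1
    aicc = 2 * k - 2 * llf + 2 * k * (k + 1) / (n - k - 1)
    return beta, F, pval, r2, adj, aicc


def dummy_fit(aicc, form="linear", slope=1.0):
    return RegressionFit(
        form=form,
        params={"intercept": 0.0, "x": slope},
        bse={"intercept": 0.0, "x": 0.0},
        n=9,
        k=3,
        r2=0.5,
        adj_r2=0.4,
        F=1.0,
        df=(1, 7),
        p_value=0.5,
        aicc=aicc,
    )


class TestFitForm:
    def test_exact_power_law_recovers_exponent(self):
        """y = 10 * x^0.36 is exact under the log-log (curvilinear) form."""
        x = np.array([100, 200, 400, 800, 1600, 3200, 640, 90, 1500.0])
        y = 10 * x**0.36
        fit = fit_form(x, y, "curvilinear")
        assert fit.slope == pytest.approx(0.36, rel=1e-10)
        assert fit.params["intercept"] == pytest.approx(1.0, rel=1e-10)  # log10(10)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_response_zero_slope_zero_r2(self):
        fit = fit_form(np.arange(9.0) + 1, np.full(9, 7.0), "linear")
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == 0.0 and fit.adj_r2 == 0.0

    @pytest.mark.parametrize("form", ["linear", "semilog", "curvilinear", "quadratic"])
    def test_matches_matrix_algebra_oracle(self, form, rng):
        """F, p, r2, AICc agree with an independent normal-equations oracle."""
        x = rng.uniform(10, 2000, 9)
        y = rng.uniform(5, 300, 9)
        fit = fit_form(x, y, form)
        xt = np.log10(x) if form in ("semilog", "curvilinear") else x
        yt = np.log10(y) if form == "curvilinear" else y
        if form == "quadratic":
            X = np.column_stack([np.ones(9), x, x**2])
        else:
            X = np.column_stack([np.ones(9), xt])
        beta, F, pval, r2, adj, aicc = ols_oracle(X, yt)
        assert fit.params["intercept"] == pytest.approx(beta[0], rel=1e-8)
        assert fit.slope == pytest.approx(beta[1], rel=1e-8)
        assert fit.F == pytest.approx(F, rel=1e-8)
        assert fit.p_value == pytest.approx(pval, rel=1e-8)
        assert fit.r2 == pytest.approx(r2, rel=1e-8)
        assert fit.adj_r2 == pytest.approx(adj, rel=1e-8)
        assert fit.aicc == pytest.approx(aicc, rel=1e-8)

    def test_nonpositive_rows_dropped_or_error(self):
        x = np.array([0.0, 1, 2, 3, 4, 5])
        y = np.array([1.0, 2, 3, 4, 5, 6])
        fit = fit_form(x, y, "semilog")
        assert fit.excluded == 1 and fit.n == 5
        with pytest.raises(ValueError, match="non-positive"):
            fit_form(x, y, "semilog", on_nonpositive="error")

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_form(np.arange(3.0), np.arange(3.0), "linear")

    def test_jacobian_changes_only_log_response_aicc(self, rng):
        x = rng.uniform(10, 2000, 9)
        y = rng.uniform(5, 300, 9)
        plain = fit_form(x, y, "curvilinear")
        corr = fit_form(x, y, "curvilinear", jacobian=True)
        assert corr.aicc == pytest.approx(
            plain.aicc + 2 * np.sum(np.log(y * np.log(10))), rel=1e-10
        )
        assert fit_form(x, y, "linear", jacobian=True).aicc == fit_form(x, y, "linear").aicc


class TestCompareModels:
    def test_equal_aicc_equal_weights(self):
        ms = compare_models([dummy_fit(10.0), dummy_fit(10.0)])
        assert ms.akaike_weight == pytest.approx((0.5, 0.5))
        assert ms.delta_aicc == (0.0, 0.0)

    def test_delta_twenty(self):
        ms = compare_models([dummy_fit(5.0), dummy_fit(25.0)])
        w2 = np.exp(-10) / (1 + np.exp(-10))
        assert ms.akaike_weight[1] == pytest.approx(w2, rel=1e-10)
        assert ms.akaike_weight[0] == pytest.approx(1 - w2, rel=1e-10)

    def test_single_fit_weight_one(self):
        ms = compare_models([dummy_fit(3.0)])
        assert ms.akaike_weight == (1.0,)
        assert ms.best.aicc == 3.0

    def test_weights_sum_to_one_and_best_delta_zero(self, rng):
        ms = compare_models([dummy_fit(a) for a in rng.uniform(0, 50, 6)])
        assert sum(ms.akaike_weight) == pytest.approx(1.0)
        assert min(ms.delta_aicc) == 0.0


class TestGlobalZ:
    def _fit(self, slope, p=0.001):
        f = dummy_fit(0.0, form="curvilinear", slope=slope)
        return RegressionFit(**{**f.__dict__, "p_value": p})

    def test_identical_slopes_zero_width(self):
        gz = global_z({f"g{i}": self._fit(0.36) for i in range(3)})
        assert gz.z == pytest.approx(0.36)
        assert gz.ci_low == pytest.approx(0.36)
        assert gz.ci_high == pytest.approx(0.36)

    def test_two_slopes_t_interval(self):
        gz = global_z({"a": self._fit(0.2), "b": self._fit(0.4)})
        se = np.std([0.2, 0.4], ddof=1) / np.sqrt(2)
        half = scipy.stats.t.ppf(0.975, 1) * se
        assert gz.z == pytest.approx(0.3)
        assert gz.ci_low == pytest.approx(0.3 - half)
        assert gz.ci_high == pytest.approx(0.3 + half)

    def test_nonsignificant_excluded(self):
        fits = {"a": self._fit(0.2), "b": self._fit(0.4), "c": self._fit(5.0, p=0.9)}
        gz = global_z(fits)
        assert set(gz.contributing) == {"a", "b"}

    def test_single_gradient_errors(self):
        with pytest.raises(ValueError, match="per-gradient"):
            global_z({"a": self._fit(0.3)})


class TestAreaCorrect:
    def test_equal_areas_identity(self, scheme):
        prof = RichnessProfile(scheme, np.array([5, 10, 20, 30, 25, 15, 8, 4, 2]))
        out = area_correct(prof, np.full(9, 700.0), z=0.36)
        np.testing.assert_allclose(out, prof.counts)

    def test_z_zero_identity(self, scheme, rng):
        counts = rng.integers(1, 50, 9)
        prof = RichnessProfile(scheme, counts)
        np.testing.assert_allclose(area_correct(prof, rng.uniform(10, 500, 9), 0.0), counts)

    def test_flat_richness_monotone_area_gives_decreasing(self, scheme):
        area = np.linspace(100, 1000, 9)
        out = area_correct(np.full(9, 40.0), area, z=0.36)
        assert (np.diff(out) < 0).all()

    def test_area_rescaling_invariance(self, scheme, rng):
        counts = rng.integers(1, 60, 9).astype(float)
        area = rng.uniform(50, 900, 9)
        a = area_correct(counts, area, 0.4)
        b = area_correct(counts, area * 37.5, 0.4)
        np.testing.assert_allclose(a, b)

    def test_zero_area_nonzero_richness_errors(self):
        with pytest.raises(ValueError, match="area"):
            area_correct(np.array([1.0, 2, 3, 4]), np.array([0.0, 1, 1, 1]), 0.3)


class TestTriModels:
    def test_exact_loglog_relation(self):
        tri = np.array([50, 80, 120, 200, 300, 160, 90, 70, 60.0])
        rich = 10 ** (0.5 + 0.8 * np.log10(tri))
        ms = tri_models(rich, tri)
        assert ms["curvilinear"].r2 == pytest.approx(1.0)
        assert ms.best.form == "curvilinear"

    def test_constant_tri_flagged(self):
        with pytest.raises(ValueError, match="constant predictor"):
            tri_models(np.arange(9.0) + 1, np.full(9, 100.0))

    def test_area_adjusted_predictor(self, rng):
        tri = rng.uniform(50, 300, 9)
        area = rng.uniform(100, 900, 9)
        y = rng.uniform(5, 60, 9)
        ms = tri_models(y, tri, area)
        manual = fit_form(tri / np.sqrt(area), y, "linear")
        assert ms["linear"].slope == pytest.approx(manual.slope)

    def test_missing_bands_dropped_pairwise(self, rng):
        tri = rng.uniform(50, 300, 9)
        tri[[0, 7]] = np.nan
        ms = tri_models(rng.uniform(5, 60, 9), tri)
        assert ms["linear"].n == 7

    def test_too_few_bands(self):
        with pytest.raises(ValueError, match=">= 4"):
            tri_models(np.arange(4.0), np.array([np.nan, 1, 2, np.nan]))


class TestSarModels:
    def test_three_forms_and_curvilinear_wins_on_power_law(self, rng):
        area = np.geomspace(50, 3000, 9)
        rich = 3.0 * area**0.36 * 10 ** rng.normal(0, 0.01, 9)
        ms = sar_models(rich, area)
        assert {f.form for f in ms.fits} == {"linear", "semilog", "curvilinear"}
        assert ms["curvilinear"].slope == pytest.approx(0.36, abs=0.05)


class TestLatitudeModels:
    def make_table(self, rng, slope=-4.55, noise=0.0):
        lat = np.array([8.0, 4.0, 1.0, -3.0, -7.0, -12.0, -15.0])
        return pd.DataFrame(
            {
                "richness": 80 + slope * np.abs(lat) + rng.normal(0, noise, lat.size),
                "mid_latitude": lat,
                "mean_tri": rng.uniform(100, 400, lat.size),
                "mid_elevation": rng.uniform(2000, 3000, lat.size),
            }
        )

    def test_recovers_generating_slope(self, rng):
        mset, avg = latitude_models(self.make_table(rng, noise=1e-6))
        assert len(mset.fits) == 4
        assert avg.estimates["latitude"] == pytest.approx(-4.55, abs=0.005)

    def test_averaged_within_per_model_span(self, rng):
        mset, avg = latitude_models(self.make_table(rng, noise=10.0))
        for param, est in avg.estimates.items():
            vals = [f.params[param] for f in mset.fits if param in f.params]
            assert min(vals) - 1e-12 <= est <= max(vals) + 1e-12

    def test_single_containing_model_equals_its_coefficient(self, rng):
        # elevation appears only in one model: natural averaging returns it as-is
        mset, avg = latitude_models(self.make_table(rng, noise=5.0))
        (m2,) = [f for f in mset.fits if "elevation" in f.params]
        assert avg.estimates["elevation"] == pytest.approx(m2.params["elevation"])

    def test_pure_noise_prefers_intercept_only(self, rng):
        df = self.make_table(rng, slope=0.0, noise=1.0)
        df["richness"] = 50 + rng.normal(0, 1.0, len(df))
        mset, avg = latitude_models(df)
        assert abs(avg.estimates["latitude"]) < 1.0

    def test_too_few_regions(self, rng):
        with pytest.raises(ValueError, match=">= 5"):
            latitude_models(self.make_table(rng).iloc[:4])

    def test_signed_latitude_flag(self, rng):
        df = self.make_table(rng, noise=1e-6)
        _, avg_abs = latitude_models(df)
        _, avg_signed = latitude_models(df, signed_latitude=True)
        assert avg_abs.estimates["latitude"] != pytest.approx(avg_signed.estimates["latitude"])
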