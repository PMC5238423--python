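import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from migraphen.trends import (aicc, build_design, detrend,
                              detrended_greenup_models, fit_cross_sectional,
                              fit_lmm_set, fit_random_intercept, model_table)


class TestAICc:
    def test_closed_form_example(self):
        assert aicc(-10.0, 2, 10) == pytest.approx(24.0 + 12.0 / 7.0)

    def test_limits_to_aic_for_large_n(self):
        aic = -2.0 * (-10.0) + 2 * 3
        assert aicc(-10.0, 3, 10**9) == pytest.approx(aic, abs=1e-6)

    def test_degenerate_sample_size_raises(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 9, 10)


class TestDetrend:
    def test_linear_input_gives_zero_residuals(self):
        yr = np.arange(2002, 2012, dtype=float)
        assert np.allclose(detrend(200 - 6.44 * (yr - 2002), yr), 0.0, atol=1e-9)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=20))
    def test_residuals_orthogonal_to_year_and_idempotent(self, vals):
        yr = np.arange(len(vals), dtype=float)
        r = detrend(vals, yr)
        assert abs(np.cov(r, yr, bias=True)[0, 1]) < 1e-6 * max(np.std(vals), 1.0)
        assert np.allclose(detrend(r, yr), r, atol=1e-8)

    def test_constant_year_rejected(self):
        with pytest.raises(ValueError):
            detrend([1.0, 2.0, 3.0], [2002, 2002, 2002])


class TestCrossSectional:
    @staticmethod
    def _frame(slope=-6.44, noise=None, n=10):
        yr = np.arange(2002, 2002 + n, dtype=float)
        y = 200.0 + slope * (yr - 2002)
        if noise is not None:
            y = y + noise
        return pd.DataFrame(dict(year=yr, date=y))

    def test_noiseless_line_recovers_slope_exactly(self):
        tab, coefs, headline = fit_cross_sectional(self._frame())
        assert headline["slope"] == pytest.approx(-6.44, abs=1e-9)
        assert headline["year_beats_null"]

    def test_table_invariants(self):
        tab, _, _ = fit_cross_sectional(self._frame(noise=np.sin(np.arange(10))))
        assert tab["delta_aicc"].min() == 0.0
        assert (tab["aicc"].diff().dropna() >= 0).all()
        assert (tab["k"] < tab["n"] - 1).all()

    def test_ar1_likelihood_dominates_iid_on_any_data(self, rng):
        """The i.i.d. model is the rho=0 special case, so exact-ML AR(1) can
        never have a lower maximized likelihood."""
        tab, _, _ = fit_cross_sectional(self._frame(noise=rng.normal(0, 3, 10)))
        ll = tab.set_index("model")["loglik"]
        assert ll["year_ar1"] >= ll["year_iid"] - 1e-8
        assert ll["null_ar1"] >= ll["null_iid"] - 1e-8


def _lmm_frame(rng, n_birds=20, years=3, id_var=9.0, resid=4.0, trend=-5.0):
    rows = []
    for i in range(n_birds):
        b = rng.normal(0, np.sqrt(id_var))
        for j in range(years):
            y = 2002 + j
            rows.append(dict(ID=f"B{i}", year=float(y), age_class="adult" if i % 2 else "immature",
                             temp=rng.normal(12, 2), prec=rng.normal(20, 5),
                             greenup=rng.normal(90, 5),
                             date=150 + trend * (y - 2002) + b + rng.normal(0, np.sqrt(resid))))
    return pd.DataFrame(rows)


class TestLMM:
    def test_zero_variance_boundary_matches_ols_loglik(self, rng):
        frame = _lmm_frame(rng, id_var=0.0)
        m = fit_random_intercept(frame, ["year"], "date")
        X, _ = build_design(frame, ["year"])
        y = frame["date"].to_numpy()
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        ssr = float(((y - X @ beta) ** 2).sum())
        n = len(y)
        ols_llf = -0.5 * n * (np.log(2 * np.pi * ssr / n) + 1.0)
        assert abs(m.loglik - ols_llf) < 1e-6

    def test_candidate_set_structure_and_ranking(self, rng):
        frame = _lmm_frame(rng)
        tab, coefs, models = fit_lmm_set(frame, ["temp", "prec"], "date")
        assert tab["delta_aicc"].iloc[0] == 0.0
        assert set(tab["model"]) == {"year", "year+age", "year+temp", "year+age+temp",
                                     "year+prec", "year+age+prec",
                                     "year+age+temp+prec+temp:prec"}
        # a model containing year should dominate under a strong trend
        assert "year" in tab["model"].iloc[0]

    def test_duplicated_rows_change_se_not_coefficients(self, rng):
        """Pseudo-replication halves standard errors while leaving estimates
        alone — a misuse signature, not a feature."""
        frame = _lmm_frame(rng)
        m1 = fit_random_intercept(frame, ["year"], "date")
        m2 = fit_random_intercept(pd.concat([frame, frame], ignore_index=True),
                                  ["year"], "date")
        assert abs(m1.params["year"] - m2.params["year"]) < 1e-6
        assert m2.bse["year"] < 0.8 * m1.bse["year"]

    def test_too_small_frame_rejected(self, rng):
        frame = _lmm_frame(rng, n_birds=3)
        with pytest.raises(ValueError):
            fit_lmm_set(frame, ["temp"], "date")


class TestDetrendedModels:
    def test_ddate_orthogonal_to_year_by_construction(self, rng):
        frame = _lmm_frame(rng)
        frame["ddate"] = detrend(frame["date"], frame["year"])
        frame["dgreenup"] = detrend(frame["greenup"], frame["year"])
        assert abs(np.cov(frame["ddate"], frame["year"], bias=True)[0, 1]) < 1e-8
        tab, coefs, models = detrended_greenup_models(frame)
        assert set(tab["model"]) == {"1", "dgreenup", "dgreenup+age",
                                     "dgreenup+age+dgreenup:age"}
        assert tab["delta_aicc"].iloc[0] == 0.0
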