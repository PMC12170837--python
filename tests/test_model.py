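"""Conditional-Poisson fitter against closed forms and explicit-dummy fits."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from heatosa.basis import CrossBasisSpec, SplineSpec, cross_basis
from heatosa.model import (
    CaseTimeSeriesModel,
    assign_strata,
    build_design,
    fit_conditional_poisson,
    fit_subgroup,
)
from heatosa.synthetic import CohortConfig, NightlyPanel, simulate_cohort


def toy_panel(rng, n_users=4, n_days=60, start="2022-01-01"):
    dates = pd.date_range(start, periods=n_days, freq="D")
    rows = []
    for u in range(n_users):
        x = rng.normal(size=n_days)
        y = rng.binomial(1, 0.3, n_days)
        rows.append(pd.DataFrame({"user_id": u, "date": dates, "x": x, "osa": y}))
    return pd.concat(rows, ignore_index=True)


class TestStrata:
    def test_same_month_same_stratum(self):
        df = pd.DataFrame(
            {
                "user_id": [1, 1],
                "date": pd.to_datetime(["2022-01-03", "2022-01-28"]),
                "osa": [1.0, 0.0],
            }
        )
        idx = assign_strata(df)
        assert idx.codes[0] == idx.codes[1]

    def test_month_boundary_splits_strata(self):
        df = pd.DataFrame(
            {
                "user_id": [1, 1],
                "date": pd.to_datetime(["2022-01-31", "2022-02-01"]),
                "osa": [1.0, 1.0],
            }
        )
        idx = assign_strata(df)
        assert idx.codes[0] != idx.codes[1]

    def test_user_month_count(self):
        dates = pd.date_range("2022-01-01", "2022-03-31", freq="D")
        df = pd.concat(
            [
                pd.DataFrame({"user_id": u, "date": dates, "osa": 1.0})
                for u in range(3)
            ],
            ignore_index=True,
        )
        assert assign_strata(df).n_strata == 9

    def test_zero_event_strata_flagged_non_informative(self):
        df = pd.DataFrame(
            {
                "user_id": [1] * 4 + [2] * 4,
                "date": list(pd.date_range("2022-01-01", periods=4)) * 2,
                "osa": [1.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0],
            }
        )
        idx = assign_strata(df)
        assert idx.informative.tolist() == [True, False]


class TestDesign:
    def test_column_counting(self, rng):
        n = 400
        dates = pd.date_range("2021-06-01", periods=n // 2, freq="D")
        df = pd.DataFrame(
            {
                "user_id": np.repeat([0, 1], n // 2),
                "date": np.tile(dates, 2),
                "osa": rng.binomial(1, 0.3, n).astype(float),
                "tmean": rng.uniform(0, 30, n),
            }
        )
        for l in range(1, 5):
            df[f"tmean_lag{l}"] = rng.uniform(0, 30, n)
        covs = [
            "cloud_cover", "rel_humidity", "pressure",
            "precipitation", "wind_speed", "pm25", "extra",
        ]
        for c in covs:
            df[c] = rng.normal(size=n)
        panel = NightlyPanel(df)
        cb = cross_basis(panel.lag_matrix(), CrossBasisSpec(exposure=SplineSpec(df=4)))
        design = build_design(panel, cb, covariates=covs)
        # 20 cross-basis + 4 day-of-year + 6 day-of-week + 7 x 4 covariates
        assert design.matrix.shape[1] == 58
        assert len(design.groups["crossbasis"]) == 20

    def test_single_weekday_drops_dow_block(self, rng):
        dates = pd.date_range("2022-01-03", periods=30, freq="7D")  # all Mondays
        df = pd.DataFrame(
            {
                "user_id": 0,
                "date": dates,
                "osa": rng.binomial(1, 0.5, 30).astype(float),
                "tmean": rng.uniform(0, 30, 30),
            }
        )
        for l in range(1, 5):
            df[f"tmean_lag{l}"] = rng.uniform(0, 30, 30)
        panel = NightlyPanel(df)
        cb = cross_basis(panel.lag_matrix(), CrossBasisSpec(exposure=SplineSpec(df=4)))
        design = build_design(panel, cb)
        assert "dow" not in design.groups


class TestConditionalPoisson:
    def test_single_stratum_closed_form(self):
        # one stratum: 10 nights at x=1 with 3 events, 10 at x=0 with 1 event
        y = np.r_[np.ones(3), np.zeros(7), np.ones(1), np.zeros(9)]
        x = np.r_[np.ones(10), np.zeros(10)].reshape(-1, 1)
        strata = np.zeros(20, dtype=int)
        res = fit_conditional_poisson(y, x, strata)
        assert res.params[0] == pytest.approx(np.log(3.0), abs=1e-8)

    def test_matches_explicit_dummy_poisson(self, rng):
        df = toy_panel(rng)
        strata = assign_strata(df)
        X = df[["x"]].to_numpy()
        res = fit_conditional_poisson(df["osa"].to_numpy(float), X, strata.codes)
        dummies = pd.get_dummies(pd.Series(strata.codes), dtype=float).to_numpy()
        keep = strata.informative[strata.codes]
        full = np.c_[X, dummies][keep]
        glm = sm.GLM(
            df["osa"].to_numpy(float)[keep], full, family=sm.families.Poisson()
        ).fit()
        assert res.params[0] == pytest.approx(glm.params[0], abs=1e-6)
        assert res.cov_params[0, 0] == pytest.approx(
            np.asarray(glm.cov_params())[0, 0], rel=1e-4
        )

    def test_dummy_oracle_many_strata_many_columns(self, rng):
        df = toy_panel(rng, n_users=6, n_days=90)  # 18 strata
        df["z"] = rng.normal(size=len(df))
        strata = assign_strata(df)
        X = df[["x", "z"]].to_numpy()
        res = fit_conditional_poisson(df["osa"].to_numpy(float), X, strata.codes)
        dummies = pd.get_dummies(pd.Series(strata.codes), dtype=float).to_numpy()
        keep = strata.informative[strata.codes]
        glm = sm.GLM(
            df["osa"].to_numpy(float)[keep],
            np.c_[X, dummies][keep],
            family=sm.families.Poisson(),
        ).fit()
        np.testing.assert_allclose(res.params, glm.params[:2], atol=1e-6)

    def test_zero_event_stratum_leaves_estimates_unchanged(self, rng):
        df = toy_panel(rng)
        strata = assign_strata(df)
        y = df["osa"].to_numpy(float)
        X = df[["x"]].to_numpy()
        base = fit_conditional_poisson(y, X, strata.codes)
        y2 = np.r_[y, np.zeros(30)]
        X2 = np.r_[X, rng.normal(size=(30, 1))]
        s2 = np.r_[strata.codes, np.full(30, strata.codes.max() + 1)]
        withnull = fit_conditional_poisson(y2, X2, s2)
        np.testing.assert_allclose(base.params, withnull.params, atol=1e-10)
        assert withnull.n_dropped_strata == base.n_dropped_strata + 1

    def test_missing_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_conditional_poisson(
                np.array([1.0, np.nan]), np.ones((2, 1)), np.zeros(2, int)
            )


class TestModelAPI:
    def test_translation_equivariance(self, weather, calibrated_config):
        cfg = CohortConfig(
            **{
                **calibrated_config.__dict__,
                "n_users": 60,
                "nights_per_user": 200,
                "seed": 23,
            }
        )
        panel = simulate_cohort(weather, cfg)
        res = CaseTimeSeriesModel(panel, covariates=()).fit()
        rr = res.rr_contrast(27.3, 6.4)

        shifted = panel.data.copy()
        shift = 100.0
        for col in panel.lag_columns:
            shifted[col] = shifted[col] + shift
        spec0 = res.model.crossbasis_spec
        spec_shift = CrossBasisSpec(
            exposure=SplineSpec(
                knots=tuple(k + shift for k in spec0.exposure.knots),
                boundary=(
                    spec0.exposure.boundary[0] + shift,
                    spec0.exposure.boundary[1] + shift,
                ),
            ),
            max_lag=spec0.max_lag,
            reference=spec0.reference + shift,
        )
        panel2 = NightlyPanel(shifted, exposure=panel.exposure, max_lag=panel.max_lag)
        res2 = CaseTimeSeriesModel(panel2, crossbasis=spec_shift, covariates=()).fit()
        rr2 = res2.rr_contrast(27.3 + shift, 6.4 + shift)
        assert rr2.rr == pytest.approx(rr.rr, rel=1e-6)
        assert rr2.ci_low == pytest.approx(rr.ci_low, rel=1e-5)

    def test_summary_mentions_convergence_and_strata(self, panel):
        res = CaseTimeSeriesModel(panel, covariates=()).fit()
        text = res.summary()
        assert "strata" in text and "converged" in text
        assert res.converged

    def test_from_dataframe_constructor(self, panel):
        model = CaseTimeSeriesModel.from_dataframe(panel.data)
        assert model.crossbasis_spec.reference is not None


class TestSubgroups:
    def test_single_level_equals_global_fit(self, weather):
        cfg = CohortConfig(n_users=40, nights_per_user=150, seed=31)
        panel = simulate_cohort(weather, cfg)
        panel.data["grp"] = "all"
        sub = fit_subgroup(panel, "grp", covariates=(), min_users=1)
        glob = CaseTimeSeriesModel(panel, covariates=()).fit()
        np.testing.assert_allclose(
            sub["all"].fit.params, glob.fit.params, atol=1e-10
        )

    def test_distinct_truths_ordered(self, weather):
        base = CohortConfig.calibrated(
            weather, rr=1.0, rr_severe=1.0, n_users=150, nights_per_user=365, seed=37
        )
        strong = CohortConfig.calibrated(
            weather, rr=2.5, rr_severe=2.5, n_users=150, nights_per_user=365, seed=38
        )
        p_null = simulate_cohort(weather, base).data
        p_strong = simulate_cohort(weather, strong).data
        p_strong["user_id"] += 1000
        p_null["grp"], p_strong["grp"] = "null", "strong"
        merged = NightlyPanel(
            pd.concat([p_null, p_strong], ignore_index=True), max_lag=4
        )
        fits = fit_subgroup(merged, "grp", covariates=(), min_users=5)
        rr = {g: f.rr_contrast(27.3, 6.4).rr for g, f in fits.items()}
        assert rr["strong"] > rr["null"]
        assert rr["null"] == pytest.approx(1.0, abs=0.25)

    def test_small_group_skipped(self, weather):
        cfg = CohortConfig(n_users=30, nights_per_user=100, seed=41)
        panel = simulate_cohort(weather, cfg)
        panel.data["grp"] = np.where(panel.data["user_id"] < 2, "tiny", "rest")
        fits = fit_subgroup(panel, "grp", covariates=(), min_users=5)
        assert fits["tiny"] is None and fits["rest"] is not None
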