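"""Derived covariates: piecewise BMI, rank-for-age, adversity, DSI,
comparison clocks."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from methclock.covariates import (
    PiecewiseRegressor,
    compute_dsi,
    cumulative_early_adversity,
    dyad_effort,
    dyadic_residuals,
    fit_comparison_clock,
    fit_piecewise_bmi,
    rank_for_age,
)


def hinge(x, bp, b0, s1, s2):
    return b0 + s1 * x + (s2 - s1) * np.maximum(x - bp, 0.0)


class TestPiecewise:
    def test_noiseless_hinge_recovered(self, rng):
        ages = pd.Series(np.linspace(0.5, 24.5, 60))
        bmi = pd.Series(hinge(ages.to_numpy(), 8.0, 30.0, 2.0, -1.0))
        fit = fit_piecewise_bmi(bmi, ages, sex="M")
        assert fit.breakpoint == pytest.approx(8.0, abs=0.1)
        assert fit.left_slope == pytest.approx(2.0, abs=1e-6)
        assert fit.right_slope == pytest.approx(-1.0, abs=1e-6)
        assert fit.residuals.abs().max() < 1e-8

    def test_pure_linear_degenerate(self):
        ages = pd.Series(np.linspace(1, 20, 30))
        bmi = pd.Series(1.5 * ages + 3)
        fit = fit_piecewise_bmi(bmi, ages, sex="F")
        assert fit.left_slope == pytest.approx(fit.right_slope, abs=1e-6)

    def test_noisy_hinge_matches_gridsearch_oracle(self, rng):
        ages = pd.Series(rng.uniform(0.5, 24.5, 80))
        bmi = pd.Series(hinge(ages.to_numpy(), 10.0, 28.0, 1.8, -0.6)
                        + rng.normal(0, 0.8, 80))
        fit = fit_piecewise_bmi(bmi, ages, sex="F")
        assert abs(fit.breakpoint - 10.0) <= 1.0
        # oracle: refit at the found breakpoint by plain least squares
        x = ages.to_numpy()
        design = np.column_stack([np.ones_like(x), x, np.maximum(x - fit.breakpoint, 0)])
        beta, *_ = np.linalg.lstsq(design, bmi.to_numpy(), rcond=None)
        assert fit.residuals.to_numpy() == pytest.approx(
            bmi.to_numpy() - design @ beta, abs=1e-8
        )

    def test_residuals_uncorrelated_with_age(self, rng):
        ages = pd.Series(rng.uniform(0.5, 24.5, 150))
        bmi = pd.Series(hinge(ages.to_numpy(), 8.0, 30.0, 2.0, -0.5)
                        + rng.normal(0, 1.0, 150))
        fit = fit_piecewise_bmi(bmi, ages, sex="M")
        assert abs(np.corrcoef(fit.residuals, ages)[0, 1]) < 0.05
        assert fit.residuals.sum() == pytest.approx(0.0, abs=1e-6)

    def test_degenerate_side_rejected(self):
        est = PiecewiseRegressor()
        with pytest.raises(ValueError):
            est.fit(np.full(10, 5.0), np.arange(10.0))


class TestRankForAge:
    def test_exact_quadratic_zero_residuals(self):
        ages = pd.Series(np.linspace(1, 20, 12))
        ranks = 3 + 0.5 * ages - 0.02 * ages**2
        assert rank_for_age(ranks, ages).abs().max() < 1e-9

    def test_constant_rank_zero_residuals(self):
        ages = pd.Series([1.0, 4.0, 9.0, 16.0])
        assert rank_for_age(pd.Series([5.0] * 4), ages).eq(0).all()

    def test_matches_closed_form_ols(self, rng):
        ages = pd.Series(rng.uniform(2, 20, 8))
        ranks = pd.Series(rng.integers(1, 20, 8).astype(float))
        got = rank_for_age(ranks, ages)
        X = sm.add_constant(np.column_stack([ages, ages**2]))
        beta = np.linalg.solve(X.T @ X, X.T @ ranks.to_numpy())
        assert got.to_numpy() == pytest.approx(ranks.to_numpy() - X @ beta, abs=1e-8)
        # orthogonality to the design
        assert got @ ages == pytest.approx(0.0, abs=1e-6)
        assert got @ ages**2 == pytest.approx(0.0, abs=1e-4)


class TestAdversity:
    def test_rainfall_threshold(self):
        df = pd.DataFrame(
            {
                "first_year_rainfall_mm": [150.0, 200.0, 201.0],
                "adv_low_maternal_rank": [0, 0, 0],
                "adv_sibling": [0, 0, 0],
                "adv_large_group": [0, 0, 0],
                "adv_maternal_loss": [0, 0, 0],
            }
        )
        assert cumulative_early_adversity(df).tolist() == [1, 1, 0]

    @pytest.mark.parametrize("value,expected", [(0, 0), (1, 5)])
    def test_extremes(self, value, expected):
        df = pd.DataFrame({c: [value] for c in (
            "adv_drought", "adv_low_maternal_rank", "adv_sibling",
            "adv_large_group", "adv_maternal_loss")})
        assert cumulative_early_adversity(df).iloc[0] == expected

    def test_missing_indicator_flags_record(self):
        df = pd.DataFrame({
            "adv_drought": [1, np.nan],
            "adv_low_maternal_rank": [0, 0],
            "adv_sibling": [0, 1],
            "adv_large_group": [0, 0],
            "adv_maternal_loss": [0, 0],
        })
        score = cumulative_early_adversity(df)
        assert score.iloc[0] == 1 and np.isnan(score.iloc[1])


def grooming_frame(rows):
    return pd.DataFrame(rows, columns=["female1", "female2", "year",
                                       "coresidence_days", "focal_samples",
                                       "mean_group_females", "grooming_count"])


class TestDSI:
    def test_identical_dyads_give_zero(self):
        rows = [("a", x, 2004, 365, 100, 10.0, 20) for x in "bcd"]
        g = grooming_frame(rows)
        val, complete = compute_dsi(g, "a", "2005-01-01")
        assert val == 0.0 and complete

    def test_scale_invariance_of_grooming_counts(self):
        rows = [("a", "b", 2004, 365, 80, 8.0, 10),
                ("a", "c", 2004, 365, 120, 8.0, 30),
                ("a", "d", 2004, 300, 60, 9.0, 5),
                ("b", "c", 2004, 365, 90, 8.0, 22),
                ("b", "d", 2004, 350, 110, 8.5, 14),
                ("c", "d", 2004, 365, 100, 8.0, 9)]
        g1 = grooming_frame(rows)
        g2 = g1.copy()
        g2["grooming_count"] *= 2
        v1, _ = compute_dsi(g1, "a", "2005-01-01")
        v2, _ = compute_dsi(g2, "a", "2005-01-01")
        assert v1 == pytest.approx(v2, abs=1e-10)

    def test_effort_unit_invariance(self):
        rows = [("a", "b", 2004, 365, 80, 8.0, 10),
                ("a", "c", 2004, 365, 120, 8.0, 30),
                ("b", "c", 2004, 365, 90, 8.0, 22)]
        g = grooming_frame(rows)
        r1 = dyadic_residuals(g)["dsi_residual"]
        g2 = g.copy()
        g2["mean_group_females"] *= 10  # uniform effort rescale
        r2 = dyadic_residuals(g2)["dsi_residual"]
        assert r1.to_numpy() == pytest.approx(r2.to_numpy(), abs=1e-10)

    def test_matches_hand_computed_loglog_ols(self):
        rows = [("a", "b", 2004, 365, 80, 8.0, 10),
                ("a", "c", 2004, 365, 120, 8.0, 30),
                ("a", "d", 2004, 300, 60, 9.0, 5),
                ("b", "c", 2004, 365, 90, 8.0, 22),
                ("b", "d", 2004, 350, 110, 8.5, 14),
                ("c", "d", 2004, 365, 100, 8.0, 9)]
        g = grooming_frame(rows)
        R = g["grooming_count"] / g["coresidence_days"]
        E = g["focal_samples"] / (g["coresidence_days"] * g["mean_group_females"])
        X = sm.add_constant(np.log(E.to_numpy()))
        beta = np.linalg.solve(X.T @ X, X.T @ np.log(R.to_numpy()))
        resid = np.log(R.to_numpy()) - X @ beta
        z = (resid - resid.mean()) / resid.std(ddof=1)
        mine = z[:3]  # dyads involving 'a'
        expected = np.sort(mine)[::-1][:3].mean()
        got, complete = compute_dsi(g, "a", "2005-01-01")
        assert got == pytest.approx(expected, abs=1e-10)
        assert complete

    def test_no_partner_in_window(self):
        g = grooming_frame([("b", "c", 1990, 365, 100, 8.0, 5),
                            ("b", "d", 1990, 365, 100, 8.0, 9)])
        val, complete = compute_dsi(g, "a", "2005-01-01")
        assert np.isnan(val) and not complete

    def test_effort_modes(self):
        g = grooming_frame([("a", "b", 2004, 100, 50, 5.0, 3)])
        assert dyad_effort(g).iloc[0] == pytest.approx(50 / (100 * 5.0))
        assert dyad_effort(g, mode="product").iloc[0] == pytest.approx(100 * 50 * 5.0)
        g0 = g.copy()
        g0["coresidence_days"] = 0
        with pytest.raises(ValueError):
            dyad_effort(g0)


class TestComparisonClock:
    def test_exact_linear_feature_perfect_loo(self):
        idx = [f"s{i}" for i in range(10)]
        ages = pd.Series(np.linspace(2, 20, 10), index=idx)
        feats = pd.DataFrame({
            "pde_m1": (ages - 1.0) / 2.0,
            "pde_m2": np.zeros(10) + np.linspace(0, 1, 10) * 0,
        }, index=idx)
        feats["pde_m2"] = np.linspace(5, 6, 10)  # non-constant nuisance
        preds, metrics = fit_comparison_clock(feats[["pde_m1"]], ages, kind="linear")
        assert metrics.mad == pytest.approx(0.0, abs=1e-8)

    def test_proportions_summing_to_one_handled(self, rng):
        idx = [f"s{i}" for i in range(12)]
        ages = pd.Series(rng.uniform(1, 20, 12), index=idx)
        p = rng.dirichlet(np.ones(3), size=12)
        feats = pd.DataFrame(p, columns=["t_cells", "b_cells", "monocytes"], index=idx)
        preds, metrics = fit_comparison_clock(feats, ages, kind="linear")
        assert len(preds) == 12  # drop-one-category let the fit succeed

    def test_constant_feature_named_in_error(self, rng):
        idx = [f"s{i}" for i in range(8)]
        ages = pd.Series(rng.uniform(1, 20, 8), index=idx)
        feats = pd.DataFrame({"pde_m1": np.ones(8)}, index=idx)
        with pytest.raises(ValueError, match="pde_m1"):
            fit_comparison_clock(feats, ages, kind="linear")

    def test_loo_matches_per_fold_refit_oracle(self, rng):
        idx = [f"s{i}" for i in range(14)]
        ages = pd.Series(rng.uniform(1, 22, 14), index=idx)
        feats = pd.DataFrame({
            "f1": 0.5 * ages + rng.normal(0, 1, 14),
            "f2": rng.normal(size=14),
        }, index=idx)
        preds, _ = fit_comparison_clock(feats, ages, kind="linear")
        for left_out in idx:
            tr = [s for s in idx if s != left_out]
            X = sm.add_constant(feats.loc[tr].to_numpy())
            beta = np.linalg.lstsq(X, ages.loc[tr].to_numpy(), rcond=None)[0]
            expected = float(np.r_[1.0, feats.loc[left_out].to_numpy()] @ beta)
            assert preds.loc[left_out, "predicted_age"] == pytest.approx(expected, abs=1e-8)
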