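"""Derived socio-environmental covariates.

Implements the covariates the age-acceleration models consume: age-adjusted
BMI from sex-specific continuous two-segment ("hinge") regressions of BMI on
age; rank-for-age as quadratic-in-age rank residuals; the cumulative
early-adversity count over five binary conditions; the female dyadic
sociality index (DSI_F) from grooming records corrected for observer effort;
and leave-one-out comparison clocks built from non-methylation age markers
(molar dentine exposure, BMI, blood cell composition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .metrics import PredictionMetrics, prediction_metrics

__all__ = [
    "PiecewiseFit",
    "PiecewiseRegressor",
    "fit_piecewise_bmi",
    "rank_for_age",
    "cumulative_early_adversity",
    "dyad_effort",
    "dyadic_residuals",
    "compute_dsi",
    "fit_comparison_clock",
]

ADVERSITY_INDICATORS = (
    "adv_drought",
    "adv_low_maternal_rank",
    "adv_sibling",
    "adv_large_group",
    "adv_maternal_loss",
)

#: first-year rainfall at or below this (mm) counts as early-life drought
DROUGHT_RAINFALL_MM = 200.0
#: a younger sibling born within this many years counts as close-in-age
SIBLING_GAP_YEARS = 1.5
#: maternal death before this age (years) counts as maternal loss
MATERNAL_LOSS_AGE = 4.0


@dataclass
class PiecewiseFit:
    """Continuous two-segment linear fit of y on x."""

    breakpoint: float
    intercept: float
    left_slope: float
    right_slope: float
    residuals: pd.Series
    fitted: pd.Series

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (
            self.intercept
            + self.left_slope * x
            + (self.right_slope - self.left_slope) * np.maximum(x - self.breakpoint, 0.0)
        )


class PiecewiseRegressor(RegressorMixin, BaseEstimator):
    """Hinge regression with the breakpoint profiled over a fixed grid.

    Candidate breakpoints lie on a ``grid_step``-spaced grid within the data
    range (each side must hold at least two observations); the breakpoint
    minimizing the residual sum of squares wins, with exact ties broken
    toward ``anchor`` (8 years for male baboon BMI, 10 for female).  The grid
    profile makes the fit deterministic and directly checkable against a
    brute-force oracle.
    """

    def __init__(self, anchor: float = 8.0, grid_step: float = 0.1):
        self.anchor = anchor
        self.grid_step = grid_step

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float)
        if x.size != y.size or x.size < 6:
            raise ValueError("need at least 6 (x, y) observations")
        xs = np.sort(x)
        lo, hi = xs[1], xs[-2]  # >= 2 points on each side
        if lo >= hi:
            raise ValueError("all ages on one side of every candidate breakpoint")
        grid = np.arange(np.ceil(lo / self.grid_step), np.floor(hi / self.grid_step) + 1)
        grid = grid * self.grid_step
        if grid.size == 0:
            grid = np.array([(lo + hi) / 2.0])

        best = None
        for bp in grid:
            design = np.column_stack([np.ones_like(x), x, np.maximum(x - bp, 0.0)])
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            sse = float(np.sum((y - design @ beta) ** 2))
            key = (round(sse, 12), abs(bp - self.anchor))
            if best is None or key < best[0]:
                best = (key, bp, beta)
        _, bp, beta = best
        self.breakpoint_ = float(bp)
        self.intercept_ = float(beta[0])
        self.left_slope_ = float(beta[1])
        self.right_slope_ = float(beta[1] + beta[2])
        return self

    def predict(self, X):
        check_is_fitted(self, "breakpoint_")
        x = np.asarray(X, dtype=float).reshape(-1)
        return (
            self.intercept_
            + self.left_slope_ * x
            + (self.right_slope_ - self.left_slope_) * np.maximum(x - self.breakpoint_, 0.0)
        )


def fit_piecewise_bmi(
    bmi: pd.Series, ages: pd.Series, sex: str = "M", grid_step: float = 0.1
) -> PiecewiseFit:
    """Sex-specific hinge regression of BMI on age; the residuals are the
    age-adjusted BMI covariate."""
    anchor = 8.0 if sex.upper().startswith("M") else 10.0
    est = PiecewiseRegressor(anchor=anchor, grid_step=grid_step)
    est.fit(ages.to_numpy(float), bmi.to_numpy(float))
    fitted = pd.Series(est.predict(ages.to_numpy(float)), index=bmi.index, name="fitted_bmi")
    return PiecewiseFit(
        breakpoint=est.breakpoint_,
        intercept=est.intercept_,
        left_slope=est.left_slope_,
        right_slope=est.right_slope_,
        residuals=(bmi - fitted).rename("age_adjusted_bmi"),
        fitted=fitted,
    )


def rank_for_age(ranks: pd.Series, ages: pd.Series) -> pd.Series:
    """Residuals of ordinal rank regressed on age and age² (mean zero).

    Captures holding a better or worse rank than expected for one's age.
    Constant rank yields all-zero residuals rather than an error.
    """
    if len(ranks) < 4:
        raise ValueError("need at least 4 samples")
    a = ages.to_numpy(float)
    if np.ptp(a) == 0:
        raise ValueError("constant age")
    r = ranks.to_numpy(float)
    if np.ptp(r) == 0:
        return pd.Series(np.zeros(len(ranks)), index=ranks.index, name="rank_for_age")
    design = sm.add_constant(np.column_stack([a, a**2]))
    resid = sm.OLS(r, design).fit().resid
    return pd.Series(resid, index=ranks.index, name="rank_for_age")


def cumulative_early_adversity(indicators: pd.DataFrame) -> pd.Series:
    """Sum of the five binary early-adversity conditions per individual.

    Accepts either the binary indicator columns directly (``adv_*``) or raw
    measurements, which are then thresholded: first-year rainfall <= 200 mm
    (drought); maternal rank in the lowest (numerically largest) quartile of
    the dataset; a younger sibling born < 1.5 years later; group size at
    birth in the top quartile; maternal death before age 4.  Individuals with
    any unresolvable indicator get a missing score (excluded from
    complete-case models downstream).
    """
    df = pd.DataFrame(index=indicators.index)
    cols = indicators.columns
    if "adv_drought" in cols:
        df["adv_drought"] = indicators["adv_drought"]
    elif "first_year_rainfall_mm" in cols:
        df["adv_drought"] = (indicators["first_year_rainfall_mm"] <= DROUGHT_RAINFALL_MM).where(
            indicators["first_year_rainfall_mm"].notna()
        )
    if "adv_low_maternal_rank" in cols:
        df["adv_low_maternal_rank"] = indicators["adv_low_maternal_rank"]
    elif "maternal_rank" in cols:
        mr = indicators["maternal_rank"]
        df["adv_low_maternal_rank"] = (mr >= mr.quantile(0.75)).where(mr.notna())
    if "adv_sibling" in cols:
        df["adv_sibling"] = indicators["adv_sibling"]
    elif "sibling_gap_years" in cols:
        gap = indicators["sibling_gap_years"]
        df["adv_sibling"] = (gap < SIBLING_GAP_YEARS).where(gap.notna())
    if "adv_large_group" in cols:
        df["adv_large_group"] = indicators["adv_large_group"]
    elif "group_size_at_birth" in cols:
        gs = indicators["group_size_at_birth"]
        df["adv_large_group"] = (gs >= gs.quantile(0.75)).where(gs.notna())
    if "adv_maternal_loss" in cols:
        df["adv_maternal_loss"] = indicators["adv_maternal_loss"]
    elif "maternal_death_age" in cols:
        # NaN death age = mother survived past the window, not missing data
        df["adv_maternal_loss"] = (
            indicators["maternal_death_age"] < MATERNAL_LOSS_AGE
        ).fillna(False)
    missing = [c for c in ADVERSITY_INDICATORS if c not in df.columns]
    if missing:
        raise ValueError(f"cannot resolve adversity indicators: {missing}")
    score = df[list(ADVERSITY_INDICATORS)].astype(float).sum(axis=1, skipna=False)
    return score.rename("cumulative_adversity")


def dyad_effort(
    records: pd.DataFrame, mode: str = "per_day_per_female"
) -> pd.Series:
    """Observer effort E_d,y per dyad-year record.

    The default, ``per_day_per_female``, is focal samples per coresident-day
    per female, ``s / (c * f)`` — smaller groups receive more observer effort
    per dyad.  ``product`` (``c * s * f``) is offered as an alternative
    combination of the same three components.
    """
    c = records["coresidence_days"].to_numpy(float)
    s = records["focal_samples"].to_numpy(float)
    f = records["mean_group_females"].to_numpy(float)
    if (c <= 0).any():
        raise ValueError("coresidence_days must be positive for included records")
    if mode == "per_day_per_female":
        e = s / (c * f)
    elif mode == "product":
        e = c * s * f
    else:
        raise ValueError(f"unknown effort mode {mode!r}")
    return pd.Series(e, index=records.index, name="effort")


def dyadic_residuals(records: pd.DataFrame, effort_mode: str = "per_day_per_female") -> pd.DataFrame:
    """Z-scored residuals of log grooming rate on log observer effort.

    R_d,y is the grooming count divided by coresidence days.  Dyad-years with
    zero grooming (or zero effort) are excluded from the log-log fit.
    Residuals are z-scored globally across dyad-years; a zero-variance
    residual vector z-scores to 0 by convention.
    """
    rec = records.copy()
    rec["rate"] = rec["grooming_count"] / rec["coresidence_days"]
    rec["effort"] = dyad_effort(rec, mode=effort_mode)
    use = rec[(rec["rate"] > 0) & (rec["effort"] > 0)].copy()
    if len(use) < 2:
        raise ValueError("need at least 2 dyad-years with nonzero grooming")
    fit = sm.OLS(np.log(use["rate"]), sm.add_constant(np.log(use["effort"]))).fit()
    resid = fit.resid
    sd = resid.std(ddof=1)
    use["dsi_residual"] = 0.0 if (not np.isfinite(sd) or sd == 0) else (resid - resid.mean()) / sd
    return use


def compute_dsi(
    records: pd.DataFrame,
    focal: str,
    sample_date: str | pd.Timestamp,
    top_n: int = 3,
    effort_mode: str = "per_day_per_female",
) -> tuple[float, bool]:
    """DSI_F: mean bond strength with the focal female's top partners.

    Residual grooming strengths are computed population-wide by
    :func:`dyadic_residuals`; the focal female's dyad-years whose calendar
    year overlaps the 365 days before ``sample_date`` are collapsed to one
    residual per partner (mean), and DSI_F is the mean of the ``top_n``
    largest.  Returns ``(value, complete)`` where ``complete`` is False when
    fewer than ``top_n`` partners were available; no partner in the window
    yields ``(nan, False)``.
    """
    resid = dyadic_residuals(records, effort_mode=effort_mode)
    date = pd.Timestamp(sample_date)
    window_years = {(date - pd.Timedelta(days=365)).year, date.year}
    mine = resid[
        ((resid["female1"] == focal) | (resid["female2"] == focal))
        & resid["year"].isin(window_years)
    ].copy()
    if mine.empty:
        return float("nan"), False
    partner = np.where(mine["female1"] == focal, mine["female2"], mine["female1"])
    per_partner = mine.groupby(partner)["dsi_residual"].mean().sort_values(ascending=False)
    top = per_partner.head(top_n)
    return float(top.mean()), len(per_partner) >= top_n


def _drop_collinear(X: pd.DataFrame) -> pd.DataFrame:
    """Drop trailing columns until the design (with intercept) is full rank.

    Raises on constant columns, naming the feature; silently drops one
    category of a proportion set that sums to a constant.
    """
    for col in X.columns:
        if np.ptp(X[col].to_numpy(float)) == 0:
            raise ValueError(f"feature {col!r} is constant")
    cols = list(X.columns)
    while cols:
        design = np.column_stack([np.ones(len(X))] + [X[c].to_numpy(float) for c in cols])
        if np.linalg.matrix_rank(design) == design.shape[1]:
            break
        cols = cols[:-1]
    if not cols:
        raise ValueError("no linearly independent features remain")
    return X[cols]


def fit_comparison_clock(
    features: pd.DataFrame,
    ages: pd.Series,
    kind: str = "linear",
    sex: str = "M",
) -> tuple[pd.DataFrame, PredictionMetrics]:
    """Leave-one-out age predictions from a non-methylation marker table.

    ``kind="linear"`` regresses age on the feature columns jointly (dentine
    exposure per molar, or blood cell proportions with one redundant category
    dropped).  ``kind="piecewise"`` handles BMI: within each fold a
    sex-specific hinge model of BMI on age is inverted by nearest fitted
    value to predict age.  Returns a prediction table comparable to the
    methylation clock's, plus its metrics.
    """
    if len(features) < 6:
        raise ValueError("need at least 6 samples")
    ages = ages.reindex(features.index)
    preds = {}
    if kind == "linear":
        X = _drop_collinear(features)
        for left_out in X.index:
            tr = X.index.drop(left_out)
            design = sm.add_constant(X.loc[tr].to_numpy(float))
            fit = sm.OLS(ages.loc[tr].to_numpy(float), design).fit()
            row = np.concatenate([[1.0], X.loc[left_out].to_numpy(float)])
            preds[left_out] = float(row @ fit.params)
    elif kind == "piecewise":
        bmi = features.iloc[:, 0]
        grid = np.arange(0.0, 30.0, 0.05)
        for left_out in bmi.index:
            tr = bmi.index.drop(left_out)
            pw = fit_piecewise_bmi(bmi.loc[tr], ages.loc[tr], sex=sex)
            curve = pw.predict(grid)
            preds[left_out] = float(grid[np.argmin(np.abs(curve - bmi.loc[left_out]))])
    else:
        raise ValueError(f"unknown comparison clock kind {kind!r}")
    out = pd.DataFrame({"age": ages, "predicted_age": pd.Series(preds)})
    out["delta_age"] = out["predicted_age"] - out["age"]
    return out, prediction_metrics(out)
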