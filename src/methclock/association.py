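"""Sex-specific models of age acceleration against socio-environmental
covariates, and within-male longitudinal rank analyses.

Δ_age (predicted minus chronological age) is modeled by OLS against dominance
rank at sampling, cumulative early adversity, age-adjusted BMI, and
chronological age (which absorbs the clock's compression of young vs. old
predictions); females additionally include social bond strength (DSI_F).
Longitudinal analyses compare relative epigenetic age within repeat-sampled
males across rank changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "DeltaAgeModelResult",
    "fit_delta_age_model",
    "paired_rank_contrast",
    "PairedContrast",
    "longitudinal_change_model",
    "select_longitudinal_pairs",
    "residual_adjust",
]

FEMALE_COVARIATES = ("rank", "cumulative_adversity", "age_adjusted_bmi", "dsi", "age")
MALE_COVARIATES = ("rank", "cumulative_adversity", "age_adjusted_bmi", "age")


@dataclass
class DeltaAgeModelResult:
    """Per-covariate OLS estimates for one sex's Δ_age model."""

    sex: str
    table: pd.DataFrame  # coef, se, p per covariate (+ Intercept)
    n: int
    dropped_incomplete: int
    condition_number: float

    def coef(self, name: str) -> float:
        return float(self.table.loc[name, "coef"])

    def conf_int(self, name: str, level: float = 0.95) -> tuple[float, float]:
        row = self.table.loc[name]
        tcrit = stats.t.ppf(0.5 + level / 2.0, self.n - len(self.table))
        return float(row["coef"] - tcrit * row["se"]), float(row["coef"] + tcrit * row["se"])


def fit_delta_age_model(
    data: pd.DataFrame,
    sex: str,
    covariates: tuple[str, ...] | None = None,
    extra_covariates: tuple[str, ...] = (),
) -> DeltaAgeModelResult:
    """Complete-case OLS of Δ_age on the sex-specific covariate set.

    ``data`` holds one row per sample with ``delta_age``, ``sex`` and the
    covariate columns.  Chronological age is always part of the default sets.
    ``extra_covariates`` supports the robustness variants (read depth,
    conversion rate, batch).  Rows with any missing covariate are dropped and
    counted; the reported n is the complete-case count.
    """
    if covariates is None:
        covariates = FEMALE_COVARIATES if sex.upper().startswith("F") else MALE_COVARIATES
    covariates = tuple(covariates) + tuple(extra_covariates)
    sub = data[data["sex"] == sex] if "sex" in data.columns else data
    cols = ["delta_age", *covariates]
    missing_cols = [c for c in cols if c not in sub.columns]
    if missing_cols:
        raise ValueError(f"missing columns: {missing_cols}")
    complete = sub[cols].dropna()
    dropped = len(sub) - len(complete)
    if len(complete) < len(covariates) + 2:
        raise ValueError("too few complete cases for the covariate set")
    X = sm.add_constant(complete[list(covariates)].astype(float))
    fit = sm.OLS(complete["delta_age"].astype(float), X).fit()
    table = pd.DataFrame({"coef": fit.params, "se": fit.bse, "p": fit.pvalues})
    return DeltaAgeModelResult(
        sex=sex,
        table=table,
        n=len(complete),
        dropped_incomplete=dropped,
        condition_number=float(np.linalg.cond(X.to_numpy(float))),
    )


@dataclass
class PairedContrast:
    t: float
    p: float
    n: int
    mean_difference: float
    degenerate: bool = False


def paired_rank_contrast(higher: pd.Series | np.ndarray, lower: pd.Series | np.ndarray) -> PairedContrast:
    """Two-sided paired t-test of relative epigenetic age at the higher- vs
    lower-rank sample of each repeat-sampled male.

    Zero-variance differences are degenerate: all-zero differences give
    t = 0, p = 1; a constant nonzero difference gives an infinite t (flagged).
    """
    hi = np.asarray(higher, dtype=float)
    lo = np.asarray(lower, dtype=float)
    if hi.size != lo.size or hi.size < 2:
        raise ValueError("need at least 2 pairs")
    d = hi - lo
    if np.ptp(d) == 0:
        if d[0] == 0:
            return PairedContrast(t=0.0, p=1.0, n=d.size, mean_difference=0.0, degenerate=True)
        t = np.inf if d[0] > 0 else -np.inf
        return PairedContrast(t=t, p=0.0, n=d.size, mean_difference=float(d.mean()), degenerate=True)
    res = stats.ttest_rel(hi, lo)
    return PairedContrast(
        t=float(res.statistic), p=float(res.pvalue), n=d.size, mean_difference=float(d.mean())
    )


def select_longitudinal_pairs(samples: pd.DataFrame, required: tuple[str, ...] = ()) -> pd.DataFrame:
    """Pick two samples per individual for longitudinal contrasts.

    For individuals with three or more samples, the two farthest apart in age
    are used, unless one of them is missing a required covariate, in which
    case the earliest complete pair is taken instead.  Returns rows indexed
    by individual with ``first`` and ``second`` sample labels (ordered in
    time).
    """
    rows = []
    for ind, grp in samples.groupby("individual_id"):
        grp = grp.sort_values("age")
        if len(grp) < 2:
            continue
        cand = [grp.index[0], grp.index[-1]]
        if required and grp.loc[cand, list(required)].isna().any().any():
            complete = grp.dropna(subset=list(required))
            if len(complete) < 2:
                continue
            cand = [complete.index[0], complete.index[1]]
        rows.append((ind, cand[0], cand[1]))
    return pd.DataFrame(rows, columns=["individual_id", "first", "second"]).set_index(
        "individual_id"
    )


def longitudinal_change_model(
    changes: pd.DataFrame,
    predictor: str = "d_rank",
    response: str = "d_delta_age",
    age_col: str = "age",
) -> dict[str, float]:
    """OLS of within-male change in Δ_age on change in rank, controlling for
    chronological age.

    ``changes`` has one row per male with the between-sample change in
    Δ_age, the change in rank (or a rank/BMI-adjusted variant), and the
    male's chronological age.  Returns the model R², the predictor's
    coefficient and p, and n.
    """
    cols = [response, predictor, age_col]
    df = changes[cols].dropna().astype(float)
    if len(df) < 4:
        raise ValueError("need at least 4 repeat-sampled males")
    if np.ptp(df[predictor].to_numpy()) == 0:
        raise ValueError(f"degenerate predictor {predictor!r}")
    if np.ptp(df[response].to_numpy()) == 0:
        # constant response: nothing to explain
        return {"r2": 0.0, "coef": 0.0, "p": 1.0, "n": len(df)}
    X = sm.add_constant(df[[predictor, age_col]])
    fit = sm.OLS(df[response], X).fit()
    return {
        "r2": float(fit.rsquared),
        "coef": float(fit.params[predictor]),
        "p": float(fit.pvalues[predictor]),
        "n": len(df),
    }


def residual_adjust(x: pd.Series, z: pd.Series) -> pd.Series:
    """Residuals of x regressed on z (with intercept): x adjusted for z.

    Used for the mutual-adjustment variants (rank adjusted for raw BMI and
    vice versa); by the Frisch–Waugh property, regressing on these residuals
    reproduces the corresponding joint-model coefficient.
    """
    df = pd.concat({"x": x, "z": z}, axis=1).dropna()
    fit = sm.OLS(df["x"].astype(float), sm.add_constant(df["z"].astype(float))).fit()
    return fit.resid.reindex(x.index).rename(f"{x.name}_adj")
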