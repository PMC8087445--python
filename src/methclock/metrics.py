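"""Accuracy metrics, relative epigenetic age, longitudinal ordering, and
sex-contrast models for clock predictions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "PredictionMetrics",
    "prediction_metrics",
    "relative_epigenetic_age",
    "longitudinal_ordering_test",
    "longitudinal_pairs",
    "sex_interaction_model",
    "abs_error_sex_test",
]


@dataclass(frozen=True)
class PredictionMetrics:
    """Clock accuracy summary.

    r, r2 : Pearson correlation between predicted and chronological age and
        its square.
    mad, mad_sd : median absolute difference in years and the s.d. of the
        absolute differences.
    slope : OLS slope of predicted on chronological age.
    bias : |1 - slope| (regression-to-the-mean compression of the clock).
    """

    r: float
    r2: float
    mad: float
    mad_sd: float
    slope: float
    bias: float
    n: int


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def prediction_metrics(preds: pd.DataFrame) -> PredictionMetrics:
    """Compute accuracy metrics from a prediction table with columns
    ``age`` and ``predicted_age``."""
    if len(preds) < 3:
        raise ValueError("need at least 3 samples")
    x = preds["age"].to_numpy(float)
    y = preds["predicted_age"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("constant chronological age; correlation undefined")
    abs_err = np.abs(y - x)
    r = float(np.corrcoef(x, y)[0, 1])
    slope, _ = _ols_line(x, y)
    return PredictionMetrics(
        r=r,
        r2=r * r,
        mad=float(np.median(abs_err)),
        mad_sd=float(np.std(abs_err, ddof=1)),
        slope=slope,
        bias=abs(1.0 - slope),
        n=len(preds),
    )


def relative_epigenetic_age(preds: pd.DataFrame) -> pd.DataFrame:
    """Residuals of the best-fit line of predicted on chronological age.

    Fitted within whatever sample group is passed in (e.g. males only), so the
    residuals have mean zero within that group.  Returns a copy with a
    ``relative_age`` column.
    """
    if len(preds) < 3:
        raise ValueError("need at least 3 samples")
    x = preds["age"].to_numpy(float)
    y = preds["predicted_age"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("constant chronological age")
    slope, intercept = _ols_line(x, y)
    out = preds.copy()
    out["relative_age"] = y - (intercept + slope * x)
    return out


def longitudinal_pairs(
    preds: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Earlier/later predicted ages for individuals sampled twice.

    Ordering is by chronological age at sampling; individuals with a single
    sample are dropped, individuals with more than two use the two samples
    farthest apart in age.
    """
    df = preds.join(metadata[["individual_id"]])
    rows = []
    for ind, grp in df.groupby("individual_id"):
        if len(grp) < 2:
            continue
        grp = grp.sort_values("age")
        first, last = grp.iloc[0], grp.iloc[-1]
        rows.append((ind, first["predicted_age"], last["predicted_age"]))
    return pd.DataFrame(rows, columns=["individual_id", "earlier", "later"])


def longitudinal_ordering_test(
    pairs: pd.DataFrame | list[tuple[float, float]],
    method: str = "tail-doubling",
    tie_policy: str = "failure",
) -> tuple[int, int, float]:
    """Exact two-sided binomial test that later samples are predicted older.

    A pair succeeds when the later-collected sample's predicted age exceeds
    the earlier one's; ties count per ``tie_policy`` ("failure" by default).
    The two-sided p at null 0.5 uses symmetric tail doubling capped at 1
    (``method="tail-doubling"``); ``method="minlike"`` gives the
    sum-of-smaller-likelihoods convention via scipy.

    Returns (k successes, n pairs, p).
    """
    if isinstance(pairs, pd.DataFrame):
        earlier = pairs["earlier"].to_numpy(float)
        later = pairs["later"].to_numpy(float)
    else:
        arr = np.asarray(pairs, dtype=float)
        earlier, later = arr[:, 0], arr[:, 1]
    n = len(earlier)
    if n < 1:
        raise ValueError("need at least one pair")
    wins = later > earlier
    if tie_policy == "success":
        wins |= later == earlier
    k = int(wins.sum())
    return k, n, binomial_p(k, n, method=method)


def binomial_p(k: int, n: int, method: str = "tail-doubling") -> float:
    """Two-sided exact binomial p at null probability 0.5."""
    if method == "minlike":
        return float(stats.binomtest(k, n, 0.5).pvalue)
    if method != "tail-doubling":
        raise ValueError(f"unknown method {method!r}")
    lower = stats.binom.cdf(k, n, 0.5)
    upper = stats.binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def sex_interaction_model(
    preds: pd.DataFrame,
    metadata: pd.DataFrame,
    min_age: float | None = None,
    max_age: float | None = None,
) -> pd.DataFrame:
    """OLS of predicted age on chronological age, sex, and their interaction.

    Returns the coefficient table (estimate, standard error, p).  The
    interaction row measures the difference in predicted-age slope between
    the sexes; age-restricted subsets reproduce the juvenile/adult contrast.
    """
    df = preds.join(metadata[["sex"]])
    if min_age is not None:
        df = df[df["age"] >= min_age]
    if max_age is not None:
        df = df[df["age"] < max_age]
    if df["sex"].nunique() < 2:
        raise ValueError("both sexes must be present")
    fit = smf.ols("predicted_age ~ age * C(sex)", data=df).fit()
    return pd.DataFrame({"coef": fit.params, "se": fit.bse, "p": fit.pvalues})


def abs_error_sex_test(preds: pd.DataFrame, metadata: pd.DataFrame) -> float:
    """Two-sided Wilcoxon rank-sum p for a sex difference in absolute
    prediction error."""
    df = preds.join(metadata[["sex"]])
    err = (df["predicted_age"] - df["age"]).abs()
    f, m = err[df["sex"] == "F"], err[df["sex"] == "M"]
    if len(f) == 0 or len(m) == 0:
        raise ValueError("both sexes must be present")
    if len(f) == len(m) and np.array_equal(np.sort(f), np.sort(m)):
        return 1.0
    return float(stats.ranksums(f, m).pvalue)
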