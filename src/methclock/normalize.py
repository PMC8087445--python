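"""Two-stage quantile normalization and leakage-free ECDF projection.

Stage 1 quantile-normalizes each sample's methylation ratios across sites to a
standard normal; stage 2 quantile-normalizes each site across the *training*
samples only.  A held-out sample never touches the training statistics: it is
stage-1 normalized on its own, then each site's value is passed through the
training samples' empirical CDF and mapped to the matching standard-normal
quantile.  This is what makes leave-one-out clock predictions leakage-free.

The quantile convention is the plotting position (i - 0.5)/n; ties receive the
mean of their tied ranks' scores.  ECDF quantiles are clamped to
[1/(n+1), n/(n+1)] so projected scores are always finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "qnorm_vector",
    "qnorm_matrix",
    "QuantileNormalizer",
    "NormalizedTrainingSet",
    "normalize_training",
    "project_test",
]


def _base_scores(n: int) -> np.ndarray:
    return ndtri((np.arange(1, n + 1) - 0.5) / n)


def qnorm_vector(values: np.ndarray) -> np.ndarray:
    """Map a vector to standard-normal scores by rank.

    The value with ascending rank i receives ``ndtri((i - 0.5)/n)``; tied
    values receive the mean of the scores of their tied ranks.  Output is in
    input order.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-D vector")
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if not np.isfinite(v).all():
        raise ValueError("non-finite values")
    return qnorm_matrix(v[None, :], axis=1)[0]


def qnorm_matrix(x: np.ndarray, axis: int) -> np.ndarray:
    """Vectorized :func:`qnorm_vector` along one axis of a 2-D array.

    Tie handling is exact: for a tie group spanning ascending ranks
    [rmin, rmax] the score is the mean of the base scores at those ranks,
    computed from a cumulative sum of the fixed score vector.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite values")
    n = x.shape[axis]
    if n < 2:
        raise ValueError("need at least 2 values along the normalized axis")
    rmin = rankdata(x, method="min", axis=axis).astype(np.int64)
    rmax = rankdata(x, method="max", axis=axis).astype(np.int64)
    cum = np.concatenate([[0.0], np.cumsum(_base_scores(n))])
    return (cum[rmax] - cum[rmin - 1]) / (rmax - rmin + 1)


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Two-stage quantile normalization with ECDF projection of new samples.

    Follows the scikit-learn convention: ``X`` is samples x sites.

    ``fit`` runs both stages on the training samples and stores, per site, the
    sorted stage-1 training values needed to evaluate the training ECDF.
    ``transform`` projects *held-out* samples: each row is stage-1 normalized
    independently across its own sites, then mapped per site through the
    training ECDF (right-continuous, ties counted as <=) to the clamped
    standard-normal quantile.  Note ``transform`` on the training data does
    not reproduce ``fit_transform`` — training scores come from the stage-2
    permutation, held-out scores from the ECDF step function.

    Attributes
    ----------
    training_scores_ : ndarray, samples x sites stage-2 scores
    stage1_sorted_ : ndarray, sites x n_train sorted stage-1 training values
    degenerate_sites_ : bool ndarray, sites constant after stage 1 (scored 0)
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 3:
            raise ValueError("need a 2-D matrix with at least 3 training samples")
        stage1 = qnorm_matrix(X, axis=1)  # within each sample, across sites
        stage2 = qnorm_matrix(stage1, axis=0)  # within each site, across samples
        self.n_features_in_ = X.shape[1]
        self.n_train_ = X.shape[0]
        self.training_scores_ = stage2
        self.stage1_sorted_ = np.sort(stage1.T, axis=1)  # sites x n_train
        self.degenerate_sites_ = stage1.max(axis=0) == stage1.min(axis=0)
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).training_scores_

    def transform(self, X):
        check_is_fitted(self, "stage1_sorted_")
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        if single:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError("site set differs from training")
        stage1 = qnorm_matrix(X, axis=1)
        n = self.n_train_
        # right-continuous ECDF: count of training values <= test value
        counts = np.empty_like(stage1)
        for i in range(stage1.shape[0]):
            counts[i] = (self.stage1_sorted_ <= stage1[i][:, None]).sum(axis=1)
        q = np.clip(counts / n, 1.0 / (n + 1), n / (n + 1.0))
        out = ndtri(q)
        return out[0] if single else out


@dataclass
class NormalizedTrainingSet:
    """Stage-2 training scores plus what :func:`project_test` needs."""

    scores: pd.DataFrame  # sites x training samples
    normalizer: QuantileNormalizer
    sites: pd.Index
    training_samples: pd.Index


def normalize_training(
    ratios: pd.DataFrame, training_samples: list | pd.Index | None = None
) -> NormalizedTrainingSet:
    """Run both normalization stages on the training columns of a sites x
    samples ratio matrix."""
    cols = ratios.columns if training_samples is None else pd.Index(training_samples)
    sub = ratios[list(cols)]
    norm = QuantileNormalizer().fit(sub.to_numpy().T)
    return NormalizedTrainingSet(
        scores=pd.DataFrame(norm.training_scores_.T, index=ratios.index, columns=cols),
        normalizer=norm,
        sites=ratios.index,
        training_samples=pd.Index(cols),
    )


def project_test(test_ratios: pd.Series, norm: NormalizedTrainingSet) -> pd.Series:
    """Project one held-out sample's raw ratios onto training-score space."""
    missing = norm.sites.difference(test_ratios.index)
    if len(missing):
        raise KeyError(f"test sample lacks {len(missing)} training sites, e.g. {missing[0]}")
    v = test_ratios.reindex(norm.sites).to_numpy(float)
    return pd.Series(norm.normalizer.transform(v), index=norm.sites, name=test_ratios.name)
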