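"""Quantile normalization and leakage-free ECDF projection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import ndtri

from methclock import QuantileNormalizer, normalize_training, project_test, qnorm_vector
from methclock.normalize import qnorm_matrix


def oracle_qnorm(v):
    """Independent rank-transform oracle: ordinal scores averaged over ties."""
    v = np.asarray(v, dtype=float)
    n = v.size
    base = ndtri((np.arange(1, n + 1) - 0.5) / n)
    order = np.argsort(v, kind="stable")
    scores = np.empty(n)
    scores[order] = base
    out = np.empty(n)
    for val in np.unique(v):
        mask = v == val
        out[mask] = scores[mask].mean()
    return out


class TestQnormVector:
    def test_three_distinct_values_closed_form(self):
        got = qnorm_vector([10.0, 1.0, 5.0])
        expected = [ndtri(5 / 6), ndtri(1 / 6), 0.0]
        assert got == pytest.approx(expected, abs=1e-12)
        assert got[0] == pytest.approx(0.9674, abs=2e-4)

    def test_all_tied_scores_zero(self):
        assert qnorm_vector([3.0] * 7) == pytest.approx([0.0] * 7, abs=1e-12)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            qnorm_vector([1.0])
        with pytest.raises(ValueError):
            qnorm_vector([1.0, np.nan])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=60))
    def test_matches_oracle_and_monotone(self, values):
        v = np.array(values)
        got = qnorm_vector(v)
        assert got == pytest.approx(oracle_qnorm(v), abs=1e-10)
        # strictly increasing input -> strictly increasing output
        s = np.unique(v)
        if s.size >= 2:
            assert np.all(np.diff(qnorm_vector(s)) > 0)

    def test_matrix_matches_vector(self, rng):
        X = rng.random((6, 15))
        X[0, :5] = 0.25  # ties
        rows = np.array([qnorm_vector(row) for row in X])
        assert qnorm_matrix(X, axis=1) == pytest.approx(rows, abs=1e-12)
        cols = np.array([qnorm_vector(col) for col in X.T]).T
        assert qnorm_matrix(X, axis=0) == pytest.approx(cols, abs=1e-12)


class TestTrainingNormalization:
    def test_permutation_invariants(self, rng):
        """Stage-1 rows are exact permutations of the fixed target quantile
        vector; stage-2 columns are too wherever stage 1 produced no ties
        (stage 1 discretizes values to n_sites scores, so cross-sample rank
        collisions at a site are averaged rather than permuted)."""
        X = rng.random((8, 20))
        norm = QuantileNormalizer().fit(X)
        stage1 = qnorm_matrix(X, axis=1)
        row_target = np.sort(ndtri((np.arange(1, 21) - 0.5) / 20))
        for sample in range(8):
            assert np.sort(stage1[sample]) == pytest.approx(row_target, abs=1e-12)
        site_target = np.sort(ndtri((np.arange(1, 9) - 0.5) / 8))
        checked = 0
        for site in range(20):
            if np.unique(stage1[:, site]).size == 8:  # tie-free column
                assert np.sort(norm.training_scores_[:, site]) == pytest.approx(
                    site_target, abs=1e-12
                )
                checked += 1
        assert checked > 0

    def test_identical_samples_degenerate(self):
        X = np.tile(np.linspace(0.1, 0.9, 12), (5, 1))
        norm = QuantileNormalizer().fit(X)
        assert norm.training_scores_ == pytest.approx(np.zeros((5, 12)), abs=1e-12)
        assert norm.degenerate_sites_.all()

    def test_matches_two_pass_rank_oracle(self, rng):
        X = rng.random((8, 20))
        norm = QuantileNormalizer().fit(X)
        stage1 = np.array([oracle_qnorm(row) for row in X])
        stage2 = np.array([oracle_qnorm(col) for col in stage1.T]).T
        assert norm.training_scores_ == pytest.approx(stage2, abs=1e-12)


class TestProjection:
    def test_clamp_floor_for_extreme_value(self, rng):
        # site 0 is the top-ranked site of every training sample, so its
        # stage-1 training values all sit at the maximum score; a test sample
        # ranking it last falls below the whole training ECDF -> clamped floor
        X = rng.uniform(0.0, 0.9, size=(6, 10))
        X[:, 0] = 0.99
        norm = QuantileNormalizer().fit(X)
        test = rng.uniform(0.1, 0.9, size=10)
        test[0] = 0.001
        out = norm.transform(test)
        assert out[0] == pytest.approx(ndtri(1 / 7), abs=1e-12)

    def test_known_ecdf_value(self):
        """Three training samples at a site; a test value landing at the
        middle training value has ECDF 2/3 -> score ndtri(2/3) ~ 0.4307."""
        n = 3
        q = np.clip(2 / 3, 1 / (n + 1), n / (n + 1))
        assert ndtri(q) == pytest.approx(0.4307, abs=1e-4)

    def test_projection_of_training_sample_within_one_ecdf_step(self, rng):
        X = rng.random((9, 25))
        ratios = pd.DataFrame(
            X.T,
            index=[f"chr1:{i + 1}" for i in range(25)],
            columns=[f"s{i}" for i in range(9)],
        )
        norm = normalize_training(ratios)
        step = 2.0 * abs(ndtri(1 / 10))  # generous bound on one ECDF step at n=9
        for sample in ratios.columns:
            proj = project_test(ratios[sample], norm)
            train_scores = norm.scores[sample]
            assert (proj - train_scores).abs().max() <= step

    def test_monotone_transform_invariance(self, rng):
        X = rng.random((7, 30))
        ratios = pd.DataFrame(X.T, index=[f"chr1:{i + 1}" for i in range(30)],
                              columns=[f"s{i}" for i in range(7)])
        norm = normalize_training(ratios, ratios.columns[:-1])
        test = ratios[ratios.columns[-1]]
        a = project_test(test, norm)
        b = project_test(np.exp(3 * test) - 0.5, norm)
        assert a.to_numpy() == pytest.approx(b.to_numpy(), abs=1e-12)

    def test_training_statistics_independent_of_test_sample(self, rng):
        X = rng.random((8, 12))
        ratios = pd.DataFrame(X.T, index=[f"chr1:{i + 1}" for i in range(12)],
                              columns=[f"s{i}" for i in range(8)])
        train_cols = ratios.columns[:-2]
        other, test = ratios.columns[-2], ratios.columns[-1]
        norm1 = normalize_training(ratios, train_cols)
        perturbed = ratios.copy()
        perturbed[test] = rng.random(12)
        norm2 = normalize_training(perturbed, train_cols)
        assert np.array_equal(norm1.normalizer.training_scores_,
                              norm2.normalizer.training_scores_)
        assert np.array_equal(project_test(ratios[other], norm1).to_numpy(),
                              project_test(perturbed[other], norm2).to_numpy())

    def test_missing_site_rejected(self, rng):
        X = rng.random((5, 6))
        ratios = pd.DataFrame(X.T, index=[f"chr1:{i + 1}" for i in range(6)],
                              columns=list("abcde"))
        norm = normalize_training(ratios)
        short = ratios["a"].iloc[:-1]
        with pytest.raises(KeyError):
            project_test(short, norm)


def test_projection_matches_independent_oracle(rng):
    """ECDF + inverse-normal oracle over many random site/test-value draws."""
    n_train, n_sites = 11, 40
    X = rng.random((n_train, n_sites))
    norm = QuantileNormalizer().fit(X)
    stage1_train = np.array([oracle_qnorm(row) for row in X])
    for _ in range(25):  # 25 draws x 40 sites = 1000 site/value pairs
        test = rng.random(n_sites)
        got = norm.transform(test)
        t1 = oracle_qnorm(test)
        expected = np.empty(n_sites)
        for s in range(n_sites):
            q = np.sum(stage1_train[:, s] <= t1[s]) / n_train
            q = min(max(q, 1 / (n_train + 1)), n_train / (n_train + 1))
            expected[s] = ndtri(q)
        assert got == pytest.approx(expected, abs=1e-12)
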