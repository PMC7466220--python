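"""PLS, cross-validated Q2 and the Levenberg-Marquardt network."""

import numpy as np
import pytest

from powdermorph import models
from powdermorph.models import (
    ann_fit,
    crossval,
    pls_fit,
    q_squared,
    r_squared,
    select_ncomp,
    split_sizes,
)


class TestGoodnessOfFit:
    def test_r2_identities(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, y) == pytest.approx(1.0)
        assert r_squared(y, np.full(3, y.mean())) == pytest.approx(0.0)
        assert r_squared(y, [1.0, 2.0, 4.0]) == pytest.approx(0.5)

    def test_r2_constant_response_rejected(self):
        with pytest.raises(ValueError):
            r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_q2_identities(self):
        assert q_squared(0.0, 5.0) == pytest.approx(1.0)
        assert q_squared(5.0, 5.0) == pytest.approx(0.0)
        assert q_squared(0.13 * 8.0, 8.0) == pytest.approx(0.87)
        with pytest.raises(ValueError):
            q_squared(1.0, 0.0)


class TestPLS:
    def test_full_rank_equals_least_squares(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        fit = pls_fit(X, y, n_components=4)
        # normal-equations oracle with intercept
        A = np.column_stack([np.ones(20), X])
        beta = np.linalg.lstsq(A, y, rcond=None)[0]
        assert np.allclose(fit.predict(X), A @ beta, atol=1e-8)

    def test_noiseless_linear_r2_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(25, 3))
        y = X @ [2.0, -1.0, 0.5] + 7.0
        assert pls_fit(X, y, 3).r2 == pytest.approx(1.0, abs=1e-10)

    def test_single_component_univariate_is_simple_regression(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = 3.0 * x + rng.normal(size=30)
        fit = pls_fit(x[:, None], y, 1)
        slope, intercept = np.polyfit(x, y, 1)
        assert fit.coef[0] == pytest.approx(slope, rel=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10)

    def test_rank_exhaustion_error(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 2))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])  # rank 2
        y = rng.normal(size=15)
        with pytest.raises(ValueError, match="rank"):
            pls_fit(X, y, 3)
        with pytest.raises(ValueError):
            pls_fit(X, y, 0)

    def test_column_scaling_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(18, 5))
        y = rng.normal(size=18)
        scale = np.array([1.0, 10.0, 0.01, 100.0, 3.0])
        a = pls_fit(X, y, 2).predict(X)
        b = pls_fit(X * scale, y, 2).predict(X * scale)
        assert np.allclose(a, b, atol=1e-9)

    def test_matches_sklearn_pls(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 6))
        y = X @ rng.normal(size=6) + 0.3 * rng.normal(size=30)
        for a in (1, 2, 3):
            ours = pls_fit(X, y, a).predict(X)
            sk = PLSRegression(n_components=a, scale=True).fit(X, y)
            assert np.allclose(ours, sk.predict(X).ravel(), atol=1e-8)


class TestCrossval:
    def test_forty_samples_five_folds_of_eight(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 5))
        y = X @ rng.normal(size=5) + rng.normal(size=40)
        report = crossval(X, y, max_components=3, rng_seed=11)
        counts = np.bincount(report.fold_assignment, minlength=5)
        assert list(counts) == [8] * 5
        assert np.all(report.q2 <= 1.0) and np.all(report.press >= 0)

    def test_noiseless_linear_q2_near_one(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 4))
        y = X @ [1.0, -2.0, 0.5, 3.0]
        report = crossval(X, y, max_components=4, rng_seed=1)
        assert report.q2[-1] >= 0.99

    def test_pure_noise_q2_nonpositive_in_expectation(self):
        # permutation oracle: break the X-y link, Q2 should average <= 0
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 3))
        y = X @ [1.0, 1.0, -1.0] + 0.1 * rng.normal(size=20)
        q2s = []
        for shuffle in range(200):
            perm = rng.permutation(20)
            report = crossval(X, y[perm], max_components=2, rng_seed=shuffle)
            q2s.append(report.q2.max())
        assert np.mean(q2s) <= 0.0

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(25, 3))
        y = rng.normal(size=25)
        a = crossval(X, y, 2, rng_seed=5)
        b = crossval(X, y, 2, rng_seed=5)
        assert np.array_equal(a.fold_assignment, b.fold_assignment)
        assert np.array_equal(a.q2, b.q2)


class TestSelectNcomp:
    def _report(self, q2):
        q2 = np.asarray(q2, float)
        n = len(q2)
        return models.CVReport(
            components=np.arange(1, n + 1),
            r2=q2,
            q2=q2,
            press=np.zeros(n),
            mse=np.zeros(n),
            fold_assignment=np.zeros(1, int),
            rng_seed=0,
        )

    def test_parsimonious_takes_first_within_tolerance(self):
        assert select_ncomp(self._report([0.5, 0.8, 0.8]), "parsimonious") == 2

    def test_max_q2_takes_argmax(self):
        assert select_ncomp(self._report([0.5, 0.8, 0.81]), "max_q2") == 3

    def test_parsimonious_picks_knee_of_monotone_curve(self):
        q2 = [0.2, 0.6, 0.85, 0.86, 0.865, 0.865]
        # oracle: enumerate the rule directly
        best = max(q2)
        expected = next(i + 1 for i, v in enumerate(q2) if v >= best - 0.02)
        assert select_ncomp(self._report(q2), "parsimonious", tolerance=0.02) == expected == 3

    def test_unknown_rule(self):
        with pytest.raises(ValueError):
            select_ncomp(self._report([0.5]), "magic")


class TestANN:
    def test_split_sizes_40_is_28_6_6(self):
        assert split_sizes(40, (0.70, 0.15, 0.15)) == (28, 6, 6)

    def test_noiseless_linear_capacity(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(40, 3))
        y = X @ [2.0, -1.0, 1.5] + 5.0
        fit = ann_fit(X, y, rng_seed=3, max_epochs=300)
        assert fit.split_sizes == (28, 6, 6)
        for subset in ("train", "validation", "test", "all"):
            assert fit.r2[subset] >= 0.99, subset

    def test_same_seed_bitwise_reproducible(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 4))
        y = X @ [1.0, 0.5, -2.0, 0.0] + 0.5 * rng.normal(size=30)
        a = ann_fit(X, y, rng_seed=7)
        b = ann_fit(X, y, rng_seed=7)
        assert np.array_equal(a.w_hidden, b.w_hidden)
        assert a.mse == b.mse and a.stopping_epoch == b.stopping_epoch

    def test_training_mse_monotone_over_accepted_steps(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(40, 5))
        y = X @ rng.normal(size=5) + rng.normal(size=40)
        fit = ann_fit(X, y, rng_seed=1)
        history = np.array(fit.train_mse_history)
        assert np.all(np.diff(history) <= 0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            ann_fit(np.ones((6, 2)), np.arange(6.0))
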