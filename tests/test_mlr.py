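"""MLR fitting, forward selection and the validation metrics, each checked
against an independent brute-force oracle where one exists."""

import numpy as np
import pytest

import qsarize as q

# ---------------------------------------------------------------- oracles


def normal_equations(X, y):
    """Independent OLS solution via the normal equations."""
    A = np.column_stack([np.ones(len(X)), X])
    return np.linalg.solve(A.T @ A, A.T @ y)


def brute_force_loo_q2(X, y):
    """Literally refit n models, each with one compound held out."""
    n = len(y)
    preds = np.empty(n)
    for i in range(n):
        keep = [k for k in range(n) if k != i]
        beta = normal_equations(X[keep], y[keep])
        preds[i] = beta[0] + X[i] @ beta[1:]
    return 1.0 - np.sum((y - preds) ** 2) / np.sum((y - y.mean()) ** 2)


def greedy_one_step(X, y, selected):
    """Exhaustive scan over all single additions; returns the best column."""
    best, best_rss = None, np.inf
    for j in range(X.shape[1]):
        if j in selected:
            continue
        cols = selected + [j]
        A = np.column_stack([np.ones(len(X))] + [X[:, c] for c in cols])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss = float(np.sum((y - A @ beta) ** 2))
        if rss < best_rss:
            best, best_rss = j, rss
    return best


# ---------------------------------------------------------------- fitting


class TestFitMlr:
    def test_exact_linear_data_recovered(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 2))
        y = 2.0 + 3.0 * X[:, 0] - 1.0 * X[:, 1]
        model = q.fit_mlr(X, y, names=["A", "B"])
        assert model.intercept == pytest.approx(2.0, abs=1e-8)
        assert model.coefficients["A"] == pytest.approx(3.0, abs=1e-8)
        assert model.coefficients["B"] == pytest.approx(-1.0, abs=1e-8)
        assert q.r_squared(y, model.predict(X)) == pytest.approx(1.0)

    def test_underdetermined_fit_rejected(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(4, 4))
        with pytest.raises(ValueError):
            q.fit_mlr(X, rng.normal(size=4))

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            X = rng.normal(size=(15, 3))
            y = rng.normal(size=15)
            model = q.fit_mlr(X, y)
            beta = normal_equations(X, y)
            assert model.intercept == pytest.approx(beta[0], abs=1e-8)
            got = [model.coefficients[n] for n in model.selected_descriptors]
            np.testing.assert_allclose(got, beta[1:], atol=1e-8)

    def test_collinear_columns_are_named(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 3))
        X[:, 2] = 2 * X[:, 0]
        with pytest.raises(ValueError, match="X3"):
            q.fit_mlr(X, rng.normal(size=10))

    def test_r2_invariant_under_descriptor_rescaling(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + rng.normal(size=25)
        base = q.fit_mlr(X, y)
        X2 = X.copy()
        X2[:, 1] = 10.0 * X2[:, 1] + 7.0  # affine rescale of one column
        scaled = q.fit_mlr(X2, y)
        r2a = q.r_squared(y, base.predict(X))
        r2b = q.r_squared(y, scaled.predict(X2))
        assert r2a == pytest.approx(r2b, abs=1e-10)
        assert scaled.coefficients["X2"] == pytest.approx(
            base.coefficients["X2"] / 10.0, abs=1e-10)


# ------------------------------------------------------- forward selection


class TestForwardSelect:
    def test_dominant_signal_selected_first(self):
        rng = np.random.default_rng(5)
        X, _ = np.linalg.qr(rng.normal(size=(30, 6)))
        y = 5.0 * X[:, 2] + 1e-9 * rng.normal(size=30)
        names = [f"X{j + 1}" for j in range(6)]
        assert q.forward_select(X, y, k=1, names=names)[0] == "X3"

    def test_every_step_matches_exhaustive_scan(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            X = rng.normal(size=(25, 8))
            y = X @ rng.normal(size=8) + rng.normal(size=25)
            picked = q.forward_select(X, y, k=4)
            cols = [int(n[1:]) - 1 for n in picked]
            oracle_sel = []
            for step in range(4):
                oracle_sel.append(greedy_one_step(X, y, oracle_sel))
            assert cols == oracle_sel

    def test_monotone_training_r2(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 6))
        y = X @ rng.normal(size=6) + rng.normal(size=30)
        r2s = []
        for k in range(1, 5):
            sel = q.forward_select(X, y, k=k)
            cols = [int(n[1:]) - 1 for n in sel]
            model = q.fit_mlr(X[:, cols], y, names=sel)
            r2s.append(q.r_squared(y, model.predict(X[:, cols])))
        assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))

    @pytest.mark.parametrize("k", [0, -1])
    def test_k_must_be_positive(self, k):
        X = np.random.default_rng(8).normal(size=(20, 4))
        with pytest.raises(ValueError):
            q.forward_select(X, X[:, 0], k=k)

    def test_k_larger_than_pool_rejected(self):
        X = np.random.default_rng(9).normal(size=(20, 3))
        with pytest.raises(ValueError):
            q.forward_select(X, X[:, 0], k=5)


# ------------------------------------------------------------- validation


class TestLooQ2:
    def test_noise_free_linear_data_gives_unity(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(15, 2))
        y = 1.0 + X @ np.array([2.0, -1.0])
        assert q.loo_q2(X, y) == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_refits(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            X = rng.normal(size=(18, 3))
            y = X @ rng.normal(size=3) + rng.normal(size=18)
            assert q.loo_q2(X, y) == pytest.approx(
                brute_force_loo_q2(X, y), abs=1e-10)

    def test_pure_noise_is_usually_negative(self):
        rng = np.random.default_rng(12)
        negative = sum(
            q.loo_q2(rng.normal(size=(20, 1)), rng.normal(size=20)) < 0
            for _ in range(100)
        )
        assert negative > 50

    def test_q2_never_exceeds_r2(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            X = rng.normal(size=(20, 3))
            y = X @ rng.normal(size=3) + 0.5 * rng.normal(size=20)
            model = q.fit_mlr(X, y)
            r2 = q.r_squared(y, model.predict(X))
            assert q.loo_q2(X, y) <= r2 + 1e-9

    def test_too_small_training_set_rejected(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(5, 3))
        with pytest.raises(ValueError):
            q.loo_q2(X, rng.normal(size=5))


class TestExternalMetrics:
    def test_perfect_prediction_gives_one(self):
        y = np.array([1.5, 2.5, 3.5])
        assert q.r2_pred(y, y, train_mean=2.0) == pytest.approx(1.0)

    def test_train_mean_prediction_gives_zero(self):
        y = np.array([1.5, 2.5, 3.5])
        pred = np.full(3, 2.0)
        assert q.r2_pred(y, pred, train_mean=2.0) == pytest.approx(0.0)

    def test_zero_denominator_rejected(self):
        y = np.array([2.0, 2.0])
        with pytest.raises(ValueError):
            q.r2_pred(y, y + 0.1, train_mean=2.0)

    def test_press_identical_vectors(self):
        y = np.array([1.0, 2.0])
        assert q.press(y, y) == 0.0

    def test_press_single_pair(self):
        assert q.press([2.0], [1.5]) == pytest.approx(0.25)

    def test_press_length_mismatch(self):
        with pytest.raises(ValueError):
            q.press([1.0, 2.0], [1.0])


class TestReliabilityVerdict:
    @staticmethod
    def metrics(q2, r2, r2_pred):
        return q.ValidationMetrics(q2=q2, r2=r2, r2_pred=r2_pred, press=0.0,
                                   reliability_pass=False, overtrained=False)

    def test_reliable_model_passes(self):
        ok, over = q.reliability_verdict(self.metrics(0.796, 0.901, 0.708))
        assert ok and not over  # gap 0.105 < 0.3

    def test_thresholds_are_strict(self):
        ok, _ = q.reliability_verdict(self.metrics(0.5, 0.901, 0.708))
        assert not ok

    def test_overtraining_gap(self):
        ok, over = q.reliability_verdict(self.metrics(0.60, 0.95, 0.7))
        assert over  # 0.35 > 0.3
        assert ok
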