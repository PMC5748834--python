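"""Multiple linear regression with forward selection and QSAR validation.

The model is Y = a0 + a1·X1 + ... + an·Xn over a small set of descriptors
picked by greedy forward selection. Internal validity is assessed by
leave-one-out cross-validation (Q²), external validity by R²_pred on a
held-out test set referenced to the training-set mean, and both are combined
with R² into the usual reliability verdict (Q² > 0.5, R² > 0.8,
R²_pred > 0.6) plus an overtraining flag when R² − Q² exceeds 0.3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .descriptors import DescriptorMatrix

RELIABILITY_Q2 = 0.5
RELIABILITY_R2 = 0.8
RELIABILITY_R2_PRED = 0.6
OVERTRAIN_GAP = 0.3


@dataclass
class MlrModel:
    """A fitted MLR model: intercept a0 and coefficients over the selected
    descriptors, plus the training context needed for external validation."""

    intercept: float
    coefficients: dict[str, float]
    selected_descriptors: list[str]
    train_mean_activity: float
    n_train: int

    def __post_init__(self):
        if set(self.coefficients) != set(self.selected_descriptors):
            raise ValueError("coefficients and selected_descriptors disagree")
        if self.n_train <= len(self.selected_descriptors) + 1:
            raise ValueError("n_train must exceed n_descriptors + 1")

    def predict(self, X) -> np.ndarray:
        """Predict activities from a matrix whose columns follow
        ``selected_descriptors`` order (a DescriptorMatrix is restricted
        automatically)."""
        if isinstance(X, DescriptorMatrix):
            X = X.restrict(self.selected_descriptors).values
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != len(self.selected_descriptors):
            raise ValueError("column count does not match selected descriptors")
        coef = np.array([self.coefficients[n] for n in self.selected_descriptors])
        return self.intercept + X @ coef

    def equation_text(self) -> str:
        terms = [f"{self.intercept:+.4g}"]
        terms += [f"{self.coefficients[n]:+.4g}·{n}"
                  for n in self.selected_descriptors]
        return "pIC50 = " + " ".join(terms)


@dataclass
class ValidationMetrics:
    """Q², R², R²_pred, PRESS over the external test set, and verdicts."""

    q2: float
    r2: float
    r2_pred: float
    press: float
    reliability_pass: bool
    overtrained: bool


def _as_array(X, names=None):
    if isinstance(X, DescriptorMatrix):
        if names is not None:
            X = X.restrict(list(names))
        return np.asarray(X.values, dtype=float), list(X.descriptor_names)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if names is None:
        names = [f"X{j + 1}" for j in range(X.shape[1])]
    return X, list(names)


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns that add no rank on top of the intercept and earlier columns."""
    basis = np.ones((len(X), 1))
    bad = []
    for j, name in enumerate(names):
        trial = np.column_stack([basis, X[:, j]])
        if np.linalg.matrix_rank(trial) == basis.shape[1]:
            bad.append(name)
        else:
            basis = trial
    return bad


def fit_mlr(X, y, names=None) -> MlrModel:
    """Ordinary least-squares fit with intercept.

    ``X`` is a DescriptorMatrix (optionally pre-restricted) or a plain
    (n × p) array with ``names`` supplying descriptor labels. Requires
    n_train > p + 1 and a full-rank design; a rank-deficient design raises,
    naming the collinear columns.
    """
    X, names = _as_array(X, names)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y row counts differ")
    if n <= p + 1:
        raise ValueError(f"need n_train > n_descriptors + 1 (got n={n}, p={p})")
    A = _design(X)
    if np.linalg.matrix_rank(A) < p + 1:
        bad = _collinear_columns(X, names)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    res = sm.OLS(y, A).fit()
    params = np.asarray(res.params, dtype=float)
    return MlrModel(
        intercept=float(params[0]),
        coefficients={name: float(c) for name, c in zip(names, params[1:])},
        selected_descriptors=list(names),
        train_mean_activity=float(np.mean(y)),
        n_train=n,
    )


def r_squared(y_obs, y_calc) -> float:
    """R² = 1 − Σ(Y_obs − Y_calc)² / Σ(Y_obs − Ȳ_obs)² on the training set."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_calc = np.asarray(y_calc, dtype=float)
    ss_res = float(np.sum((y_obs - y_calc) ** 2))
    ss_tot = float(np.sum((y_obs - np.mean(y_obs)) ** 2))
    if ss_tot == 0:
        raise ValueError("training activities are all equal")
    return 1.0 - ss_res / ss_tot


def _rss_with(A_sel: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(A_sel, y, rcond=None)
    r = y - A_sel @ coef
    return float(r @ r)


def forward_select(X, y, k: int, names=None) -> list[str]:
    """Greedy forward selection of ``k`` descriptors.

    At each step the descriptor whose addition most reduces the training
    residual sum of squares is added; ties are resolved toward earlier
    column order. Candidates that would make the design rank-deficient or
    give some training compound a leverage of 1 (which leaves that
    compound's LOO prediction undefined, e.g. a column constant but for one
    compound) are skipped. Returns names in order of addition.
    """
    X, names = _as_array(X, names)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if k < 1:
        raise ValueError("k must be at least 1")
    if k >= n - 1:
        raise ValueError(f"k={k} too large for n_train={n}")
    if k > p:
        raise ValueError(f"k={k} exceeds available descriptors ({p})")

    selected: list[int] = []
    current = _design(np.empty((n, 0)))
    for _ in range(k):
        best_j, best_rss = None, np.inf
        for j in range(p):
            if j in selected:
                continue
            trial = np.column_stack([current, X[:, j]])
            if np.linalg.matrix_rank(trial) < trial.shape[1]:
                continue  # collinear with what is already in the model
            q_trial, _ = np.linalg.qr(trial)
            if np.max(np.sum(q_trial**2, axis=1)) >= 1.0 - 1e-10:
                continue  # a unit leverage would break LOO validation
            rss = _rss_with(trial, y)
            if rss < best_rss:  # strict: ties keep the earlier column
                best_j, best_rss = j, rss
        if best_j is None:
            raise ValueError("no non-collinear descriptor left to add")
        selected.append(best_j)
        current = np.column_stack([current, X[:, best_j]])
    return [names[j] for j in selected]


def loo_q2(X, y, selected=None) -> float:
    """Leave-one-out cross-validated Q².

    Each training compound is held out in turn and predicted by a model
    refit on the remaining n−1 compounds with the *same* descriptor set
    (coefficients re-estimated, selection untouched). Computed via the
    hat-matrix identity e_i/(1 − h_ii) for the LOO residuals, which is
    algebraically exact for OLS.

    Q² = 1 − Σ(Y_obs − Y_pred)² / Σ(Y_obs − Ȳ_training)².
    """
    X, _ = _as_array(X, selected)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 2:
        raise ValueError(f"LOO needs n_train > n_descriptors + 2 (n={n}, p={p})")
    A = _design(X)
    if np.linalg.matrix_rank(A) < p + 1:
        raise ValueError("rank-deficient design in LOO")
    H = A @ np.linalg.solve(A.T @ A, A.T)
    h = np.diag(H)
    if np.any(h >= 1.0 - 1e-12):
        raise ValueError("a leverage of 1 makes a LOO prediction undefined")
    resid = y - H @ y
    press_train = float(np.sum((resid / (1.0 - h)) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        raise ValueError("training activities are all equal")
    return 1.0 - press_train / ss_tot


def r2_pred(y_obs_test, y_pred_test, train_mean: float) -> float:
    """External R²_pred = 1 − Σ(obs − pred)²_test / Σ(obs − Ȳ_training)²_test."""
    y_obs = np.asarray(y_obs_test, dtype=float)
    y_pred = np.asarray(y_pred_test, dtype=float)
    if y_obs.shape != y_pred.shape or y_obs.size < 1:
        raise ValueError("observed/predicted test vectors must match and be non-empty")
    denom = float(np.sum((y_obs - train_mean) ** 2))
    if denom == 0:
        raise ValueError("test activities all equal the training mean")
    return 1.0 - float(np.sum((y_obs - y_pred) ** 2)) / denom


def press(y_obs, y_pred) -> float:
    """Predicted residual sum of squares Σ(obs − pred)²."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape or y_obs.size < 1:
        raise ValueError("observed/predicted vectors must match and be non-empty")
    return float(np.sum((y_obs - y_pred) ** 2))


def reliability_verdict(metrics: ValidationMetrics) -> tuple[bool, bool]:
    """(reliability_pass, overtrained) with strict inequalities:
    pass iff Q² > 0.5 and R² > 0.8 and R²_pred > 0.6; overtrained iff
    R² − Q² > 0.3."""
    ok = (metrics.q2 > RELIABILITY_Q2 and metrics.r2 > RELIABILITY_R2
          and metrics.r2_pred > RELIABILITY_R2_PRED)
    over = (metrics.r2 - metrics.q2) > OVERTRAIN_GAP
    return ok, over


def compute_validation_metrics(model: MlrModel, X_train, y_train,
                               X_test, y_test) -> ValidationMetrics:
    """Assemble the full metric set for a fitted model.

    PRESS is reported over the external test set (the held-out compounds
    the model never saw).
    """
    X_train, _ = _as_array(X_train, model.selected_descriptors)
    X_test, _ = _as_array(X_test, model.selected_descriptors)
    y_train = np.asarray(y_train, dtype=float)
    y_test = np.asarray(y_test, dtype=float)

    r2 = r_squared(y_train, model.predict(X_train))
    q2 = loo_q2(X_train, y_train)
    y_pred_test = model.predict(X_test)
    rp = r2_pred(y_test, y_pred_test, model.train_mean_activity)
    pr = press(y_test, y_pred_test)
    metrics = ValidationMetrics(q2=q2, r2=r2, r2_pred=rp, press=pr,
                                reliability_pass=False, overtrained=False)
    metrics.reliability_pass, metrics.overtrained = reliability_verdict(metrics)
    return metrics
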