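"""Cross-validated L1 / elastic-net fitting on a shared regularization path.

This is the single numerical core behind the cis baseline (elastic net) and
the TF models (LASSO), including every permutation-null refit. It wraps
scikit-learn's coordinate-descent path solver in a manual k-fold loop so that
one pass yields, simultaneously,

* the penalty selected at minimum cross-validated MSE,
* out-of-fold ("cross-validated") predictions at that penalty, and
* full-data coefficients at that penalty.

Because background null models refit the same predictor matrix against
hundreds of permuted responses, :class:`CVPathEngine` caches everything that
depends only on the predictors (fold splits, centered fold matrices, Gram
matrices) and exposes a cheap per-response ``fit``.

Predictors are expected to be standardized (unit population variance) by the
caller; coefficients are therefore on the standardized-predictor scale. The
intercept is handled by centering the response within each training fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import enet_path
from sklearn.model_selection import KFold

__all__ = [
    "PenalizedFit",
    "CVPathEngine",
    "cv_penalized_fit",
    "standardize_columns",
    "floored_cv_r2",
]


@dataclass
class PenalizedFit:
    """Result of a cross-validated penalized fit.

    ``coef`` is on the scale of the (standardized) predictors passed in;
    ``alpha`` is the selected penalty on scikit-learn's scale (the LASSO
    soft-threshold boundary is ``alpha_max = max|X'y| / n`` for centered
    inputs and ``l1_ratio=1``).
    """

    alpha: float
    coef: np.ndarray
    cv_pred: np.ndarray
    insample_pred: np.ndarray
    alphas: np.ndarray = field(repr=False)
    cv_mse: np.ndarray = field(repr=False)

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coef))


def standardize_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center columns and scale to unit population variance.

    Returns the standardized matrix and a boolean mask of columns that had
    nonzero variance; zero-variance columns come back as all-zero (they can
    never enter the model).
    """
    X = np.asarray(X, dtype=np.float64)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    Z = np.zeros_like(X)
    Z[:, keep] = (X[:, keep] - mu[keep]) / sd[keep]
    return Z, keep


def _constant_fit(n: int, p: int, y_mean: float) -> PenalizedFit:
    pred = np.full(n, y_mean)
    return PenalizedFit(
        alpha=np.inf,
        coef=np.zeros(p),
        cv_pred=pred.copy(),
        insample_pred=pred,
        alphas=np.array([np.inf]),
        cv_mse=np.array([np.nan]),
    )


class CVPathEngine:
    """K-fold CV engine for one predictor matrix and many responses."""

    def __init__(
        self,
        X: np.ndarray,
        *,
        l1_ratio: float = 1.0,
        folds: int = 10,
        seed: int = 0,
        n_alphas: int = 30,
        eps: float = 1e-3,
    ) -> None:
        X = np.ascontiguousarray(X, dtype=np.float64)
        self.n, self.p = X.shape
        self.l1_ratio = float(l1_ratio)
        self.n_alphas = int(n_alphas)
        self.eps = float(eps)
        self.degenerate = self.p == 0 or not np.any(X.std(axis=0) > 0)
        if self.degenerate:
            return
        self._Xc = X - X.mean(axis=0)
        self._Xc_f = np.asfortranarray(self._Xc)
        self._gram_full = self._Xc.T @ self._Xc

        folds = min(int(folds), self.n)
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        self._folds = []
        for train, test in kf.split(X):
            Xtr = X[train]
            mu = Xtr.mean(axis=0)
            Xtr_c = np.asfortranarray(Xtr - mu)
            self._folds.append(
                {
                    "train": train,
                    "test": test,
                    "Xtr_c": Xtr_c,
                    "gram": Xtr_c.T @ Xtr_c,
                    "Xte_c": X[test] - mu,
                }
            )

    def fit(self, y: np.ndarray) -> PenalizedFit:
        y = np.ascontiguousarray(y, dtype=np.float64)
        if y.shape[0] != self.n:
            raise ValueError("response length does not match predictor matrix")
        if self.degenerate:
            return _constant_fit(self.n, self.p, float(y.mean()))

        yc = y - y.mean()
        alpha_max = float(np.max(np.abs(self._Xc.T @ yc)) / (self.n * max(self.l1_ratio, 1e-12)))
        if alpha_max <= 0:
            return _constant_fit(self.n, self.p, float(y.mean()))
        alphas = np.geomspace(alpha_max, alpha_max * self.eps, self.n_alphas)

        cv_pred_path = np.empty((self.n, self.n_alphas))
        for fold in self._folds:
            ytr = y[fold["train"]]
            ytr_mean = ytr.mean()
            ytr_c = ytr - ytr_mean
            _, coefs, _ = enet_path(
                fold["Xtr_c"],
                ytr_c,
                l1_ratio=self.l1_ratio,
                alphas=alphas,
                precompute=fold["gram"],
                Xy=fold["Xtr_c"].T @ ytr_c,
                check_input=False,
            )
            cv_pred_path[fold["test"]] = fold["Xte_c"] @ coefs + ytr_mean

        cv_mse = ((cv_pred_path - y[:, None]) ** 2).mean(axis=0)
        best = int(np.argmin(cv_mse))  # alphas descend; ties pick the sparser fit

        _, coefs_full, _ = enet_path(
            self._Xc_f,
            yc,
            l1_ratio=self.l1_ratio,
            alphas=alphas,
            precompute=self._gram_full,
            Xy=self._Xc.T @ yc,
            check_input=False,
        )
        coef = coefs_full[:, best].copy()
        return PenalizedFit(
            alpha=float(alphas[best]),
            coef=coef,
            cv_pred=cv_pred_path[:, best].copy(),
            insample_pred=self._Xc @ coef + y.mean(),
            alphas=alphas,
            cv_mse=cv_mse,
        )


def cv_penalized_fit(
    X: np.ndarray,
    y: np.ndarray,
    *,
    l1_ratio: float = 1.0,
    folds: int = 10,
    seed: int = 0,
    n_alphas: int = 30,
    eps: float = 1e-3,
) -> PenalizedFit:
    """One-shot convenience wrapper around :class:`CVPathEngine`.

    The path runs from ``alpha_max`` (all coefficients zero) down to
    ``eps * alpha_max`` on a log grid shared across folds. Ties in the CV
    error are broken toward the larger (sparser) penalty. With fewer than
    ``folds`` samples the fold count drops to ``n`` (leave-one-out).
    """
    engine = CVPathEngine(
        np.asarray(X, dtype=np.float64),
        l1_ratio=l1_ratio,
        folds=folds,
        seed=seed,
        n_alphas=n_alphas,
        eps=eps,
    )
    return engine.fit(np.asarray(y, dtype=np.float64))


def floored_cv_r2(pred: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of predictions with the response.

    Degenerate cases (constant predictions, as produced when the selected
    penalty zeroes every coefficient, or constant response) return 0.0 —
    the "floor" that keeps model-quality scores comparable across genes.
    """
    pred = np.asarray(pred, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if pred.std() == 0 or y.std() == 0:
        return 0.0
    r = float(np.corrcoef(pred, y)[0, 1])
    if not np.isfinite(r):
        return 0.0
    return r * r
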