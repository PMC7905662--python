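"""Genomic classifier: quantile normalization + lasso multinomial logistic CV.

The classifier transfers cluster labels to external expression data.  The
model is a multinomial logistic regression with an L1 penalty, fit by FISTA
(accelerated proximal gradient) with warm starts along a decreasing lambda
path; lambda is chosen by stratified cross-validated multinomial deviance.
Quantile normalization against a pooled reference removes platform-level
monotone distortions before prediction.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.model_selection import StratifiedKFold


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Pooled-reference quantile normalization over samples x features rows.

    ``fit`` stores the mean sorted profile across all supplied samples;
    ``transform`` replaces each sample's values by reference values at the
    sample's own (average, tie-aware) ranks, so new samples can be projected
    onto the training reference.
    """

    def fit(self, X, y=None):
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("expected a 2-D samples x features matrix")
        self.n_features_in_ = arr.shape[1]
        self.reference_ = np.sort(arr, axis=1).mean(axis=0)
        return self

    def transform(self, X):
        arr = np.asarray(X, dtype=float)
        if arr.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature mismatch: fitted on {self.n_features_in_}, got {arr.shape[1]}"
            )
        p = self.n_features_in_
        out = np.empty_like(arr)
        grid = np.arange(1, p + 1, dtype=float)
        for i in range(arr.shape[0]):
            ranks = rankdata(arr[i], method="average")
            out[i] = np.interp(ranks, grid, self.reference_)
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out


def quantile_normalize(*matrices: pd.DataFrame) -> list[pd.DataFrame]:
    """Quantile-normalize feature x sample matrices against their pooled
    reference.  All matrices must share the same feature index."""
    first = matrices[0]
    for m in matrices[1:]:
        if list(m.index) != list(first.index):
            raise ValueError("matrices do not share a feature space")
    pooled = pd.concat([m.T for m in matrices], axis=0)
    qn = QuantileNormalizer().fit(pooled)
    return [qn.transform(m.T).T for m in matrices]


# ---------------------------------------------------------------------------
# multinomial lasso via FISTA
# ---------------------------------------------------------------------------


def _softmax(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=1, keepdims=True)
    e = np.exp(Z)
    return e / e.sum(axis=1, keepdims=True)


def _objective(X, Y, B, b0, lam) -> float:
    P = _softmax(X @ B.T + b0)
    n = X.shape[0]
    ll = -np.sum(Y * np.log(np.clip(P, 1e-300, None))) / n
    return ll + lam * np.abs(B).sum()


def _gradients(X, Y, B, b0):
    n = X.shape[0]
    P = _softmax(X @ B.T + b0)
    R = P - Y
    return R.T @ X / n, R.mean(axis=0)


def _kkt_violation(G: np.ndarray, B: np.ndarray, lam: float) -> float:
    """Max violation of the L1 subgradient stationarity conditions."""
    active = B != 0
    v_active = np.abs(G + lam * np.sign(B))[active].max() if active.any() else 0.0
    v_zero = np.maximum(np.abs(G[~active]) - lam, 0.0).max() if (~active).any() else 0.0
    return float(max(v_active, v_zero))


def _fista(
    X, Y, lam, B0, b00, max_iter: int = 5000, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, float]:
    """Accelerated proximal gradient for L1 multinomial logistic regression.

    Step size 2/L with L from the softmax Hessian bound 0.5 * sigma_max^2 / n
    of the intercept-augmented design; adaptive restart on objective increase.
    Returns (coefficients, intercepts, final KKT violation).
    """
    n = X.shape[0]
    Xa = np.column_stack([np.ones(n), X])
    smax = np.linalg.norm(Xa, 2)
    L = 0.5 * smax**2 / n
    step = 1.0 / L
    B, b0 = B0.copy(), b00.copy()
    Bv, b0v = B.copy(), b0.copy()
    t = 1.0
    prev_obj = _objective(X, Y, B, b0, lam)
    for it in range(max_iter):
        GB, gb = _gradients(X, Y, Bv, b0v)
        B_new = Bv - step * GB
        B_new = np.sign(B_new) * np.maximum(np.abs(B_new) - step * lam, 0.0)
        b0_new = b0v - step * gb
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t**2)) / 2.0
        Bv = B_new + (t - 1.0) / t_new * (B_new - B)
        b0v = b0_new + (t - 1.0) / t_new * (b0_new - b0)
        B, b0, t = B_new, b0_new, t_new
        if it % 10 == 0:
            GB_at, gb_at = _gradients(X, Y, B, b0)
            viol = max(_kkt_violation(GB_at, B, lam), np.abs(gb_at).max())
            if viol < tol:
                break
            obj = _objective(X, Y, B, b0, lam)
            if obj > prev_obj + 1e-12:  # adaptive restart
                Bv, b0v, t = B.copy(), b0.copy(), 1.0
            prev_obj = obj
    GB_at, gb_at = _gradients(X, Y, B, b0)
    viol = max(_kkt_violation(GB_at, B, lam), np.abs(gb_at).max())
    return B, b0, viol


class LassoMultinomialCV(BaseEstimator, ClassifierMixin):
    """L1-penalized multinomial logistic regression with CV lambda selection.

    Features are standardized internally; the penalty applies to the
    standardized coefficients, the intercept is unpenalized.  The lambda grid
    is log-spaced from lambda_max (the smallest lambda zeroing every
    coefficient) down by ``lambda_min_ratio``; folds are stratified by class.

    Fitted attributes: ``classes_``, ``coef_`` (classes x features,
    standardized space), ``intercept_``, ``lambda_``, ``cv_deviance_``,
    ``lambda_path_``, ``path_nonzero_``, ``kkt_violations_``,
    ``signature_`` (features nonzero in any class at the chosen lambda).
    """

    def __init__(
        self,
        n_folds: int = 10,
        n_lambdas: int = 100,
        lambda_min_ratio: float = 1e-4,
        lambda_grid=None,
        cv_metric: str = "deviance",
        max_iter: int = 5000,
        tol: float = 1e-8,
        random_state: int = 0,
    ):
        self.n_folds = n_folds
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.lambda_grid = lambda_grid
        self.cv_metric = cv_metric
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------
    def _standardize(self, X):
        return (X - self.center_) / self.scale_

    def _path(self, X, Y, lambdas):
        K, p = Y.shape[1], X.shape[1]
        B = np.zeros((K, p))
        b0 = np.log(np.clip(Y.mean(axis=0), 1e-12, None))
        b0 = b0 - b0.mean()
        fits = []
        for lam in lambdas:
            B, b0, viol = _fista(X, Y, lam, B, b0, self.max_iter, self.tol)
            fits.append((lam, B.copy(), b0.copy(), viol))
        return fits

    # -- estimator API ---------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if hasattr(X, "ndim") and X.ndim != 2:
            raise ValueError("X must be 2-D")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        K = len(self.classes_)
        n, p = X.shape
        counts = np.bincount(y_idx, minlength=K)
        if self.n_folds > 1 and (counts < self.n_folds).any():
            raise ValueError(
                f"every class needs >= n_folds={self.n_folds} members; got {counts.tolist()}"
            )
        self.center_ = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        self.scale_ = np.where(scale == 0, 1.0, scale)
        Xs = self._standardize(X)
        Y = np.zeros((n, K))
        Y[np.arange(n), y_idx] = 1.0

        if self.lambda_grid is not None:
            lambdas = np.sort(np.asarray(self.lambda_grid, dtype=float))[::-1]
            if len(lambdas) == 0:
                raise ValueError("lambda_grid is empty")
        else:
            P0 = np.tile(Y.mean(axis=0), (n, 1))
            lam_max = np.abs((P0 - Y).T @ Xs / n).max()
            lam_max = max(lam_max, 1e-10)
            lambdas = np.geomspace(lam_max, lam_max * self.lambda_min_ratio, self.n_lambdas)

        # cross-validated deviance per lambda
        if self.n_folds > 1:
            skf = StratifiedKFold(
                n_splits=self.n_folds, shuffle=True, random_state=self.random_state
            )
            dev = np.zeros((self.n_folds, len(lambdas)))
            for f, (tr, te) in enumerate(skf.split(Xs, y_idx)):
                fits = self._path(Xs[tr], Y[tr], lambdas)
                for li, (lam, B, b0, _) in enumerate(fits):
                    P = _softmax(Xs[te] @ B.T + b0)
                    if self.cv_metric == "deviance":
                        dev[f, li] = -2.0 * np.mean(
                            np.log(np.clip(P[np.arange(len(te)), y_idx[te]], 1e-300, None))
                        )
                    elif self.cv_metric == "misclassification":
                        dev[f, li] = np.mean(np.argmax(P, axis=1) != y_idx[te])
                    else:
                        raise ValueError(f"unknown cv_metric {self.cv_metric!r}")
            self.cv_deviance_ = dev.mean(axis=0)
            best = int(np.argmin(self.cv_deviance_))
        else:
            self.cv_deviance_ = None
            best = len(lambdas) - 1

        fits = self._path(Xs, Y, lambdas)
        self.lambda_path_ = np.asarray(lambdas)
        self.path_nonzero_ = np.asarray(
            [np.count_nonzero(np.any(B != 0, axis=0)) for _, B, _, _ in fits]
        )
        self.kkt_violations_ = np.asarray([v for _, _, _, v in fits])
        self.lambda_ = float(lambdas[best])
        _, self.coef_, self.intercept_, self.kkt_violation_ = fits[best]
        self.n_features_in_ = p
        self.signature_mask_ = np.any(self.coef_ != 0, axis=0)
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        return _softmax(self._standardize(X) @ self.coef_.T + self.intercept_)

    def predict(self, X):
        P = self.predict_proba(X)
        return self.classes_[np.argmax(P, axis=1)]  # argmax ties -> lowest class

    def deviance(self, X, y) -> float:
        """Mean multinomial deviance of the fitted model on (X, y)."""
        y_idx = np.searchsorted(self.classes_, y)
        P = self.predict_proba(X)
        return float(
            -2.0 * np.mean(np.log(np.clip(P[np.arange(len(y_idx)), y_idx], 1e-300, None)))
        )


def fit_lasso_multinomial_cv(
    X: pd.DataFrame, labels: pd.Series, n_folds: int = 10, lambda_grid=None, seed: int = 0, **kw
) -> "GenomicClassifier":
    """Fit the genomic classifier on a samples x features matrix."""
    model = LassoMultinomialCV(
        n_folds=n_folds, lambda_grid=lambda_grid, random_state=seed, **kw
    )
    qn = QuantileNormalizer().fit(X.to_numpy(dtype=float))
    # train on the quantile-normalized data so external samples projected
    # onto the same reference are exchangeable with training samples
    model.fit(qn.transform(X.to_numpy(dtype=float)), labels.loc[X.index].to_numpy())
    return GenomicClassifier(list(X.columns), model, qn)


class GenomicClassifier:
    """Trained classifier bundle: feature list, lasso model, and the training
    quantile reference used to project external data."""

    def __init__(self, features: list[str], model: LassoMultinomialCV, normalizer: QuantileNormalizer):
        self.features = features
        self.model = model
        self.normalizer = normalizer

    @property
    def signature(self) -> list[str]:
        return [f for f, keep in zip(self.features, self.model.signature_mask_) if keep]

    def predict(self, X_new: pd.DataFrame, normalize: bool = True) -> pd.DataFrame:
        """Class probabilities and labels for samples x features input."""
        missing = [f for f in self.features if f not in X_new.columns]
        if missing:
            raise ValueError(f"input is missing model features: {missing}")
        arr = X_new.loc[:, self.features].to_numpy(dtype=float)
        if normalize:
            arr = self.normalizer.transform(arr)
        proba = self.model.predict_proba(arr)
        out = pd.DataFrame(proba, index=X_new.index, columns=self.model.classes_)
        out["label"] = self.model.classes_[np.argmax(proba, axis=1)]
        return out

    # -- JSON round trip --------------------------------------------------
    def to_json(self) -> str:
        m = self.model
        return json.dumps(
            {
                "features": self.features,
                "classes": [int(c) if isinstance(c, (int, np.integer)) else c for c in m.classes_],
                "coefficients": m.coef_.tolist(),
                "intercept": m.intercept_.tolist(),
                "lambda": m.lambda_,
                "center": m.center_.tolist(),
                "scale": m.scale_.tolist(),
                "quantile_reference": self.normalizer.reference_.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GenomicClassifier":
        d = json.loads(text)
        model = LassoMultinomialCV()
        model.classes_ = np.asarray(d["classes"])
        model.coef_ = np.asarray(d["coefficients"], dtype=float)
        model.intercept_ = np.asarray(d["intercept"], dtype=float)
        model.lambda_ = float(d["lambda"])
        model.center_ = np.asarray(d["center"], dtype=float)
        model.scale_ = np.asarray(d["scale"], dtype=float)
        model.signature_mask_ = np.any(model.coef_ != 0, axis=0)
        model.n_features_in_ = len(d["features"])
        qn = QuantileNormalizer()
        qn.reference_ = np.asarray(d["quantile_reference"], dtype=float)
        qn.n_features_in_ = len(qn.reference_)
        return cls(d["features"], model, qn)
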