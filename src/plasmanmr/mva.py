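"""Multivariate analysis: PCA, two-class PLS-DA with nested
cross-validation, VIP signatures and cross-method signature comparison.

PLS-DA is a NIPALS-style PLS1 regression on mean-centered X against a
centered +-1 class coding; the number of latent variables is chosen by
leave-one-out cross-validation, and model quality is assessed by double
(nested leave-one-out) cross-validation in which the component count is
re-selected inside every outer fold before the held-out sample is
classified.  Variable importance in projection (VIP) scores summarize a
fitted model's feature signature; signatures from different acquisition
methods are compared by position matching of their important features.

Estimators follow the scikit-learn protocol (``fit``/``predict``/
``transform``, fitted attributes with trailing underscores) and compose
with sklearn model selection, without depending on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._base import BaseEstimator, check_is_fitted

__all__ = [
    "PCA",
    "pca",
    "PLSDA",
    "plsda_fit",
    "plsda_predict",
    "select_components_loocv",
    "double_cv",
    "vip_scores",
    "VipSignature",
    "signature_overlap",
]


class PCA(BaseEstimator):
    """Principal component analysis on mean-centered data (via SVD)."""

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        max_rank = min(n - 1, p)
        k = max_rank if self.n_components is None else self.n_components
        if k < 1 or k > max_rank:
            raise ValueError(
                f"n_components must lie in [1, {max_rank}] for a {n}x{p} table"
            )
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        self.components_ = Vt[:k]  # orthonormal loadings, rows
        self.singular_values_ = s[:k]
        self.explained_variance_ = (s[:k] ** 2) / (n - 1)
        total = float(np.sum(s**2)) / (n - 1)
        self.explained_variance_ratio_ = (
            self.explained_variance_ / total if total > 0
            else np.zeros_like(self.explained_variance_)
        )
        self.scores_ = U[:, :k] * s[:k]
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        return (np.asarray(X, float) - self.mean_) @ self.components_.T

    def fit_transform(self, X, y=None):
        self.fit(X)
        return self.scores_


def pca(X, n_components: int | None = None):
    """Convenience wrapper: returns (scores, loadings, explained_variance_ratio)."""
    m = PCA(n_components).fit(np.asarray(X, float))
    return m.scores_, m.components_, m.explained_variance_ratio_


class PLSDA(BaseEstimator):
    """Two-class PLS discriminant analysis (NIPALS PLS1, mean-centered).

    Classes are coded -1/+1 (sorted label order); a continuous prediction
    of exactly 0 is assigned to the -1-coded class.  Fitted attributes:
    ``x_weights_`` (p x A), ``x_scores_`` (n x A), ``x_loadings_``
    (p x A), ``y_loadings_`` (A,), ``coef_`` (p,), ``classes_``.
    """

    def __init__(self, n_components: int = 2, scale: bool = False):
        self.n_components = n_components
        self.scale = scale

    def _encode(self, y) -> np.ndarray:
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError(
                f"PLSDA requires exactly 2 classes, got {self.classes_.size}"
            )
        for c in self.classes_:
            if (y == c).sum() < 2:
                raise ValueError(f"class {c!r} has fewer than 2 samples")
        return np.where(y == self.classes_[1], 1.0, -1.0)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        ycode = self._encode(y)
        n, p = X.shape
        self.x_mean_ = X.mean(axis=0)
        self.x_std_ = X.std(axis=0, ddof=1) if self.scale else np.ones(p)
        self.x_std_[self.x_std_ == 0] = 1.0
        self.y_mean_ = float(ycode.mean())
        Xc = (X - self.x_mean_) / self.x_std_
        yc = ycode - self.y_mean_

        A = min(self.n_components, min(n - 1, p))
        W = np.zeros((p, A))
        T = np.zeros((n, A))
        P = np.zeros((p, A))
        q = np.zeros(A)
        a = 0
        for _ in range(A):
            w = Xc.T @ yc
            nw = np.linalg.norm(w)
            if nw <= 1e-12 * max(1.0, np.abs(Xc).max()):
                break  # X exhausted or y orthogonal to the residual
            w /= nw
            t = Xc @ w
            tt = float(t @ t)
            if tt <= 0:
                break
            p_a = (Xc.T @ t) / tt
            q_a = float(yc @ t) / tt
            Xc = Xc - np.outer(t, p_a)
            yc = yc - q_a * t
            W[:, a], T[:, a], P[:, a], q[a] = w, t, p_a, q_a
            a += 1
        self.n_components_ = a
        self.x_weights_ = W[:, :a]
        self.x_scores_ = T[:, :a]
        self.x_loadings_ = P[:, :a]
        self.y_loadings_ = q[:a]
        if a == 0:
            # degenerate fit (constant X): predict the centered mean, so
            # every sample falls to the tie-rule class
            self.coef_ = np.zeros(p)
        else:
            # regression vector on (centered, scaled) X
            R = self.x_weights_ @ np.linalg.inv(
                self.x_loadings_.T @ self.x_weights_
            )
            self.coef_ = R @ self.y_loadings_
        self.x_residual_ = Xc
        return self

    def decision_function(self, X):
        """Continuous prediction on the centered +-1 coding scale.

        The score is the centered regression prediction, so the decision
        threshold sits at the training mid-point: a constant (fully
        uninformative) X always scores exactly 0 regardless of fold
        class balance.
        """
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.x_mean_.size:
            raise ValueError(
                f"X has {X.shape[1]} features; model was fitted with "
                f"{self.x_mean_.size}"
            )
        Xc = (X - self.x_mean_) / self.x_std_
        return Xc @ self.coef_

    def predict(self, X):
        """Class labels; a score of exactly 0 falls to the -1-coded class."""
        score = self.decision_function(X)
        return np.where(score > 0, self.classes_[1], self.classes_[0])

    def transform(self, X):
        check_is_fitted(self, "coef_")
        Xc = (np.asarray(X, float) - self.x_mean_) / self.x_std_
        R = self.x_weights_ @ np.linalg.inv(self.x_loadings_.T @ self.x_weights_)
        return Xc @ R


def plsda_fit(X, y, n_components: int) -> PLSDA:
    return PLSDA(n_components=n_components).fit(X, y)


def plsda_predict(model: PLSDA, X_new):
    """Returns (labels, continuous scores)."""
    return model.predict(X_new), model.decision_function(X_new)


def _loo_misclassifications(X, y, a: int) -> int:
    X = np.asarray(X, float)
    y = np.asarray(y)
    wrong = 0
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        try:
            m = PLSDA(n_components=a).fit(X[mask], y[mask])
        except ValueError:
            return len(y)  # degenerate fold: treat as failure of this a
        if m.predict(X[i : i + 1])[0] != y[i]:
            wrong += 1
    return wrong


def select_components_loocv(X, y, a_max: int | None = None) -> int:
    """Smallest component count minimizing leave-one-out misclassifications."""
    y = np.asarray(y)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 samples for LOO component selection")
    if a_max is None:
        a_max = min(10, n - 2)
    a_max = max(1, min(a_max, n - 2))
    errors = [
        _loo_misclassifications(X, y, a) for a in range(1, a_max + 1)
    ]
    return int(np.argmin(errors)) + 1  # ties -> smaller a


def double_cv(X, y, a_max: int | None = None):
    """Nested leave-one-out model assessment.

    For every outer fold the component count is re-selected by inner LOO
    on the remaining samples, the model refitted, and the held-out sample
    classified.  Returns
    ``(misclassification_count, predicted_labels, per_fold_components)``.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    n = len(y)
    if n < 6:
        raise ValueError("need at least 6 samples for double cross-validation")
    preds = np.empty(n, dtype=y.dtype)
    comps = np.empty(n, dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        ytr = y[mask]
        if np.unique(ytr).size < 2:
            raise ValueError("an outer fold lost an entire class")
        a_star = select_components_loocv(X[mask], ytr, a_max=a_max)
        m = PLSDA(n_components=a_star).fit(X[mask], ytr)
        preds[i] = m.predict(X[i : i + 1])[0]
        comps[i] = m.n_components_
    wrong = int(np.sum(preds != y))
    return wrong, preds, comps


# ---------------------------------------------------------------------------
# VIP signatures


@dataclass
class VipSignature:
    scores: np.ndarray  # per-feature VIP
    positions: np.ndarray  # feature centers, ppm
    threshold: float = 1.0

    @property
    def important(self) -> np.ndarray:
        return self.scores > self.threshold

    @property
    def important_positions(self) -> np.ndarray:
        return self.positions[self.important]


def vip_scores(model: PLSDA, positions=None, threshold: float = 1.0) -> VipSignature:
    """Variable importance in projection for every feature.

    ``VIP_j = sqrt( p * sum_a SSY_a (w_aj/||w_a||)^2 / sum_a SSY_a )``
    with ``SSY_a = q_a^2 (t_a' t_a)``; mean squared VIP is 1 by
    construction.
    """
    check_is_fitted(model, "coef_")
    W = model.x_weights_
    T = model.x_scores_
    q = model.y_loadings_
    p, A = W.shape
    ssy = q**2 * np.einsum("na,na->a", T, T)
    total = float(ssy.sum())
    if total <= 0:
        raise ValueError("zero total explained sum of squares of y")
    wnorm2 = np.sum(W**2, axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    vip = np.sqrt(p * ((W**2 / wnorm2) @ ssy) / total)
    if positions is None:
        positions = np.arange(p, dtype=float)
    return VipSignature(scores=vip, positions=np.asarray(positions, float),
                        threshold=threshold)


def signature_overlap(sig_a: VipSignature, sig_b: VipSignature,
                      match_tol: float = 0.005) -> dict:
    """Greedy nearest-position matching of important features.

    Returns counts ``{"shared": ..., "a_only": ..., "b_only": ...}``.
    """
    if match_tol <= 0:
        raise ValueError("match tolerance must be > 0")
    a = list(sig_a.important_positions)
    b = list(sig_b.important_positions)
    pairs = []
    for i, pa in enumerate(a):
        for j, pb in enumerate(b):
            d = abs(pa - pb)
            if d <= match_tol:
                pairs.append((d, i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    shared = 0
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        shared += 1
    return {
        "shared": shared,
        "a_only": len(a) - shared,
        "b_only": len(b) - shared,
    }
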