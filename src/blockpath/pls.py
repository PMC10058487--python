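"""Partial least squares regression (PLS1/PLS2) via NIPALS, with VIP.

This is the workhorse underneath every arrow of a path diagram: the
global-effect model, the two residualization models and the final
residual-on-residual regression are all plain PLS regressions.

The implementation is the classical NIPALS algorithm with deflation of X
(and Y in the multivariate case), which agrees with the kernel-PLS family
on fitted values for any common component count.  Fitting is fully
deterministic: the inner iteration is initialized with the response column
of maximal variance, and PLS1 converges in a single pass.

Both X and Y are mean-centered internally with *training* means; no scaling
happens here (unit-variance scaling is a preprocessing step applied once to
the blocks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PLSModel",
    "fit_pls",
    "predict",
    "predict_components",
    "explained_variance_fraction",
    "vip",
]

#: convergence tolerance of the NIPALS inner iteration
NIPALS_TOL = 1e-12
#: cap on inner iterations (PLS1 needs one; PLS2 typically a handful)
NIPALS_MAX_ITER = 500
#: weight norms below this trigger an early stop (no covariance left)
DEGENERATE_EPS = 1e-12


@dataclass(frozen=True)
class PLSModel:
    """A fitted PLS regression model.

    Attributes
    ----------
    n_components : realized number of components (may be fewer than
        requested if the X/Y covariance degenerated; see ``early_stopped``).
    weights : W, (p, a) — X weights, unit norm per column.
    x_scores : T, (n, a) — mutually orthogonal training scores.
    x_loadings : P, (p, a).
    y_loadings : Q, (q, a).
    coefficients : V, (p, q) — regression coefficients on centered data,
        V = W (PᵀW)⁻¹ Qᵀ.
    x_means, y_means : training column means used for centering.
    early_stopped : True when fewer components than requested were fitted.
    """

    n_components: int
    weights: np.ndarray
    x_scores: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    coefficients: np.ndarray
    x_means: np.ndarray
    y_means: np.ndarray
    early_stopped: bool = False

    @property
    def n_predictors(self) -> int:
        return self.weights.shape[0]

    @property
    def n_responses(self) -> int:
        return self.y_loadings.shape[0]

    def rotations(self) -> np.ndarray:
        """R = W (PᵀW)⁻¹, mapping centered X to scores: T = Xc R."""
        W, P = self.weights, self.x_loadings
        return W @ np.linalg.inv(P.T @ W)

    def to_dict(self) -> dict:
        """JSON-compatible serialization (lists of floats)."""
        return {
            "n_components": self.n_components,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coefficients": self.coefficients.tolist(),
            "x_means": self.x_means.tolist(),
            "y_means": self.y_means.tolist(),
            "early_stopped": self.early_stopped,
        }


def _as_2d(Y) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    return Y[:, None] if Y.ndim == 1 else Y


def fit_pls(X, Y, n_components: int) -> PLSModel:
    """Fit a PLS regression of ``Y`` on ``X`` with ``n_components`` latent
    components by NIPALS.

    Components are nested: the model fitted with ``a`` components agrees
    with the first ``a`` components of any larger fit on the same data.
    If the residual X/Y covariance vanishes before ``n_components`` is
    reached, fitting stops early and ``early_stopped`` is set.
    """
    X = np.asarray(X, dtype=float)
    Y = _as_2d(Y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError(f"X has {n} rows but Y has {Y.shape[0]}")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    max_a = min(n - 1, p)
    if n_components > max_a:
        raise ValueError(
            f"n_components={n_components} exceeds min(n-1, p)={max_a}"
        )
    x_means = X.mean(axis=0)
    y_means = Y.mean(axis=0)
    Xc = X - x_means
    Yc = Y - y_means
    q = Y.shape[1]

    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((q, n_components))
    realized = 0
    early = False

    Xd, Yd = Xc.copy(), Yc.copy()
    for a in range(n_components):
        # deterministic start: response column of maximal residual variance
        u = Yd[:, int(np.argmax(Yd.var(axis=0)))].copy()
        w = np.zeros(p)
        for _ in range(NIPALS_MAX_ITER):
            w_new = Xd.T @ u
            norm = np.linalg.norm(w_new)
            if norm < DEGENERATE_EPS:
                break
            w_new /= norm
            t = Xd @ w_new
            tt = t @ t
            if tt < DEGENERATE_EPS:
                norm = 0.0
                break
            qa = Yd.T @ t / tt
            if q == 1:
                w = w_new
                break
            u_new = Yd @ qa / (qa @ qa)
            if np.linalg.norm(w_new - w) < NIPALS_TOL:
                w = w_new
                break
            w = w_new
            u = u_new
        if norm < DEGENERATE_EPS:
            early = True
            break
        t = Xd @ w
        tt = t @ t
        pa = Xd.T @ t / tt
        qa = Yd.T @ t / tt
        W[:, a], T[:, a], P[:, a], Q[:, a] = w, t, pa, qa
        Xd = Xd - np.outer(t, pa)
        Yd = Yd - np.outer(t, qa)
        realized = a + 1

    if realized == 0:
        # no covariance at all: intercept-only model
        coef = np.zeros((p, q))
        return PLSModel(
            n_components=0,
            weights=np.zeros((p, 0)),
            x_scores=np.zeros((n, 0)),
            x_loadings=np.zeros((p, 0)),
            y_loadings=np.zeros((q, 0)),
            coefficients=coef,
            x_means=x_means,
            y_means=y_means,
            early_stopped=True,
        )

    W, T, P, Q = W[:, :realized], T[:, :realized], P[:, :realized], Q[:, :realized]
    R = W @ np.linalg.inv(P.T @ W)
    coef = R @ Q.T
    return PLSModel(
        n_components=realized,
        weights=W,
        x_scores=T,
        x_loadings=P,
        y_loadings=Q,
        coefficients=coef,
        x_means=x_means,
        y_means=y_means,
        early_stopped=early,
    )


def predict(model: PLSModel, X_new) -> np.ndarray:
    """Predict responses for new observations: (X - x̄) V + ȳ."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.n_predictors:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, model expects "
            f"{model.n_predictors}"
        )
    return (X_new - model.x_means) @ model.coefficients + model.y_means


def predict_components(model: PLSModel, X_new) -> np.ndarray:
    """Predictions for every component count 1..n_components at once.

    Returns an array of shape (n_components, n_new, q); slice ``a-1`` is
    the prediction of the nested a-component model.  Exploits the nesting
    of NIPALS components: Ŷ(a) = Ŷ(a-1) + t_a q_aᵀ with t = Xc R.
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.n_predictors:
        raise ValueError("column-count mismatch")
    a = model.n_components
    if a == 0:
        return np.broadcast_to(
            model.y_means, (1, X_new.shape[0], model.n_responses)
        ).copy()
    scores = (X_new - model.x_means) @ model.rotations()  # (n_new, a)
    increments = scores[:, :, None] * model.y_loadings.T[None, :, :]  # (n_new, a, q)
    cum = np.cumsum(increments, axis=1)  # (n_new, a, q)
    return np.moveaxis(cum, 1, 0) + model.y_means


def explained_variance_fraction(Y_true, Y_pred, Y_reference_mean) -> float:
    """1 − ‖Y − Ŷ‖² / ‖Y − ȳ_ref‖² with Frobenius norms over all columns.

    For a training fit this is the squared-Frobenius-norm ratio of fitted
    to total (centered) response variation, because PLS fitted values are
    orthogonal to the residuals.  For out-of-sample predictions it may be
    negative.
    """
    Y_true = _as_2d(Y_true)
    Y_pred = _as_2d(Y_pred)
    ref = np.broadcast_to(np.asarray(Y_reference_mean, dtype=float), Y_true.shape)
    if Y_true.shape != Y_pred.shape:
        raise ValueError("Y_true and Y_pred shapes differ")
    tss = float(np.sum((Y_true - ref) ** 2))
    if tss == 0:
        raise ValueError("zero total variance in Y_true")
    rss = float(np.sum((Y_true - Y_pred) ** 2))
    return 1.0 - rss / tss


def vip(model: PLSModel) -> np.ndarray:
    """Variable importance in the projection for every predictor.

    VIP_j = sqrt( p · Σ_a SSY_a (w_ja / ‖w_a‖)² / Σ_a SSY_a ) where
    SSY_a = ‖q_a‖² t_aᵀt_a is the response sum of squares captured by
    component a.  The mean of squared VIPs is 1 by construction.
    """
    if model.n_components < 1:
        raise ValueError("VIP requires a fitted model with >= 1 components")
    W, T, Q = model.weights, model.x_scores, model.y_loadings
    p = W.shape[0]
    ssy = np.sum(Q**2, axis=0) * np.sum(T**2, axis=0)  # (a,)
    total = ssy.sum()
    if total <= 0:
        raise ValueError("no response variance captured by any component")
    wnorm2 = np.sum(W**2, axis=0)
    contrib = (W**2 / wnorm2) @ ssy  # (p,)
    return np.sqrt(p * contrib / total)
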