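"""Independent reference implementations used only for cross-checking.

These deliberately take different algorithmic routes from the package
(projected/proximal gradient instead of coordinate descent; SVD instead of
NIPALS power iteration) so agreement is evidence of correctness, not of
shared code.
"""

from __future__ import annotations

import numpy as np


def lasso_oracle(s: np.ndarray, X: np.ndarray, lam: float, nonnegative: bool = True,
                 n_iter: int = 50_000) -> np.ndarray:
    """Proximal-gradient solver for 1/2||s - Xc||^2 + lam*||c||_1 (c >= 0)."""
    G = X.T @ X
    b = X.T @ s
    L = np.linalg.norm(G, 2)
    eta = 1.0 / L
    c = np.zeros(X.shape[1])
    for _ in range(n_iter):
        z = c - eta * (G @ c - b)
        if nonnegative:
            c_new = np.maximum(z - eta * lam, 0.0)
        else:
            c_new = np.sign(z) * np.maximum(np.abs(z) - eta * lam, 0.0)
        if np.max(np.abs(c_new - c)) < 1e-14:
            c = c_new
            break
        c = c_new
    return c


def lasso_objective(s: np.ndarray, X: np.ndarray, c: np.ndarray, lam: float) -> float:
    r = s - X @ c
    return 0.5 * float(r @ r) + lam * float(np.abs(c).sum())


def pls2da_oracle(X: np.ndarray, Y: np.ndarray, A: int) -> np.ndarray:
    """Minimal PLS2 on (autoscaled X, one-hot Y) via SVD weights.

    Returns the fitted Y-hat (same centering and deflation conventions as
    a standard NIPALS PLS2: weight = leading left singular vector of
    X^T Y_res, deflate both blocks by the X-score).  Predictions are
    sign-invariant, so no sign convention is needed.
    """
    Xd = X.copy()
    y_mean = Y.mean(axis=0)
    Yd = Y - y_mean
    Yhat = np.zeros_like(Yd)
    for _ in range(A):
        U, _, _ = np.linalg.svd(Xd.T @ Yd, full_matrices=False)
        w = U[:, 0]
        t = Xd @ w
        tt = float(t @ t)
        p = Xd.T @ t / tt
        c = Yd.T @ t / tt
        Xd = Xd - np.outer(t, p)
        Yd = Yd - np.outer(t, c)
        Yhat = Yhat + np.outer(t, c)
    return Yhat + y_mean
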