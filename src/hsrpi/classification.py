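"""OPLS-DA: orthogonal projections to latent structures, discriminant form.

Implemented from first principles.  Class labels are one-hot encoded into a
dummy matrix Y (n×K).  Features are autoscaled (column-wise centering and
unit-variance scaling with the sample, n−1, standard deviation; constant
columns get sd 1 and become zero columns).  The model then

1. removes ``A_ortho`` Y-orthogonal components: each round computes the
   dominant PLS2 weight ``w`` of the current (X, Yc), takes the loading of
   its score, strips the part along ``w``, and — because with a multi-column
   Y the classical single-y orthogonality guarantee does not carry over —
   projects the resulting weight onto the null space of ``Yc^T X`` so that
   the orthogonal score ``t_o = X w_o`` is *exactly* uncorrelated with every
   dummy column; X is then deflated by the orthogonal component
   (an orthogonal projection, so sum-of-squares is conserved);
2. fits ``A`` predictive PLS2 components on the filtered X by NIPALS
   (deterministic start from the largest-variance Y residual column,
   tolerance 1e-12 on the weight, max 1000 iterations), deflating both X
   and Y;
3. predicts ``Y_hat = T C^T + mean(Y)`` and assigns the argmax class (ties
   broken toward the lowest class index).

Every weight column is unit-norm with its largest-magnitude element made
positive, so fitted models (and scores plots) are sign-reproducible.
With ``A_ortho = 0`` the model is exactly a PLS2-DA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "RankError",
    "ScaledMatrix",
    "OplsDaModel",
    "Prediction",
    "autoscale",
    "apply_scaler",
    "fit_oplsda",
    "predict_oplsda",
    "scores_plot_data",
    "save_model",
    "load_model",
]

_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 1000


class RankError(ValueError):
    """Requested more components than the data can support."""


@dataclass
class ScaledMatrix:
    X: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    scaling: str = "uv"


@dataclass
class OplsDaModel:
    class_labels: list[str]
    means: np.ndarray
    sds: np.ndarray
    W_pred: np.ndarray  # p x A
    P_pred: np.ndarray  # p x A
    C: np.ndarray       # K x A
    W_ortho: np.ndarray  # p x A_ortho
    P_ortho: np.ndarray  # p x A_ortho
    T_pred: np.ndarray   # n x A (training scores)
    T_ortho: np.ndarray  # n x A_ortho
    y_mean: np.ndarray   # K
    A: int
    A_ortho: int
    ss_input: float = 0.0
    ss_ortho: float = 0.0
    ss_filtered: float = 0.0


@dataclass
class Prediction:
    predicted_label: list[str]
    predicted_Y: np.ndarray
    scores_pred: np.ndarray
    scores_ortho: np.ndarray


def autoscale(raw: np.ndarray) -> ScaledMatrix:
    """Column-wise center and unit-variance scale (sample sd, n−1).

    Constant columns are centered and their sd recorded as 1, so they map
    to all-zero columns instead of NaN.
    """
    X = np.asarray(raw, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    sds = np.where(sds == 0.0, 1.0, sds)
    return ScaledMatrix((X - means) / sds, means, sds)


def apply_scaler(model_or_scaler, raw: np.ndarray) -> np.ndarray:
    s = model_or_scaler
    X = np.asarray(raw, dtype=float)
    return (X - s.means) / s.sds


def _sign_fix(w: np.ndarray) -> float:
    """Return ±1 making the largest-|.| element of w positive."""
    i = int(np.argmax(np.abs(w)))
    return 1.0 if w[i] >= 0 else -1.0


def _dummy(labels: Sequence[str], classes: list[str]) -> np.ndarray:
    idx = {c: j for j, c in enumerate(classes)}
    Y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        Y[i, idx[lab]] = 1.0
    return Y


def _pls2_weight(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Dominant PLS2 weight of (X, Y) by NIPALS power iteration (unit norm)."""
    u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
    if not np.any(u):
        u = Y[:, 0] + 1.0
    w = None
    for _ in range(_NIPALS_MAX_ITER):
        w_new = X.T @ u
        nrm = np.linalg.norm(w_new)
        if nrm == 0:
            raise RankError("X has no covariance left with Y")
        w_new /= nrm
        t = X @ w_new
        tt = float(t @ t)
        if tt == 0:
            raise RankError("degenerate score in NIPALS")
        c = Y.T @ t / tt
        cc = float(c @ c)
        if cc == 0:
            raise RankError("Y residual exhausted in NIPALS")
        u = Y @ c / cc
        if w is not None and np.linalg.norm(w_new - w) < _NIPALS_TOL:
            w = w_new
            break
        w = w_new
    return w * _sign_fix(w)


def fit_oplsda(
    X_scaled: ScaledMatrix,
    labels: Sequence[str],
    A: int | None = None,
    A_ortho: int | None = None,
) -> OplsDaModel:
    """Fit an OPLS-DA model on an autoscaled feature matrix.

    ``A`` predictive components (1 ≤ A ≤ min(K−1, p); default
    min(K−1, p), the full discriminant rank — an argmax over a rank-A
    predicted dummy matrix can only assign winning regions to all K
    classes when A reaches K−1, so smaller A is for visualization, not
    prediction) and ``A_ortho ≥ 0`` Y-orthogonal components.  Every class
    must have at least 2 samples.

    Exactly Y-uncorrelated score directions live in the null space of
    ``Yc^T X``, which has dimension p − rank(Yc^T X) (generically
    p − (K−1)).  ``A_ortho=None`` picks min(1, that dimension) — one
    orthogonal component when the feature space has room for one, none
    otherwise (e.g. 6 classes on 5 features); an explicit request beyond
    the feasible count raises :class:`RankError`.
    """
    X = X_scaled.X.copy()
    n, p = X.shape
    classes = sorted(set(labels))
    K = len(classes)
    if K < 2:
        raise ValueError("need at least 2 classes")
    counts = {c: sum(1 for l in labels if l == c) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError(f"every class needs >= 2 samples, got {counts}")
    if A is None:
        A = min(K - 1, p)
    if A < 1 or A > min(K - 1, p):
        raise RankError(f"A must satisfy 1 <= A <= min(K-1={K-1}, p={p})")

    Y = _dummy(labels, classes)
    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean
    ss_input = float(np.sum(X**2))

    feasible_ortho = p - int(np.linalg.matrix_rank(Yc.T @ X))
    if A_ortho is None:
        A_ortho = min(1, max(0, feasible_ortho))
    if A_ortho < 0 or A_ortho > feasible_ortho:
        raise RankError(
            f"A_ortho={A_ortho} infeasible: only {feasible_ortho} exactly "
            f"Y-uncorrelated directions exist (p={p}, rank(Yc^T X)={p - feasible_ortho})"
        )

    W_o = np.zeros((p, A_ortho))
    P_o = np.zeros((p, A_ortho))
    T_o = np.zeros((n, A_ortho))
    # rows of Yc^T X span the directions whose scores correlate with class;
    # orthogonal weights are constrained to their null space (exact).
    for a in range(A_ortho):
        w = _pls2_weight(X, Yc)
        t = X @ w
        pld = X.T @ t / float(t @ t)
        w_o = pld - float(w @ pld) * w
        Acon = Yc.T @ X  # K x p
        # project w_o onto null(Acon) via least squares (rank-safe)
        if np.any(Acon):
            sol, *_ = np.linalg.lstsq(Acon.T, w_o, rcond=None)
            w_o = w_o - Acon.T @ sol
        nrm = np.linalg.norm(w_o)
        if nrm < 1e-12:
            raise RankError("no Y-orthogonal variation left to extract")
        w_o = w_o / nrm * _sign_fix(w_o)
        t_o = X @ w_o
        p_o = X.T @ t_o / float(t_o @ t_o)
        X = X - np.outer(t_o, p_o)
        W_o[:, a], P_o[:, a], T_o[:, a] = w_o, p_o, t_o

    ss_filtered = float(np.sum(X**2))

    W = np.zeros((p, A))
    P = np.zeros((p, A))
    C = np.zeros((K, A))
    T = np.zeros((n, A))
    Yd = Yc.copy()
    for a in range(A):
        w = _pls2_weight(X, Yd)
        t = X @ w
        tt = float(t @ t)
        pld = X.T @ t / tt
        c = Yd.T @ t / tt
        X = X - np.outer(t, pld)
        Yd = Yd - np.outer(t, c)
        W[:, a], P[:, a], C[:, a], T[:, a] = w, pld, c, t

    return OplsDaModel(
        class_labels=classes,
        means=X_scaled.means,
        sds=X_scaled.sds,
        W_pred=W, P_pred=P, C=C,
        W_ortho=W_o, P_ortho=P_o,
        T_pred=T, T_ortho=T_o,
        y_mean=y_mean, A=A, A_ortho=A_ortho,
        ss_input=ss_input,
        ss_ortho=ss_input - ss_filtered,
        ss_filtered=ss_filtered,
    )


def _project(model: OplsDaModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal filtering + predictive projection of (already scaled) X."""
    X = X.copy()
    T_o = np.zeros((X.shape[0], model.A_ortho))
    for a in range(model.A_ortho):
        t_o = X @ model.W_ortho[:, a]
        X = X - np.outer(t_o, model.P_ortho[:, a])
        T_o[:, a] = t_o
    T = np.zeros((X.shape[0], model.A))
    for a in range(model.A):
        t = X @ model.W_pred[:, a]
        X = X - np.outer(t, model.P_pred[:, a])
        T[:, a] = t
    return T, T_o


def predict_oplsda(model: OplsDaModel, X_new: np.ndarray) -> Prediction:
    """Scale, filter and project new raw samples; argmax-class decision."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.means.size:
        raise ValueError(
            f"expected {model.means.size} feature columns, got {X_new.shape[1]}"
        )
    Xs = apply_scaler(model, X_new)
    T, T_o = _project(model, Xs)
    Y_hat = T @ model.C.T + model.y_mean
    labels = [model.class_labels[int(j)] for j in np.argmax(Y_hat, axis=1)]
    return Prediction(predicted_label=labels, predicted_Y=Y_hat, scores_pred=T, scores_ortho=T_o)


def scores_plot_data(model: OplsDaModel, labels: Sequence[str] | None = None) -> np.ndarray:
    """(n, 2) training-score coordinates for the standard scores scatter.

    Uses the first two predictive scores; with a single predictive
    component the second coordinate falls back to the first orthogonal
    score (the usual 1+1 OPLS-DA display).
    """
    if model.A >= 2:
        coords = model.T_pred[:, :2]
    elif model.A_ortho >= 1:
        coords = np.column_stack([model.T_pred[:, 0], model.T_ortho[:, 0]])
    else:
        raise ValueError("need A >= 2 or at least one orthogonal component for a 2-D plot")
    return coords


def save_model(model: OplsDaModel, path: str | Path) -> None:
    payload = {"format_version": "1"}
    for k, v in vars(model).items():
        payload[k] = v.tolist() if isinstance(v, np.ndarray) else v
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def load_model(path: str | Path) -> OplsDaModel:
    raw = json.loads(Path(path).read_text())
    raw.pop("format_version", None)
    arrays = {
        k: np.asarray(v, dtype=float)
        for k, v in raw.items()
        if isinstance(v, list) and k != "class_labels"
    }
    rest = {k: v for k, v in raw.items() if k not in arrays}
    return OplsDaModel(**rest, **arrays)
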