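"""Pixel-wise sparsity-constrained (LASSO) spectral unmixing.

Each pixel spectrum s (C channels) is decomposed against the 4-column
reference library X by solving

    min_c  1/2 ||s - X c||^2  +  lambda * ||c||_1,   c >= 0 (default),

independently per pixel (no spatial coupling).  The solver is cyclic
coordinate descent with soft-thresholding and nonnegative clamping,
vectorized across all pixels of an image: with the 4x4 Gram matrix
G = X^T X precomputed, each coordinate update is a closed-form
soft-threshold applied to every pixel at once.  The problem is convex, so
the solution is independent of initialization (we start from zero);
iteration stops when the largest coefficient change over all pixels falls
below ``tol``.

With unit-norm library columns the all-zero solution is optimal exactly
when lambda >= max_k |x_k^T s| (``lambda_max``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .spectral_library import COMPONENTS, SpectralAxis, SpectralLibrary

__all__ = [
    "HyperspectralImage",
    "UnmixConfig",
    "ChemicalMaps",
    "lasso_unmix_pixel",
    "unmix_image",
    "lasso_objective",
    "lambda_max",
    "reconstruction_report",
    "select_lambda",
]


@dataclass
class HyperspectralImage:
    """H×W×C intensity cube with its spectral axis."""

    data: np.ndarray
    axis: "SpectralAxis"

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3 or d.shape[2] != self.axis.n_channels:
            raise ValueError("data must be H x W x C with C == axis.n_channels")
        if not np.all(np.isfinite(d)):
            raise ValueError("intensity cube contains non-finite values")
        self.data = d


@dataclass
class UnmixConfig:
    lambda_: float = 1e-3
    nonnegative: bool = True
    max_iter: int = 1000
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class ChemicalMaps:
    """Per-component abundance images plus a reconstruction-residual image.

    ``maps`` has shape (4, H, W) in the fixed library component order;
    ``residual`` is the per-pixel RMS of ``s - X c`` over channels.
    """

    maps: np.ndarray
    lambda_used: float
    residual: np.ndarray
    components: tuple[str, ...] = COMPONENTS
    n_iterations: int = 0

    def __post_init__(self) -> None:
        if self.maps.ndim != 3 or self.maps.shape[0] != len(self.components):
            raise ValueError("maps must have shape (n_components, H, W)")
        if self.residual.shape != self.maps.shape[1:]:
            raise ValueError("residual image must match map dimensions")

    def component_map(self, name: str) -> np.ndarray:
        return self.maps[self.components.index(name)]

    @property
    def total_signal(self) -> np.ndarray:
        return self.maps.sum(axis=0)


def _cd_solve(
    B: np.ndarray, G: np.ndarray, lam: float, nonnegative: bool, max_iter: int, tol: float
) -> tuple[np.ndarray, int]:
    """Cyclic coordinate descent over all rows of B simultaneously.

    B[i] = X^T s_i for pixel i; G = X^T X.  Returns (coefficients, sweeps).
    """
    n, K = B.shape
    Cf = np.zeros((n, K))
    diag = np.diag(G).copy()
    for sweep in range(max_iter):
        max_delta = 0.0
        for k in range(K):  # fixed cyclic order = library component order
            rho = B[:, k] - Cf @ G[:, k] + Cf[:, k] * diag[k]
            if nonnegative:
                new = np.maximum(rho - lam, 0.0) / diag[k]
            else:
                new = np.sign(rho) * np.maximum(np.abs(rho) - lam, 0.0) / diag[k]
            d = np.abs(new - Cf[:, k]).max(initial=0.0)
            if d > max_delta:
                max_delta = d
            Cf[:, k] = new
        if max_delta < tol:
            return Cf, sweep + 1
    return Cf, max_iter


def lasso_unmix_pixel(spectrum: np.ndarray, library: SpectralLibrary, cfg: UnmixConfig | None = None) -> np.ndarray:
    """Solve the penalized fit for one spectrum; returns the 4 abundances."""
    cfg = cfg or UnmixConfig()
    s = np.asarray(spectrum, dtype=float)
    X = library.matrix
    if s.shape != (X.shape[0],):
        raise ValueError(f"spectrum length {s.shape} does not match library channel count {X.shape[0]}")
    if not np.all(np.isfinite(s)):
        raise ValueError("spectrum contains non-finite values")
    coef, _ = _cd_solve((s @ X)[None, :], X.T @ X, cfg.lambda_, cfg.nonnegative, cfg.max_iter, cfg.tol)
    return coef[0]


def lasso_objective(spectrum: np.ndarray, library: SpectralLibrary, coef: np.ndarray, lambda_: float) -> float:
    """Penalized objective 1/2||s - Xc||^2 + lambda*||c||_1."""
    r = np.asarray(spectrum, float) - library.matrix @ np.asarray(coef, float)
    return 0.5 * float(r @ r) + lambda_ * float(np.abs(coef).sum())


def lambda_max(spectrum: np.ndarray, library: SpectralLibrary) -> float:
    """Smallest penalty at which the solution is identically zero."""
    return float(np.abs(np.asarray(spectrum, float) @ library.matrix).max())


def unmix_image(img, library: SpectralLibrary, cfg: UnmixConfig | None = None) -> ChemicalMaps:
    """Unmix every pixel of an H×W×C cube against the library.

    ``img`` is either a raw ndarray cube or an object with ``data`` and
    ``axis`` attributes; when an axis is present it must equal the library
    axis (no silent resampling).  Deterministic: no randomness anywhere in
    the solver and a fixed cyclic coordinate order.
    """
    cfg = cfg or UnmixConfig()
    if hasattr(img, "data") and hasattr(img, "axis"):
        if img.axis != library.axis:
            raise ValueError("image axis does not match library axis; resample the library explicitly")
        data = np.asarray(img.data, dtype=float)
    else:
        data = np.asarray(img, dtype=float)
    if data.ndim != 3 or data.shape[2] != library.axis.n_channels:
        raise ValueError(
            f"expected an H x W x {library.axis.n_channels} cube, got shape {data.shape}"
        )
    if not np.all(np.isfinite(data)):
        raise ValueError("image contains non-finite values")
    H, W, C = data.shape
    X = library.matrix
    S = data.reshape(-1, C)
    coef, sweeps = _cd_solve(S @ X, X.T @ X, cfg.lambda_, cfg.nonnegative, cfg.max_iter, cfg.tol)
    recon = coef @ X.T
    residual = np.sqrt(np.mean((S - recon) ** 2, axis=1)).reshape(H, W)
    maps = np.moveaxis(coef.reshape(H, W, 4), 2, 0)
    return ChemicalMaps(maps=maps, lambda_used=cfg.lambda_, residual=residual, n_iterations=sweeps)


def reconstruction_report(
    maps: ChemicalMaps,
    library: SpectralLibrary,
    img,
    saturation_level: float = 10.0,
) -> Mapping[str, float]:
    """QC summary: mean and 95th-percentile residual RMS, saturated fraction.

    A pixel counts as saturated when any coefficient reaches
    ``saturation_level`` (in units of the unit-norm-reference coefficients);
    with well-scaled data this fraction should be 0.
    """
    data = np.asarray(getattr(img, "data", img), dtype=float)
    if data.shape[:2] != maps.residual.shape:
        raise ValueError("image and maps dimensions are inconsistent")
    S = data.reshape(-1, data.shape[2])
    coef = np.moveaxis(maps.maps, 0, 2).reshape(-1, maps.maps.shape[0])
    resid = np.sqrt(np.mean((S - coef @ library.matrix.T) ** 2, axis=1))
    return {
        "mean_residual": float(resid.mean()),
        "p95_residual": float(np.percentile(resid, 95)),
        "saturated_fraction": float(np.mean(coef.max(axis=1) >= saturation_level)),
    }


def select_lambda(
    img,
    library: SpectralLibrary,
    candidates=(0.0, 1e-4, 1e-3, 1e-2, 1e-1),
    pixel_fraction: float = 0.01,
    n_folds: int = 5,
    seed: int = 0,
    cfg: UnmixConfig | None = None,
) -> float:
    """Pick lambda by k-fold cross-validated reconstruction error.

    Channels of a random pixel subsample are split into ``n_folds`` folds;
    for each candidate, coefficients are fitted on the training channels and
    scored on the held-out channels (squared error), averaged over folds and
    pixels.  Returns the candidate with the lowest CV error.
    """
    base = cfg or UnmixConfig()
    data = np.asarray(getattr(img, "data", img), dtype=float)
    S = data.reshape(-1, data.shape[-1])
    rng = np.random.default_rng(seed)
    n_pix = max(1, int(round(pixel_fraction * S.shape[0])))
    S = S[rng.choice(S.shape[0], size=n_pix, replace=False)]
    C = S.shape[1]
    perm = rng.permutation(C)
    folds = np.array_split(perm, n_folds)
    X = library.matrix
    errors = []
    for lam in candidates:
        err = 0.0
        for hold in folds:
            train = np.setdiff1d(perm, hold)
            Xt = X[train]
            coef, _ = _cd_solve(S[:, train] @ Xt, Xt.T @ Xt, lam, base.nonnegative, base.max_iter, base.tol)
            r = S[:, hold] - coef @ X[hold].T
            err += float(np.mean(r**2))
        errors.append(err / n_folds)
    return float(candidates[int(np.argmin(errors))])
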