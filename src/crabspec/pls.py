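"""PLS1 regression core: NIPALS fit, regression coefficients, RMSECV.

This is the engine shared by the wavelength selectors: a mean-centered
NIPALS fit of a single numeric response (class codes 0..K-1 when used for
classification-oriented selection), the assembled regression-coefficient
vector b with ``yhat = (x - x_mean) @ b + y_mean``, and k-fold
cross-validated RMSE over candidate component counts.

Fold assignment in :func:`rmsecv` is canonical: rows are first ranked by
a content-based lexicographic sort on (y, X), then a seeded permutation
of those ranks defines the folds, so the result does not depend on the
order in which samples are supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PLSModel", "CVResult", "fit_pls", "predict_pls", "rmsecv"]

_TINY = 1e-12


@dataclass
class PLSModel:
    """Fitted PLS1 model (centered NIPALS)."""

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # W, (p, k)
    loadings: np.ndarray  # P, (p, k)
    scores: np.ndarray  # T, (n, k)
    y_loadings: np.ndarray  # q, (k,)
    b: np.ndarray = field(repr=False)  # (p,) regression coefficients


def _nipals_path(X: np.ndarray, y: np.ndarray, max_components: int):
    """Centered NIPALS returning per-count coefficient vectors.

    Returns (x_mean, y_mean, W, P, T, q, B) where B[k] is the coefficient
    vector using k+1 components.  Stops early if X or the response is
    fully deflated (exact fit); later counts then repeat the last vector.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    yd = y - y_mean

    W = np.zeros((p, max_components))
    P = np.zeros((p, max_components))
    T = np.zeros((n, max_components))
    q = np.zeros(max_components)
    R = np.zeros((p, max_components))  # R = W (P'W)^{-1}, built by recurrence
    B = np.zeros((max_components, p))
    b = np.zeros(p)
    k_eff = 0
    for k in range(max_components):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < _TINY:
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt < _TINY:
            break
        pk = Xd.T @ t / tt
        qk = float(t @ yd) / tt
        Xd -= np.outer(t, pk)
        yd = yd - qk * t
        W[:, k], P[:, k], T[:, k], q[k] = w, pk, t, qk
        r = w - R[:, :k] @ (P[:, :k].T @ w)
        R[:, k] = r
        b = b + qk * r
        B[k] = b
        k_eff = k + 1
    for k in range(k_eff, max_components):
        B[k] = B[k_eff - 1] if k_eff else 0.0
    return x_mean, y_mean, W[:, :k_eff], P[:, :k_eff], T[:, :k_eff], q[:k_eff], B


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit a PLS1 model with the requested number of latent variables."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X and y must be row-aligned")
    n, p = X.shape
    if np.ptp(y) == 0.0:
        raise ValueError("response has zero variance")
    bound = min(n - 1, p)
    if not 1 <= n_components <= bound:
        raise ValueError(
            f"n_components must be in [1, {bound}] for shape {X.shape}, got {n_components}"
        )
    x_mean, y_mean, W, P, T, q, B = _nipals_path(X, y, n_components)
    k_eff = W.shape[1]
    return PLSModel(
        n_components=k_eff,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        loadings=P,
        scores=T,
        y_loadings=q,
        b=B[n_components - 1],
    )


def predict_pls(model: PLSModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return model.y_mean + (X - model.x_mean) @ model.b


@dataclass(frozen=True)
class CVResult:
    """RMSECV per candidate component count (index k -> k+1 components)."""

    rmsecv: np.ndarray
    best_n_components: int

    def __post_init__(self) -> None:
        r = np.asarray(self.rmsecv, dtype=float)
        object.__setattr__(self, "rmsecv", r)
        if np.any(r < 0):
            raise ValueError("RMSECV values must be >= 0")

    @property
    def best_rmsecv(self) -> float:
        return float(self.rmsecv[self.best_n_components - 1])


def _canonical_folds(X: np.ndarray, y: np.ndarray, folds: int, seed: int) -> list[np.ndarray]:
    n = len(y)
    keys = tuple(X[:, j] for j in range(X.shape[1] - 1, -1, -1)) + (y,)
    order = np.lexsort(keys)  # content-based canonical rank; y is the primary key
    rng = np.random.default_rng(seed)
    shuffled = order[rng.permutation(n)]
    return [f for f in np.array_split(shuffled, folds)]


def rmsecv(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int = 10,
    folds: int = 5,
    seed: int = 0,
    fold_indices: list[np.ndarray] | None = None,
) -> CVResult:
    """k-fold cross-validated RMSE for 1..max_components latent variables.

    ``fold_indices`` lets a caller evaluate many variable subsets of the
    same samples under one fixed fold assignment.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if not 2 <= folds <= n:
        raise ValueError(f"folds must be in [2, {n}], got {folds}")
    max_components = min(max_components, p)
    fold_idx = fold_indices if fold_indices is not None else _canonical_folds(X, y, folds, seed)
    min_train = n - max(len(f) for f in fold_idx)
    if min_train < max_components + 1:
        raise ValueError(
            f"a fold leaves only {min_train} training samples; "
            f"need >= {max_components + 1} for {max_components} components"
        )
    preds = np.zeros((max_components, n))
    for test in fold_idx:
        mask = np.ones(n, dtype=bool)
        mask[test] = False
        x_mean, y_mean, _W, _P, _T, _q, B = _nipals_path(X[mask], y[mask], max_components)
        centered = X[test] - x_mean
        preds[:, test] = y_mean + B @ centered.T
    errors = preds - y[None, :]
    curve = np.sqrt(np.mean(errors**2, axis=1))
    best = int(np.argmin(curve)) + 1
    return CVResult(rmsecv=curve, best_n_components=best)
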