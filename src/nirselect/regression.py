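"""NIPALS PLS1 and MLR calibration with cross-validation.

The PLS implementation is the classical single-response NIPALS recursion:
per component ``a``

    w_a = X'y / ||X'y||        (weights, unit norm)
    t_a = X w_a                (scores)
    p_a = X't_a / (t_a't_a)    (x-loadings)
    q_a = t_a'y / (t_a't_a)    (y-loading)
    X  <- X - t_a p_a',  y <- y - q_a t_a   (deflation)

with the regression vector in (centered) X space assembled as
``b = W (P'W)^{-1} q``.  X and y are always centered internally so every
model is self-contained — in particular inside cross-validation folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError


@dataclass
class PLSModel:
    """Fitted NIPALS PLS1 model (all arrays in preprocessed-X coordinates)."""

    n_lv: int
    W: np.ndarray          # (p, h) weight vectors, unit norm columns
    T: np.ndarray          # (n, h) scores
    P: np.ndarray          # (p, h) x-loadings
    q: np.ndarray          # (h,)  y-loadings
    b: np.ndarray          # (p,)  regression vector
    x_means: np.ndarray
    y_mean: float
    fit_rmsec: float

    @property
    def n_vars(self) -> int:
        return self.b.size

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.b.size:
            raise ValidationError(
                f"model expects {self.b.size} variables, got {X.shape[1]}"
            )
        return self.y_mean + (X - self.x_means) @ self.b


@dataclass
class MLRModel:
    """Ordinary least squares on a small set of selected variables."""

    variable_indices: np.ndarray
    coefficients: np.ndarray
    intercept: float

    @property
    def n_vars(self) -> int:
        return self.variable_indices.size

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] == self.variable_indices.size:
            cols = X
        else:
            if self.variable_indices.size and self.variable_indices.max() >= X.shape[1]:
                raise ValidationError("X has fewer columns than the stored indices")
            cols = X[:, self.variable_indices]
        return self.intercept + cols @ self.coefficients


@dataclass
class CVResult:
    """Per-complexity cross-validation errors and the chosen complexity."""

    rmsecv: np.ndarray     # indexed by LV count - 1
    rcv2: np.ndarray
    chosen_lv: int
    scheme: str

    @property
    def best_rmsecv(self) -> float:
        return float(self.rmsecv[self.chosen_lv - 1])

    @property
    def best_rcv2(self) -> float:
        return float(self.rcv2[self.chosen_lv - 1])


def _nipals(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    """NIPALS PLS1 on centered data; may stop early when covariance vanishes."""
    n, p = Xc.shape
    W = np.zeros((p, n_lv))
    T = np.zeros((n, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    Xd = Xc.copy()
    yd = yc.copy()
    scale = np.linalg.norm(Xc.T @ yc)
    h = 0
    for a in range(n_lv):
        s = Xd.T @ yd
        ns = np.linalg.norm(s)
        if ns <= max(scale, 1.0) * 1e-14:
            warnings.warn(
                f"no remaining X–y covariance after {h} latent variables; "
                f"stopping early (requested {n_lv})",
                RuntimeWarning,
                stacklevel=3,
            )
            break
        w = s / ns
        t = Xd @ w
        tt = t @ t
        if tt <= 0:
            break
        pa = Xd.T @ t / tt
        qa = (t @ yd) / tt
        Xd -= np.outer(t, pa)
        yd -= qa * t
        W[:, a], T[:, a], P[:, a], q[a] = w, t, pa, qa
        h += 1
    return W[:, :h], T[:, :h], P[:, :h], q[:h]


def _beta(W: np.ndarray, P: np.ndarray, q: np.ndarray, h: int) -> np.ndarray:
    """Regression vector using the first ``h`` components."""
    if h == 0:
        return np.zeros(W.shape[0])
    R = P[:, :h].T @ W[:, :h]
    return W[:, :h] @ np.linalg.solve(R, q[:h])


def fit_pls(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSModel:
    """Fit a PLS1 model with ``n_lv`` latent variables (centered internally)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValidationError("X and y have different sample counts")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValidationError("X and y must be finite")
    if n_lv < 1 or n_lv > min(n - 1, p):
        raise ValidationError(
            f"n_lv={n_lv} outside the valid range 1..{min(n - 1, p)}"
        )
    x_means = X.mean(axis=0)
    y_mean = float(y.mean())
    W, T, P, q = _nipals(X - x_means, y - y_mean, n_lv)
    b = _beta(W, P, q, W.shape[1])
    resid = y - (y_mean + (X - x_means) @ b)
    return PLSModel(
        n_lv=W.shape[1], W=W, T=T, P=P, q=q, b=b,
        x_means=x_means, y_mean=y_mean,
        fit_rmsec=float(np.sqrt(np.mean(resid**2))),
    )


def predict(model, X: np.ndarray) -> np.ndarray:
    """Predict with a fitted :class:`PLSModel` or :class:`MLRModel`."""
    return model.predict(X)


def _fold_indices(n: int, folds: int, scheme: str, seed: int | None):
    if scheme == "venetian":
        return [np.arange(i, n, folds) for i in range(folds)]
    if scheme == "random":
        rng = np.random.default_rng(seed)
        return [np.sort(f) for f in np.array_split(rng.permutation(n), folds)]
    raise ValidationError(f"unknown CV scheme {scheme!r}")


def cross_validate_pls(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int,
    folds: int = 10,
    scheme: str = "venetian",
    seed: int | None = None,
) -> CVResult:
    """RMSECV / Rcv² for 1..max_lv latent variables.

    Centering is refit inside each training fold.  The chosen complexity is
    the smallest LV count whose RMSECV lies within 2% of the global minimum
    (parsimony rule).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if folds < 2 or folds > n:
        raise ValidationError("folds must be between 2 and n_samples")
    assignments = _fold_indices(n, folds, scheme, seed)
    if min(len(f) for f in assignments) < 1 or n - max(len(f) for f in assignments) < 2:
        raise ValidationError("a fold leaves fewer than 2 training samples")
    max_lv_eff = min(max_lv, X.shape[1], n - max(len(f) for f in assignments) - 1)
    if max_lv_eff < 1:
        raise ValidationError("max_lv invalid for the smallest training fold")

    yhat = np.zeros((n, max_lv_eff))
    mask = np.ones(n, dtype=bool)
    for test in assignments:
        mask[:] = True
        mask[test] = False
        Xtr, ytr = X[mask], y[mask]
        xm = Xtr.mean(axis=0)
        ym = ytr.mean()
        W, T, P, q = _nipals(Xtr - xm, ytr - ym, max_lv_eff)
        Xte_c = X[test] - xm
        h_fit = W.shape[1]
        for h in range(1, max_lv_eff + 1):
            b = _beta(W, P, q, min(h, h_fit))
            yhat[test, h - 1] = ym + Xte_c @ b

    err = yhat - y[:, None]
    rmsecv = np.sqrt(np.mean(err**2, axis=0))
    sst = np.sum((y - y.mean()) ** 2)
    rcv2 = 1.0 - np.sum(err**2, axis=0) / sst
    chosen = int(np.flatnonzero(rmsecv <= 1.02 * rmsecv.min())[0]) + 1
    return CVResult(rmsecv=rmsecv, rcv2=rcv2, chosen_lv=chosen,
                    scheme=f"{scheme}:{folds}")


def fit_mlr(
    X: np.ndarray,
    y: np.ndarray,
    variable_indices=None,
) -> MLRModel:
    """Ordinary least squares on the selected columns (with intercept)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if variable_indices is None:
        variable_indices = np.arange(X.shape[1])
    idx = np.asarray(variable_indices, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= X.shape[1]):
        raise ValidationError("variable index out of range")
    n, k = X.shape[0], idx.size
    if n <= k + 1:
        raise ValidationError(
            f"need n_samples > n_variables + 1 (n={n}, variables={k})"
        )
    A = np.column_stack([np.ones(n), X[:, idx]])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < k + 1:
        # identify the offending columns by pivoted QR
        from scipy.linalg import qr

        _, R, piv = qr(A, pivoting=True, mode="economic")
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(A.shape) * np.finfo(float).eps
        dead = sorted(int(idx[j - 1]) for j in piv[diag < tol] if j > 0)
        raise ValidationError(f"collinear selected columns: {dead}")
    return MLRModel(
        variable_indices=idx,
        coefficients=coef[1:],
        intercept=float(coef[0]),
    )
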