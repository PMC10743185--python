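"""Successive projections algorithm (SPA) variable selection.

SPA builds, from each candidate start variable, a chain of variables with
minimal mutual collinearity: at every step all unselected columns are
replaced by their component orthogonal to the span of the selected ones and
the column with the largest residual norm is appended.  Each chain prefix
is then turned into an MLR model and scored by RMSE on a validation set;
the global minimum decides the start variable and the subset size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .regression import fit_mlr

_RESIDUAL_TOL = 1e-10


@dataclass
class SPAResult:
    chains: dict[int, np.ndarray]   # start column -> projection-ordered chain
    rmse_curve: np.ndarray          # validation RMSE vs subset size, winning start
    curve_sizes: np.ndarray
    chosen_indices: np.ndarray      # first chosen_size entries of the winning chain
    chosen_size: int
    winning_start: int
    rmse: float

    @property
    def n_selected(self) -> int:
        return self.chosen_size


def spa_chain(X: np.ndarray, start: int, max_vars: int) -> np.ndarray:
    """Projection chain from one start column (columns should be centered).

    Stops early when every remaining residual norm falls below 1e-10 —
    i.e. the remaining columns are linear combinations of the selected ones.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if not 0 <= start < p:
        raise ValidationError(f"start column {start} out of range 0..{p - 1}")
    if max_vars < 1 or max_vars > min(n - 1, p):
        raise ValidationError(
            f"max_vars must lie in 1..min(n-1, p) = {min(n - 1, p)}"
        )
    R = X.copy()
    chain = [start]
    available = np.ones(p, dtype=bool)
    available[start] = False
    for _ in range(max_vars - 1):
        u = R[:, chain[-1]]
        uu = u @ u
        if uu <= _RESIDUAL_TOL**2:
            break
        R = R - np.outer(u, (u @ R) / uu)   # project everything ⟂ u
        norms = np.linalg.norm(R, axis=0)
        norms[~available] = -1.0
        nxt = int(np.argmax(norms))
        if norms[nxt] < _RESIDUAL_TOL:
            break
        chain.append(nxt)
        available[nxt] = False
    return np.array(chain, dtype=int)


def spa_select(
    Xcal: np.ndarray,
    ycal: np.ndarray,
    Xval: np.ndarray,
    yval: np.ndarray,
    min_vars: int = 1,
    max_vars: int | None = None,
    starts="all",
) -> SPAResult:
    """Run SPA over candidate starts and pick the subset by validation RMSE.

    ``starts`` is ``"all"`` (every column; capped at the 200 columns most
    correlated with y when p > 2000) or an explicit index list.  Ties go to
    the smaller subset, then to the smaller start index.  The validation
    set is typically the Kennard–Stone prediction set.
    """
    Xcal = np.atleast_2d(np.asarray(Xcal, dtype=float))
    ycal = np.asarray(ycal, dtype=float).ravel()
    Xval = np.atleast_2d(np.asarray(Xval, dtype=float))
    yval = np.asarray(yval, dtype=float).ravel()
    n, p = Xcal.shape
    if Xval.shape[1] != p:
        raise ValidationError("calibration and validation widths differ")
    if min_vars < 1:
        raise ValidationError("min_vars must be >= 1")
    if max_vars is None:
        max_vars = min(30, max(n // 5, min_vars))
    max_vars = min(max_vars, n - 2, p)
    if max_vars < min_vars:
        raise ValidationError("max_vars smaller than min_vars")

    if isinstance(starts, str) and starts == "all":
        if p > 2000:
            r = np.abs(
                (Xcal - Xcal.mean(0)).T @ (ycal - ycal.mean())
            ) / np.maximum(np.linalg.norm(Xcal - Xcal.mean(0), axis=0), 1e-300)
            start_list = np.sort(np.argsort(-r, kind="stable")[:200])
        else:
            start_list = np.arange(p)
    else:
        start_list = np.asarray(starts, dtype=int)

    Xc = Xcal - Xcal.mean(axis=0)   # calibration means only
    chains: dict[int, np.ndarray] = {}
    curves: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    # RMSE differences below numerical noise count as ties (-> smaller subset)
    tie_tol = 1e-10 * max(float(np.std(yval)), 1e-30)
    best = None   # (rmse, size, start, indices)
    for start in start_list:
        chain = spa_chain(Xc, int(start), max_vars)
        chains[int(start)] = chain
        sizes, errs = [], []
        for l in range(min_vars, chain.size + 1):
            idx = chain[:l]
            try:
                model = fit_mlr(Xcal[:, idx], ycal)
            except ValidationError:
                continue   # rank-deficient prefix: skip this length
            pred = model.predict(Xval[:, idx])
            e = float(np.sqrt(np.mean((pred - yval) ** 2)))
            sizes.append(l)
            errs.append(e)
            cand = (e, l, int(start), np.array(idx))
            if best is None or e < best[0] - tie_tol or (
                e <= best[0] + tie_tol and (l, int(start)) < (best[1], best[2])
            ):
                best = cand
        curves[int(start)] = (np.array(sizes), np.array(errs))
    if best is None:
        raise ValidationError("no evaluable SPA subset (all prefixes rank-deficient)")

    e, l, start, idx = best
    sizes, errs = curves[start]
    return SPAResult(
        chains=chains,
        rmse_curve=errs,
        curve_sizes=sizes,
        chosen_indices=idx,
        chosen_size=l,
        winning_start=start,
        rmse=e,
    )
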