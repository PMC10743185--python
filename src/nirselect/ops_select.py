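"""Ordered predictors selection (OPS) and its automated variants.

OPS ranks spectral variables by the magnitude of an "informative vector" —
a per-variable importance score derived from a pilot PLS model or from
simple X–y statistics — and then evaluates growing prefixes of the ranking
by cross-validation, keeping the prefix with the lowest RMSECV.

The automated variant (autoOPS) searches over eight informative-vector
kinds (REG, COR, COV, VIP, WGHT, URXY, SQR, NAS) plus the element-wise
products of all min–max-normalized pairs, and returns the overall best
selection.  feedOPS iterates autoOPS on its own selection until it stops
improving; iOPS applies autoOPS inside contiguous spectral intervals first
and reselects from the union of the per-interval picks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .regression import _beta, _nipals, cross_validate_pls

VECTOR_KINDS = ("COR", "COV", "NAS", "REG", "SQR", "URXY", "VIP", "WGHT")


@dataclass
class InformativeVector:
    """Per-variable importance scores of a named kind (rank by |values|)."""

    kind: str
    values: np.ndarray
    h: int

    def ranking(self) -> np.ndarray:
        """Variable indices in descending |score| order (stable)."""
        return np.argsort(-np.abs(self.values), kind="stable")


@dataclass
class SubsetScore:
    indices: np.ndarray   # sorted, original coordinates
    size: int
    rmsecv: float
    rcv2: float
    n_lv: int


@dataclass
class SelectionResult:
    """Outcome of one selection run (shared by the OPS family and SPA)."""

    method: str
    ranking: np.ndarray | None
    subsets: list[SubsetScore]
    chosen_indices: np.ndarray    # sorted, original coordinates
    rmsecv: float
    rcv2: float
    vector_kind: str | None = None
    window: int | None = None
    increment: int | None = None
    extras: dict = field(default_factory=dict)

    @property
    def n_selected(self) -> int:
        return self.chosen_indices.size


@dataclass
class OPSConfig:
    """Tunables of the OPS family.

    ``h_vector``/``h_model`` default to the CV-chosen LV count of a pilot
    full-spectrum PLS model; ``window`` defaults to 10·h and ``increment``
    to p/50 (at least 1).
    """

    window: int | None = None
    increment: int | None = None
    folds: int = 10
    h_vector: int | None = None
    h_model: int | None = None
    max_lv: int = 10
    kinds: tuple[str, ...] = VECTOR_KINDS
    combinations: bool = True
    cv_scheme: str = "venetian"
    seed: int | None = None


def informative_vector(
    X: np.ndarray, y: np.ndarray, kind: str, h: int
) -> InformativeVector:
    """Compute one informative vector from centered X/y statistics.

    REG — |PLS regression coefficients|; COR — |Pearson r(x_j, y)|;
    COV — |cov(x_j, y)| (n−1); URXY — squared correlation (univariate R²);
    VIP — variable importance on projection; WGHT — y-variance-weighted
    NIPALS weight magnitudes; SQR — per-variable explained fraction of the
    h-LV reconstruction X̂ = TP'; NAS — per-column norm of the rank-1
    y-correlated approximation X b b'/||b||².
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if h < 1:
        raise ValidationError("h must be >= 1")
    kind = kind.upper()
    if kind not in VECTOR_KINDS:
        raise ValidationError(f"unknown informative-vector kind {kind!r}")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.linalg.norm(Xc, axis=0)
    sy = np.linalg.norm(yc)
    dead = sx == 0

    if kind in ("COR", "URXY"):
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Xc.T @ yc) / (sx * sy)
        r[dead] = 0.0
        values = np.abs(r) if kind == "COR" else r**2
    elif kind == "COV":
        values = np.abs(Xc.T @ yc) / (X.shape[0] - 1)
    elif kind in ("REG", "NAS", "VIP", "WGHT", "SQR"):
        h_eff = min(h, X.shape[0] - 1, X.shape[1])
        W, T, P, q = _nipals(Xc, yc, h_eff)
        b = _beta(W, P, q, W.shape[1])
        if kind == "REG":
            values = np.abs(b)
        elif kind == "NAS":
            nb2 = b @ b
            values = (np.abs(b) * np.linalg.norm(Xc @ b) / nb2
                      if nb2 > 0 else np.zeros_like(b))
        elif kind == "SQR":
            resid = Xc - T @ P.T
            with np.errstate(invalid="ignore", divide="ignore"):
                values = 1.0 - np.sum(resid**2, axis=0) / sx**2
            values[dead] = 0.0
        else:  # VIP or WGHT
            ssy = q**2 * np.einsum("ij,ij->j", T, T)   # per-LV explained y-variance
            tot = ssy.sum()
            if tot <= 0:
                values = np.zeros(X.shape[1])
            elif kind == "VIP":
                wn = W / np.linalg.norm(W, axis=0, keepdims=True)
                values = np.sqrt(X.shape[1] * (wn**2 @ ssy) / tot)
            else:
                values = np.abs(W) @ ssy / tot
    values = np.asarray(values, dtype=float)
    values[~np.isfinite(values)] = 0.0
    return InformativeVector(kind=kind, values=values, h=h)


def _prefix_sizes(p: int, window: int, increment: int) -> list[int]:
    sizes = list(range(window, p + 1, increment))
    if not sizes or sizes[-1] != p:
        sizes.append(p)
    return sizes


def ops_run(
    Xcal: np.ndarray,
    ycal: np.ndarray,
    vector: InformativeVector,
    window: int,
    increment: int,
    folds: int = 10,
    h_model: int = 5,
    cv_scheme: str = "venetian",
    seed: int | None = None,
) -> SelectionResult:
    """Evaluate the prefix schedule of one informative-vector ranking.

    Candidate subsets are the top-``window``, top-``window+increment``, …
    variables of the ranking (the full width is always included); each is
    scored by PLS cross-validation and the minimizer wins (ties toward the
    smaller subset).
    """
    Xcal = np.atleast_2d(np.asarray(Xcal, dtype=float))
    ycal = np.asarray(ycal, dtype=float).ravel()
    p = Xcal.shape[1]
    if vector.values.size != p:
        raise ValidationError("informative vector length does not match X")
    if window < 1 or increment < 1:
        raise ValidationError("window and increment must be >= 1")
    if window > p:
        raise ValidationError("window larger than the number of variables")

    order = vector.ranking()
    Xsorted = np.ascontiguousarray(Xcal[:, order])
    subsets: list[SubsetScore] = []
    for m in _prefix_sizes(p, window, increment):
        h = min(h_model, m)
        try:
            cv = cross_validate_pls(
                Xsorted[:, :m], ycal, max_lv=h, folds=folds,
                scheme=cv_scheme, seed=seed,
            )
        except ValidationError:
            continue  # subset incompatible with the fold geometry: skip
        subsets.append(
            SubsetScore(
                indices=np.sort(order[:m]),
                size=m,
                rmsecv=cv.best_rmsecv,
                rcv2=cv.best_rcv2,
                n_lv=cv.chosen_lv,
            )
        )
    if not subsets:
        raise ValidationError("no evaluable subsets in the OPS schedule")
    best = min(subsets, key=lambda s: (s.rmsecv, s.size))
    return SelectionResult(
        method="ops",
        ranking=order,
        subsets=subsets,
        chosen_indices=best.indices,
        rmsecv=best.rmsecv,
        rcv2=best.rcv2,
        vector_kind=vector.kind,
        window=window,
        increment=increment,
    )


def _resolve_config(Xcal, ycal, config: OPSConfig):
    """Fill in data-dependent defaults (pilot model LV count, window, increment)."""
    n, p = Xcal.shape
    h = config.h_model
    if h is None or config.h_vector is None:
        max_lv = min(config.max_lv, n - (n // config.folds) - 2, p)
        pilot = cross_validate_pls(
            Xcal, ycal, max_lv=max(max_lv, 1), folds=config.folds,
            scheme=config.cv_scheme, seed=config.seed,
        )
        h = config.h_model if config.h_model is not None else pilot.chosen_lv
        h_vec = config.h_vector if config.h_vector is not None else pilot.chosen_lv
    else:
        h_vec = config.h_vector
    window = config.window if config.window is not None else min(10 * h, p)
    increment = (
        config.increment if config.increment is not None else max(1, round(p / 50))
    )
    return h, h_vec, min(window, p), increment


def _minmax(values: np.ndarray) -> np.ndarray:
    v = np.abs(values)
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def candidate_vectors(
    Xcal: np.ndarray, ycal: np.ndarray, config: OPSConfig, h_vec: int
) -> list[InformativeVector]:
    """The autoOPS vector pool: the base kinds plus pairwise products."""
    base = [informative_vector(Xcal, ycal, k, h_vec) for k in config.kinds]
    vectors = list(base)
    if config.combinations:
        for va, vb in itertools.combinations(base, 2):
            vectors.append(
                InformativeVector(
                    kind=f"{va.kind}*{vb.kind}",
                    values=_minmax(va.values) * _minmax(vb.values),
                    h=h_vec,
                )
            )
    return vectors


def auto_ops(Xcal: np.ndarray, ycal: np.ndarray, config: OPSConfig | None = None) -> SelectionResult:
    """Automated OPS: try every candidate vector, keep the global best.

    Ties are broken toward fewer variables, then by vector-kind name.
    """
    Xcal = np.atleast_2d(np.asarray(Xcal, dtype=float))
    ycal = np.asarray(ycal, dtype=float).ravel()
    config = config or OPSConfig()
    h, h_vec, window, increment = _resolve_config(Xcal, ycal, config)

    results: list[SelectionResult] = []
    errors: list[str] = []
    for vec in candidate_vectors(Xcal, ycal, config, h_vec):
        try:
            results.append(
                ops_run(
                    Xcal, ycal, vec, window=window, increment=increment,
                    folds=config.folds, h_model=h,
                    cv_scheme=config.cv_scheme, seed=config.seed,
                )
            )
        except ValidationError as e:
            errors.append(f"{vec.kind}: {e}")
    if not results:
        raise ValidationError("all OPS runs failed: " + "; ".join(errors))
    best = min(results, key=lambda r: (r.rmsecv, r.n_selected, r.vector_kind))
    return replace(
        best,
        method="autoops",
        extras={"per_vector_rmsecv": {r.vector_kind: r.rmsecv for r in results}},
    )


def feed_ops(
    Xcal: np.ndarray,
    ycal: np.ndarray,
    config: OPSConfig | None = None,
    max_rounds: int = 10,
    rel_tol: float = 1e-3,
) -> SelectionResult:
    """Feedback OPS: rerun autoOPS on its own selection until convergence.

    Stops when the subset no longer changes, the RMSECV improvement falls
    below ``rel_tol`` (relative), or ``max_rounds`` is reached.
    """
    if max_rounds < 1:
        raise ValidationError("max_rounds must be >= 1")
    Xcal = np.atleast_2d(np.asarray(Xcal, dtype=float))
    ycal = np.asarray(ycal, dtype=float).ravel()
    config = config or OPSConfig()

    current = np.arange(Xcal.shape[1])
    trace: list[SelectionResult] = []
    result = None
    for _ in range(max_rounds):
        sub = auto_ops(Xcal[:, current], ycal, _shrunk(config, current.size))
        mapped = current[sub.chosen_indices]
        round_result = replace(sub, chosen_indices=mapped, ranking=current[sub.ranking])
        trace.append(round_result)
        if result is not None:
            improved = (result.rmsecv - sub.rmsecv) > rel_tol * result.rmsecv
            unchanged = np.array_equal(mapped, result.chosen_indices)
            if unchanged or not improved:
                if sub.rmsecv <= result.rmsecv:
                    result = round_result
                break
        result = round_result
        current = mapped
    return replace(result, method="feedops", extras={"rounds": trace})


def _shrunk(config: OPSConfig, p: int) -> OPSConfig:
    """Clip window/increment for a reduced variable set."""
    window = config.window
    if window is not None:
        window = min(window, p)
    return replace(config, window=window)


def i_ops(
    Xcal: np.ndarray,
    ycal: np.ndarray,
    interval_size: int,
    config: OPSConfig | None = None,
) -> SelectionResult:
    """Interval OPS: per-interval autoOPS, then reselection from the union.

    The spectrum is cut into contiguous intervals of ``interval_size``
    variables (the last may be shorter); autoOPS runs inside each, the
    selected variables are pooled into a reduced matrix, and a final
    autoOPS pass on the pool gives the result in original coordinates.
    """
    Xcal = np.atleast_2d(np.asarray(Xcal, dtype=float))
    ycal = np.asarray(ycal, dtype=float).ravel()
    config = config or OPSConfig()
    p = Xcal.shape[1]
    if interval_size < 1:
        raise ValidationError("interval_size must be >= 1")

    interval_picks: list[np.ndarray] = []
    for lo in range(0, p, interval_size):
        hi = min(lo + interval_size, p)
        cols = np.arange(lo, hi)
        sub = auto_ops(Xcal[:, cols], ycal, _shrunk(config, cols.size))
        interval_picks.append(cols[sub.chosen_indices])
    pool = np.unique(np.concatenate(interval_picks))
    final = auto_ops(Xcal[:, pool], ycal, _shrunk(config, pool.size))
    return replace(
        final,
        method="iops",
        ranking=pool[final.ranking],
        chosen_indices=pool[final.chosen_indices],
        extras={"interval_size": interval_size,
                "interval_picks": interval_picks,
                "pool_size": int(pool.size)},
    )
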