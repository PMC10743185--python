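"""Sample-set partitioning and Monte Carlo outlier detection.

Kennard–Stone picks calibration samples deterministically by max–min
Euclidean distance; the Monte Carlo scan repeatedly splits the data at
random, fits a PLS model on the training part, and accumulates signed
prediction errors per sample.  Samples whose error mean (systematic
misfit) or error spread (instability) is far above the bulk — judged on a
robust median + k·MAD scale — are flagged as outliers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import squareform, pdist
from scipy.stats import median_abs_deviation

from .errors import ValidationError
from .regression import fit_pls


@dataclass
class SplitResult:
    calibration_indices: np.ndarray
    prediction_indices: np.ndarray
    ratio: float


@dataclass
class OutlierDiagnostics:
    """Per-sample Monte Carlo prediction-error summaries."""

    mean: np.ndarray          # signed mean of accumulated errors (NaN if never tested)
    sd: np.ndarray            # sample sd of accumulated errors
    counts: np.ndarray        # test-set appearances per sample
    flagged: np.ndarray       # indices flagged by flag_outliers (empty before)
    thresholds: dict


def kennard_stone_split(X: np.ndarray, ratio: float) -> SplitResult:
    """Deterministic Kennard–Stone calibration/prediction partition.

    Seeds with the most distant pair, then repeatedly adds the sample whose
    minimum distance to the already-selected set is largest, until the
    calibration set holds ``round(ratio * n)`` samples.  Ties are broken
    toward the lowest index.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValidationError("Kennard–Stone needs at least 2 samples")
    if not 0.0 < ratio < 1.0:
        raise ValidationError("ratio must lie strictly between 0 and 1")
    n_cal = int(round(ratio * n))
    if n_cal < 2:
        raise ValidationError(f"calibration size {n_cal} too small (need >= 2)")
    if n_cal >= n:
        raise ValidationError("calibration would leave an empty prediction set")

    D = squareform(pdist(X, metric="euclidean"))
    # most distant pair; np.argmax returns the first (lowest flat index) maximum
    i, j = np.unravel_index(np.argmax(D), D.shape)
    selected = [min(i, j), max(i, j)]
    mindist = np.minimum(D[selected[0]], D[selected[1]])
    mindist[selected] = -np.inf
    while len(selected) < n_cal:
        nxt = int(np.argmax(mindist))   # first occurrence = lowest index
        selected.append(nxt)
        mindist = np.minimum(mindist, D[nxt])
        mindist[nxt] = -np.inf
    cal = np.array(sorted(selected))
    pred = np.setdiff1d(np.arange(n), cal)
    return SplitResult(calibration_indices=cal, prediction_indices=pred, ratio=ratio)


def default_iterations(train_fraction: float, target_appearances: int = 500) -> int:
    """Iteration count giving ~``target_appearances`` expected test picks per sample."""
    return math.ceil(target_appearances / (1.0 - train_fraction))


def monte_carlo_outlier_scan(
    X: np.ndarray,
    y: np.ndarray,
    iterations: int | None = None,
    train_fraction: float = 0.75,
    n_lv: int = 5,
    seed: int | None = None,
) -> OutlierDiagnostics:
    """Accumulate signed test-set prediction errors over random splits.

    Each iteration draws a uniform random ``train_fraction`` split, fits a
    PLS model (mean-centered internally) on the training part and records
    the signed errors ``y - yhat`` of the held-out samples.  With the
    default iteration count every sample is expected in the test set about
    500 times.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if y.size != n:
        raise ValidationError("X and y have different sample counts")
    if not 0.0 < train_fraction < 1.0:
        raise ValidationError("train_fraction must lie strictly between 0 and 1")
    if iterations is None:
        iterations = default_iterations(train_fraction)
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 2), n - 1)
    n_lv_eff = min(n_lv, n_train - 1, X.shape[1])
    if n_lv_eff < 1:
        raise ValidationError("n_lv must be >= 1")

    rng = np.random.default_rng(seed)
    sums = np.zeros(n)
    sumsq = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    for _ in range(iterations):
        perm = rng.permutation(n)
        train, test = perm[:n_train], perm[n_train:]
        model = fit_pls(X[train], y[train], n_lv_eff)
        err = y[test] - model.predict(X[test])
        sums[test] += err
        sumsq[test] += err**2
        counts[test] += 1

    never = counts == 0
    if never.any():
        warnings.warn(
            f"samples never selected into a test set: {np.flatnonzero(never).tolist()}",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        var = (sumsq - counts * mean**2) / np.maximum(counts - 1, 1)
        sd = np.where(counts > 1, np.sqrt(np.maximum(var, 0.0)), np.nan)
    return OutlierDiagnostics(
        mean=mean, sd=sd, counts=counts,
        flagged=np.array([], dtype=int), thresholds={},
    )


def flag_outliers(d: OutlierDiagnostics, k: float = 3.0) -> OutlierDiagnostics:
    """Flag samples with elevated |MEAN| or SD.

    A sample is flagged when ``|MEAN| > median(|MEAN|) + k * MAD(|MEAN|)``
    or ``SD > median(SD) + k * MAD(SD)``; the MAD uses the
    normal-consistent scaling (x1.4826).
    """
    absmean = np.abs(d.mean)
    thr_mean = float(
        np.nanmedian(absmean)
        + k * median_abs_deviation(absmean, scale="normal", nan_policy="omit")
    )
    thr_sd = float(
        np.nanmedian(d.sd)
        + k * median_abs_deviation(d.sd, scale="normal", nan_policy="omit")
    )
    with np.errstate(invalid="ignore"):
        bad = (absmean > thr_mean) | (d.sd > thr_sd)
    return replace(
        d,
        flagged=np.flatnonzero(np.nan_to_num(bad, nan=False)),
        thresholds={"k": k, "abs_mean": thr_mean, "sd": thr_sd},
    )
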