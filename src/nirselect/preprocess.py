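"""Spectral preprocessing operators and their composition.

All operators work on a plain (n_samples, n_wavelengths) absorbance matrix.
Column-statistic operators (mean centering, autoscaling) and MSC separate
fitting from application so that statistics estimated on a calibration set
can be replayed exactly on prediction spectra; SNV and Savitzky–Golay
filtering are per-row and stateless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.signal import savgol_filter

from .errors import ValidationError
from .spectra_io import SpectraSet

_SUPPORTED = {"mean_center", "autoscale", "snv", "msc", "savitzky_golay"}


def mean_center(X: np.ndarray, stats: np.ndarray | None = None):
    """Subtract column means.

    Returns ``(X_centered, means)``.  When ``stats`` (stored training means)
    is given those means are subtracted instead of refitting.
    """
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValidationError("cannot mean-center an empty matrix")
    if stats is None:
        stats = X.mean(axis=0)
    else:
        stats = np.asarray(stats, dtype=float).ravel()
        if stats.size != X.shape[1]:
            raise ValidationError(
                f"stored means have length {stats.size}, expected {X.shape[1]}"
            )
    return X - stats, stats


def autoscale(X: np.ndarray, stats: tuple[np.ndarray, np.ndarray] | None = None):
    """Center each column and scale to unit sample standard deviation (n-1).

    Returns ``(X_scaled, (means, sds))``.
    """
    X = np.asarray(X, dtype=float)
    if stats is None:
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1)
        bad = np.flatnonzero(sds == 0)
        if bad.size:
            raise ValidationError(f"zero-variance column(s) at index {bad.tolist()}")
        stats = (means, sds)
    else:
        means, sds = (np.asarray(a, dtype=float).ravel() for a in stats)
        if means.size != X.shape[1] or sds.size != X.shape[1]:
            raise ValidationError("stored autoscale statistics have wrong length")
        stats = (means, sds)
    return (X - stats[0]) / stats[1], stats


def snv(X: np.ndarray) -> np.ndarray:
    """Standard normal variate: each row to mean 0, sample sd 1 (row-wise)."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        raise ValidationError(f"constant spectrum in row(s) {bad.tolist()}: SNV undefined")
    return (X - mu) / sd


def msc(X: np.ndarray, reference: np.ndarray | None = None):
    """Multiplicative scatter correction against a reference spectrum.

    Each row x is regressed on the reference, x ≈ a + b·r, and replaced by
    (x − a)/b.  The default reference is the column-mean spectrum of the
    fitted matrix; pass the stored reference to transform new spectra.
    Returns ``(X_corrected, reference)``.
    """
    X = np.asarray(X, dtype=float)
    if reference is None:
        reference = X.mean(axis=0)
    reference = np.asarray(reference, dtype=float).ravel()
    if reference.size != X.shape[1]:
        raise ValidationError("MSC reference has wrong length")
    rc = reference - reference.mean()
    denom = rc @ rc
    if denom == 0:
        raise ValidationError("MSC reference has zero variance")
    # per-row OLS of x on [1, r]
    b = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
    a = X.mean(axis=1) - b * reference.mean()
    if np.any(b == 0):
        raise ValidationError("MSC slope of zero: spectrum uncorrelated with reference")
    return (X - a[:, None]) / b[:, None], reference


def savitzky_golay(
    X: np.ndarray,
    window: int,
    polyorder: int,
    deriv: int = 0,
    axis_spacing: float = 1.0,
) -> np.ndarray:
    """Savitzky–Golay smoothing / derivative along the wavelength axis.

    Output width equals input width (edge points come from evaluating the
    boundary-window polynomial fit).  For ``deriv > 0`` values are scaled by
    ``axis_spacing ** -deriv`` so derivatives are per wavelength unit.
    """
    X = np.asarray(X, dtype=float)
    if window % 2 == 0 or window <= polyorder:
        raise ValidationError("SG window must be odd and greater than polyorder")
    if deriv not in (0, 1, 2):
        raise ValidationError("deriv must be 0, 1 or 2")
    if X.shape[1] < window:
        raise ValidationError("fewer wavelengths than the SG window")
    if axis_spacing <= 0:
        raise ValidationError("axis_spacing must be positive")
    return savgol_filter(
        X, window_length=window, polyorder=polyorder, deriv=deriv,
        delta=axis_spacing, axis=1, mode="interp",
    )


@dataclass
class PreprocessConfig:
    """Ordered list of preprocessing steps, each ``(name, params)``."""

    steps: list[tuple[str, dict[str, Any]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        norm = []
        for step in self.steps:
            if isinstance(step, str):
                name, params = step, {}
            else:
                name, params = step[0], dict(step[1] or {})
            if name not in _SUPPORTED:
                raise ValidationError(
                    f"unknown preprocessing step {name!r}; supported: {sorted(_SUPPORTED)}"
                )
            if name == "savitzky_golay":
                w = int(params.get("window", 11))
                po = int(params.get("polyorder", 2))
                dv = int(params.get("deriv", 0))
                if w % 2 == 0 or w <= po:
                    raise ValidationError("SG window must be odd and > polyorder")
                if dv not in (0, 1, 2):
                    raise ValidationError("SG deriv must be in {0, 1, 2}")
                params = {"window": w, "polyorder": po, "deriv": dv}
            norm.append((name, params))
        self.steps = norm


def apply_pipeline(
    s: SpectraSet,
    cfg: PreprocessConfig,
    fitted: list | None = None,
):
    """Apply the configured steps in order.

    When ``fitted`` is None the statistics of each stateful step are
    estimated from ``s`` (calibration mode) and returned; pass the returned
    list back to replay the identical transform on prediction spectra.

    Returns ``(SpectraSet, fitted)``.
    """
    X = s.X.copy()
    fitting = fitted is None
    if fitting:
        fitted = [None] * len(cfg.steps)
    elif len(fitted) != len(cfg.steps):
        raise ValidationError("fitted statistics do not match the step list")

    for k, (name, params) in enumerate(cfg.steps):
        try:
            if name == "mean_center":
                X, st = mean_center(X, stats=fitted[k])
                if fitting:
                    fitted[k] = st
            elif name == "autoscale":
                X, st = autoscale(X, stats=fitted[k])
                if fitting:
                    fitted[k] = st
            elif name == "snv":
                X = snv(X)
            elif name == "msc":
                X, ref = msc(X, reference=fitted[k])
                if fitting:
                    fitted[k] = ref
            elif name == "savitzky_golay":
                deriv = params["deriv"]
                spacing = 1.0
                if deriv > 0:
                    d = np.diff(s.wavelengths)
                    if d.size and not np.allclose(d, d[0], rtol=1e-6):
                        raise ValidationError(
                            "non-uniform wavelength axis: SG derivative undefined"
                        )
                    spacing = float(d[0]) if d.size else 1.0
                X = savitzky_golay(
                    X, params["window"], params["polyorder"], deriv, spacing
                )
        except ValidationError as e:
            raise ValidationError(f"step {k} ({name}): {e}") from e
    return s.with_X(X), fitted
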