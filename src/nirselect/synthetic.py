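"""Synthetic FT-NIR diffuse-reflectance data with known ground truth.

Spectra are generated from a Beer–Lambert bilinear model: each chemical
component contributes a pure spectrum built from Gaussian absorption bands,
mixed by per-sample concentrations,

    X = C·S  +  baseline  +  gain ⊙ (C·S)  +  noise,

where the optional baseline is a per-sample low-order polynomial drift, the
optional gain is a per-sample multiplicative scatter distortion, and the
noise is iid Gaussian.  The default scenario emulates fresh plant tissue on
a 1000–2500 nm axis: a phenolic analyte at 0.05–0.20 mg/g, a dominant
water-like interferent with its strong ~1920 nm combination band, and two
broad nuisance components, all with overlapping bands.  The grid indices
inside the analyte's band regions are returned as the ground-truth
informative-variable set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .spectra_io import SpectraSet


@dataclass
class Band:
    """One Gaussian absorption band: amplitude·exp(−(λ−center)²/(2·width²))."""

    center: float   # nm
    width: float    # nm (Gaussian sigma)
    amplitude: float


@dataclass
class Component:
    """A chemical component: its bands and its concentration distribution.

    ``concentration`` is ``("uniform", lo, hi)`` or ``("normal", mu, sd)``;
    normal draws are clipped at zero (concentrations cannot be negative).
    """

    name: str
    bands: list[Band]
    concentration: tuple = ("uniform", 0.0, 1.0)


def _default_components() -> list[Component]:
    return [
        Component(
            "analyte",  # phenolic O-H overtone/combination bands
            bands=[Band(1440.0, 35.0, 0.55), Band(1700.0, 40.0, 0.45),
                   Band(2000.0, 40.0, 0.50)],
            concentration=("uniform", 0.05, 0.20),
        ),
        Component(
            "water",   # dominant O-H bands of fresh tissue, ~1920 nm combination
            bands=[Band(1190.0, 45.0, 0.25), Band(1450.0, 55.0, 0.90),
                   Band(1920.0, 70.0, 1.00)],
            concentration=("normal", 1.0, 0.08),
        ),
        Component(
            "carbohydrate",
            bands=[Band(1580.0, 50.0, 0.30), Band(2100.0, 60.0, 0.35),
                   Band(2320.0, 45.0, 0.30)],
            concentration=("uniform", 0.3, 0.7),
        ),
        Component(
            "protein",
            bands=[Band(1510.0, 40.0, 0.20), Band(1730.0, 45.0, 0.25),
                   Band(2180.0, 50.0, 0.30)],
            concentration=("uniform", 0.2, 0.5),
        ),
    ]


@dataclass
class SyntheticSpec:
    """Scenario description for :func:`generate_dataset`.

    Defaults are the study-scale scenario: 260 samples, 1000 grid points on
    1000–2500 nm, 4 components, analyte concentration uniform on
    [0.05, 0.20] mg/g, additive noise sd 0.001 absorbance units, baseline
    and scatter distortions off.
    """

    wl_start: float = 1000.0
    wl_stop: float = 2500.0
    n_points: int = 1000
    components: list[Component] = field(default_factory=_default_components)
    analyte_index: int = 0
    baseline_sd: tuple[float, float, float] = (0.0, 0.0, 0.0)  # poly coeff sds, deg <= 2
    scatter_sd: float = 0.0      # sd of per-sample multiplicative gain
    noise_sd: float = 0.001      # additive iid noise, absorbance units
    n_samples: int = 260
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.scatter_sd < 0:
            raise ValidationError("noise_sd and scatter_sd must be >= 0")
        if self.n_points < 2 or self.n_samples < 2:
            raise ValidationError("need at least 2 grid points and 2 samples")
        if not 0 <= self.analyte_index < len(self.components):
            raise ValidationError("analyte_index out of range")
        grid_lo, grid_hi = self.wl_start, self.wl_stop
        for comp in self.components:
            for b in comp.bands:
                if b.width <= 0:
                    raise ValidationError(f"band width must be > 0 ({comp.name})")
                if not grid_lo <= b.center <= grid_hi:
                    raise ValidationError(
                        f"band center {b.center} nm outside grid ({comp.name})"
                    )
        kind, a, b_ = self.components[self.analyte_index].concentration
        lo = a if kind == "uniform" else a - 5 * b_
        if kind == "uniform" and a <= 0:
            raise ValidationError("analyte concentration must be positive")
        del lo

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wl_start, self.wl_stop, self.n_points)

    def with_distortions(self) -> "SyntheticSpec":
        """The end-to-end demo variant: baseline drift and scatter on."""
        return replace(self, baseline_sd=(0.02, 0.01, 0.005), scatter_sd=0.05)


def pure_spectra(spec: SyntheticSpec) -> np.ndarray:
    """(n_components, n_points) pure component spectra (deterministic)."""
    wl = spec.wavelengths
    S = np.zeros((len(spec.components), spec.n_points))
    for k, comp in enumerate(spec.components):
        for b in comp.bands:
            S[k] += b.amplitude * np.exp(-((wl - b.center) ** 2) / (2.0 * b.width**2))
    return S


def truth_indices(spec: SyntheticSpec) -> np.ndarray:
    """Grid indices within ±2·width of any analyte band center."""
    wl = spec.wavelengths
    mask = np.zeros(spec.n_points, dtype=bool)
    for b in spec.components[spec.analyte_index].bands:
        mask |= np.abs(wl - b.center) <= 2.0 * b.width
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValidationError("no grid points inside the analyte bands")
    return idx


def _draw_concentration(rng: np.random.Generator, dist: tuple, n: int) -> np.ndarray:
    kind, a, b = dist
    if kind == "uniform":
        return rng.uniform(a, b, size=n)
    if kind == "normal":
        return np.clip(rng.normal(a, b, size=n), 0.0, None)
    raise ValidationError(f"unknown concentration distribution {kind!r}")


def generate_dataset(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[SpectraSet, np.ndarray]:
    """Draw one dataset; returns ``(SpectraSet with y, truth index array)``.

    The truth set depends only on the scenario geometry, not on the draw.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    S = pure_spectra(spec)
    n, p = spec.n_samples, spec.n_points
    C = np.column_stack(
        [_draw_concentration(rng, comp.concentration, n) for comp in spec.components]
    )
    X = C @ S
    if spec.scatter_sd > 0:
        gain = rng.normal(0.0, spec.scatter_sd, size=n)
        X = X + gain[:, None] * X
    if any(c > 0 for c in spec.baseline_sd):
        u = np.linspace(-1.0, 1.0, p)
        coeffs = rng.normal(0.0, spec.baseline_sd, size=(n, 3))
        X = X + coeffs @ np.vstack([np.ones(p), u, u**2])
    if spec.noise_sd > 0:
        X = X + rng.normal(0.0, spec.noise_sd, size=(n, p))
    s = SpectraSet(
        ids=[f"s{i:04d}" for i in range(n)],
        wavelengths=spec.wavelengths,
        X=X,
        y=C[:, spec.analyte_index],
        unit="nm",
    )
    return s, truth_indices(spec)


def plant_response_outliers(
    s: SpectraSet, indices, shift: float
) -> SpectraSet:
    """Return a copy with the reference value of the given samples shifted.

    Emulates gross reference-assay errors: the spectra are untouched, only
    y moves, so a calibration model systematically mispredicts the planted
    samples.
    """
    if s.y is None:
        raise ValidationError("SpectraSet has no reference values to shift")
    y = s.y.copy()
    y[np.asarray(indices, dtype=int)] += shift
    return SpectraSet(ids=list(s.ids), wavelengths=s.wavelengths.copy(),
                      X=s.X.copy(), y=y, unit=s.unit)


def band_coverage(selected_indices, spec: SyntheticSpec) -> float:
    """Fraction of truth variables whose band region holds a selected wavelength.

    A truth grid index counts as covered when at least one selected index
    falls inside the ±2·width window of a band the truth index belongs to.
    With a handful of selected wavelengths per band this saturates near 1;
    it is the recovery measure used by the selection-quality checks.
    """
    selected = np.asarray(selected_indices, dtype=int)
    wl = spec.wavelengths
    covered = 0
    total = 0
    for b in spec.components[spec.analyte_index].bands:
        in_band = np.abs(wl - b.center) <= 2.0 * b.width
        n_band = int(in_band.sum())
        total += n_band
        if selected.size and np.any(in_band[selected]):
            covered += n_band
    if total == 0:
        raise ValidationError("no truth variables in the scenario")
    return covered / total
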