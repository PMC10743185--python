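"""Delimited-text I/O for NIR spectra tables.

The on-disk dialect is a plain CSV matrix: header row ``id,<wavelength...>[,y]``,
then one row per spectrum — sample identifier, one absorbance value per
wavelength and, optionally, the reference analyte concentration in a trailing
``y`` column.  Wavelength axes may be given in nm or cm^-1; descending axes
(typical for wavenumber instruments) are reversed to ascending on load, with
the absorbance columns reversed consistently.
"""

from __future__ import annotations

import csv
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, replace

import numpy as np

from .errors import ParseError, ValidationError

#: nm <-> cm^-1 conversion constant (lambda[nm] = 1e7 / nu[cm^-1]).
WAVENUMBER_FACTOR = 1.0e7


def nm_to_wavenumber(values: np.ndarray) -> np.ndarray:
    """Convert wavelengths in nm to wavenumbers in cm^-1 (and vice versa)."""
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValidationError("wavelength/wavenumber values must be positive")
    return WAVENUMBER_FACTOR / values


def reflectance_to_absorbance(R: np.ndarray) -> np.ndarray:
    """Convert relative reflectance to absorbance, A = log10(1/R)."""
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0):
        raise ValidationError("reflectance values must be positive for log10(1/R)")
    return -np.log10(R)


@dataclass
class SpectraSet:
    """Samples x wavelengths absorbance matrix with metadata.

    Attributes
    ----------
    ids : list of str
        One identifier per sample (row of ``X``); must be unique.
    wavelengths : ndarray, shape (p,)
        Strictly ascending spectral axis.  ``unit`` records whether the
        values are nm or cm^-1.
    X : ndarray, shape (n, p)
        Absorbance matrix, log10(1/R).
    y : ndarray, shape (n,), optional
        Reference analyte concentration per sample (mg/g).
    """

    ids: list[str]
    wavelengths: np.ndarray
    X: np.ndarray
    y: np.ndarray | None = None
    unit: str = "nm"

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.wavelengths = np.asarray(self.wavelengths, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float).ravel()
        if self.unit not in ("nm", "cm-1"):
            raise ValidationError(f"unknown wavelength unit {self.unit!r}")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if self.X.shape[0] != len(self.ids):
            raise ValidationError(
                f"X has {self.X.shape[0]} rows but {len(self.ids)} ids"
            )
        if self.X.shape[1] != self.wavelengths.size:
            raise ValidationError(
                f"X has {self.X.shape[1]} columns but {self.wavelengths.size} wavelengths"
            )
        d = np.diff(self.wavelengths)
        if self.wavelengths.size > 1 and np.all(d < 0):
            # descending axis: reverse to ascending together with X columns
            self.wavelengths = self.wavelengths[::-1].copy()
            self.X = self.X[:, ::-1].copy()
            d = np.diff(self.wavelengths)
        if self.wavelengths.size > 1 and not np.all(d > 0):
            raise ValidationError("wavelength axis must be strictly monotone")
        if self.y is not None:
            if self.y.size != self.X.shape[0]:
                raise ValidationError("y length does not match number of samples")
            if not np.all(np.isfinite(self.y)):
                raise ValidationError("y contains non-finite values")
        if not np.all(np.isfinite(self.X)):
            raise ValidationError("X contains non-finite values")

    # -- convenience -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.X.shape[1]

    def subset(self, rows: Sequence[int]) -> "SpectraSet":
        """Return a new set restricted to the given sample rows."""
        rows = np.asarray(rows, dtype=int)
        return SpectraSet(
            ids=[self.ids[i] for i in rows],
            wavelengths=self.wavelengths.copy(),
            X=self.X[rows].copy(),
            y=None if self.y is None else self.y[rows].copy(),
            unit=self.unit,
        )

    def select_variables(self, cols: Sequence[int]) -> "SpectraSet":
        """Return a new set restricted to the given wavelength columns."""
        cols = np.asarray(cols, dtype=int)
        return SpectraSet(
            ids=list(self.ids),
            wavelengths=self.wavelengths[cols].copy(),
            X=self.X[:, cols].copy(),
            y=None if self.y is None else self.y.copy(),
            unit=self.unit,
        )

    def convert_unit(self) -> "SpectraSet":
        """Convert the axis between nm and cm^-1 (1e7/value), re-sorting ascending."""
        new_unit = "cm-1" if self.unit == "nm" else "nm"
        return SpectraSet(
            ids=list(self.ids),
            wavelengths=nm_to_wavenumber(self.wavelengths),
            X=self.X.copy(),
            y=None if self.y is None else self.y.copy(),
            unit=new_unit,
        )

    def with_X(self, X: np.ndarray) -> "SpectraSet":
        return replace(self, ids=list(self.ids), X=np.asarray(X, dtype=float))


def load_spectra(
    path,
    unit: str = "nm",
    reflectance: bool = False,
) -> SpectraSet:
    """Read a spectra CSV file (dialect in the module docstring).

    Parameters
    ----------
    unit : {"nm", "cm-1"}
        Unit of the wavelength header values.
    reflectance : bool
        If True the stored values are relative reflectance and are converted
        to absorbance log10(1/R) on load.
    """
    with open(path, "r", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if not header or header[0].strip().lower() != "id":
            raise ParseError(f"{path}: header must start with 'id'")
        has_y = len(header) > 1 and header[-1].strip().lower() == "y"
        wl_tokens = header[1 : -1 if has_y else None]
        if not wl_tokens:
            raise ParseError(f"{path}: header contains no wavelengths")
        try:
            wavelengths = np.array([float(t) for t in wl_tokens])
        except ValueError as e:
            raise ParseError(f"{path}: non-numeric wavelength in header: {e}") from None

        ncol = len(header)
        ids: list[str] = []
        rows: list[list[float]] = []
        yvals: list[float] = []
        for lineno, rec in enumerate(reader, start=2):
            if not rec:
                continue
            if len(rec) != ncol:
                raise ParseError(
                    f"{path}: line {lineno}: expected {ncol} fields, got {len(rec)}"
                )
            ids.append(rec[0])
            body = rec[1 : -1 if has_y else None]
            try:
                rows.append([float(t) for t in body])
                if has_y:
                    yvals.append(float(rec[-1]))
            except ValueError as e:
                raise ParseError(f"{path}: line {lineno}: non-numeric value: {e}") from None
    if not rows:
        raise ParseError(f"{path}: no data rows")
    X = np.array(rows)
    if reflectance:
        X = reflectance_to_absorbance(X)
    return SpectraSet(
        ids=ids,
        wavelengths=wavelengths,
        X=X,
        y=np.array(yvals) if has_y else None,
        unit=unit,
    )


def save_spectra(s: SpectraSet, path) -> None:
    """Write a SpectraSet in the CSV dialect read by :func:`load_spectra`.

    Wavelengths are printed with up to 6 significant digits; absorbance and
    y values use shortest round-trip representation, so load(save(s))
    reproduces ``X`` and ``y`` exactly.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        header = ["id"] + [f"{w:.6g}" for w in s.wavelengths]
        if s.y is not None:
            header.append("y")
        writer.writerow(header)
        for i, sid in enumerate(s.ids):
            row = [sid] + [repr(float(v)) for v in s.X[i]]
            if s.y is not None:
                row.append(repr(float(s.y[i])))
            writer.writerow(row)


def average_replicates(s: SpectraSet, groups: Mapping[str, str]) -> SpectraSet:
    """Average replicate spectra into one spectrum per sample.

    ``groups`` maps each replicate id (a row of ``s``) to its sample id.
    Reference values, when present, must agree within a group.
    """
    missing = [i for i in s.ids if i not in groups]
    if missing:
        raise ValidationError(f"replicates missing from groups: {missing}")
    order: list[str] = []
    members: dict[str, list[int]] = {}
    for row, rid in enumerate(s.ids):
        g = str(groups[rid])
        if g not in members:
            members[g] = []
            order.append(g)
        members[g].append(row)

    X = np.empty((len(order), s.n_wavelengths))
    y = np.empty(len(order)) if s.y is not None else None
    for k, g in enumerate(order):
        rows = members[g]
        X[k] = s.X[rows].mean(axis=0)
        if y is not None:
            vals = s.y[rows]
            if not np.allclose(vals, vals[0], rtol=0, atol=1e-12):
                raise ValidationError(
                    f"conflicting reference values within group {g!r}: {vals.tolist()}"
                )
            y[k] = vals[0]
    return SpectraSet(ids=order, wavelengths=s.wavelengths.copy(), X=X, y=y, unit=s.unit)
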