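"""Calibration-model evaluation statistics and the summary report.

The figures of merit are the standard multivariate-calibration set:

    R²    = 1 − Σ(yᵢ−ŷᵢ)² / Σ(yᵢ−ȳ)²
    RMSE  = sqrt( Σ(ŷᵢ−yᵢ)² / n )
    RPD   = SD(y_ref of the prediction set) / RMSEP       (sd with n−1)
    RER   = range(y_ref) / RMSEP
    RE%   = (yᵢ−ŷᵢ)/yᵢ · 100  per sample

together with SEP/SEC = RMSEP/RMSEC as a robustness ratio.  An RPD above 2
is conventionally read as an acceptable quantitative model; above 3 as good.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields

import numpy as np

from .errors import ValidationError
from .spectra_io import SpectraSet


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size or y.size < 2:
        raise ValidationError("r_squared needs two equal-length vectors, n >= 2")
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0:
        raise ValidationError("constant reference values: R² undefined")
    return float(1.0 - np.sum((y - yhat) ** 2) / sst)


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size or y.size < 1:
        raise ValidationError("rmse needs two equal-length, nonempty vectors")
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def rpd(y_reference: np.ndarray, rmsep: float) -> float:
    """Ratio of performance to deviation: sd(y_reference, n−1) / RMSEP."""
    y_reference = np.asarray(y_reference, dtype=float).ravel()
    if y_reference.size < 2:
        raise ValidationError("RPD needs at least 2 reference values")
    if rmsep <= 0:
        raise ValidationError("RPD undefined for RMSEP <= 0")
    return float(np.std(y_reference, ddof=1) / rmsep)


def rer(y_reference: np.ndarray, rmsep: float) -> float:
    """Range error ratio: (max − min of y_reference) / RMSEP."""
    y_reference = np.asarray(y_reference, dtype=float).ravel()
    if y_reference.size < 2:
        raise ValidationError("RER needs at least 2 reference values")
    if rmsep <= 0:
        raise ValidationError("RER undefined for RMSEP <= 0")
    return float((y_reference.max() - y_reference.min()) / rmsep)


def relative_errors(y: np.ndarray, yhat: np.ndarray) -> np.ndarray:
    """Per-sample relative error (y − ŷ)/y · 100 (%)."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValidationError("relative_errors needs equal-length vectors")
    zero = np.flatnonzero(y == 0)
    if zero.size:
        raise ValidationError(f"zero reference value at sample(s) {zero.tolist()}")
    return (y - yhat) / y * 100.0


@dataclass
class EvalReport:
    """Calibration/prediction statistics in the conventional table layout."""

    n_cal: int
    n_pred: int
    n_vars: int
    rc2: float
    rmsec: float
    rp2: float
    rmsep: float
    rpd: float
    rer: float
    sep_over_sec: float
    rcv2: float | None = None
    rmsecv: float | None = None
    lvs: int | None = None
    re_cal: np.ndarray | None = None
    re_pred: np.ndarray | None = None

    def to_csv(self, path) -> None:
        """One-row CSV; vector fields are ';'-joined at 6 significant digits."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            names = [f.name for f in fields(self)]
            writer.writerow(names)
            row = []
            for name in names:
                v = getattr(self, name)
                if v is None:
                    row.append("")
                elif isinstance(v, np.ndarray):
                    row.append(";".join(f"{x:.6g}" for x in v))
                elif isinstance(v, float):
                    row.append(f"{v:.6g}")
                else:
                    row.append(str(v))
            writer.writerow(row)

    @classmethod
    def from_csv(cls, path) -> "EvalReport":
        with open(path, "r", newline="") as fh:
            reader = csv.reader(fh)
            names = next(reader)
            values = next(reader)
        kwargs = {}
        for name, raw in zip(names, values):
            if raw == "":
                kwargs[name] = None
            elif name.startswith("re_"):
                kwargs[name] = np.array([float(t) for t in raw.split(";")])
            elif name.startswith("n_") or name == "lvs":
                kwargs[name] = int(raw)
            else:
                kwargs[name] = float(raw)
        return cls(**kwargs)

    def to_markdown(self) -> str:
        """Conventional report row: R²/RMSE at 4 d.p., RPD/RER/SEP-SEC at 2 d.p."""
        head = (
            "| nVars | LVs | Rc2 | RMSEC | Rp2 | RMSEP | RPD | RER | SEP/SEC |\n"
            "|---|---|---|---|---|---|---|---|---|\n"
        )
        lvs = "-" if self.lvs is None else str(self.lvs)
        return head + (
            f"| {self.n_vars} | {lvs} | {self.rc2:.4f} | {self.rmsec:.4f} "
            f"| {self.rp2:.4f} | {self.rmsep:.4f} | {self.rpd:.2f} "
            f"| {self.rer:.2f} | {self.sep_over_sec:.2f} |"
        )


def evaluate(model, cal: SpectraSet, pred: SpectraSet, cv=None) -> EvalReport:
    """Assemble the full report from a fitted model and the two sample sets.

    ``cal`` and ``pred`` must carry the same preprocessing lineage the model
    was trained on, and both need reference values.
    """
    if cal.y is None or pred.y is None:
        raise ValidationError("both sets need reference values for evaluation")
    yc_hat = model.predict(cal.X)
    yp_hat = model.predict(pred.X)
    rmsec_v = rmse(cal.y, yc_hat)
    rmsep_v = rmse(pred.y, yp_hat)
    return EvalReport(
        n_cal=cal.n_samples,
        n_pred=pred.n_samples,
        n_vars=model.n_vars,
        rc2=r_squared(cal.y, yc_hat),
        rmsec=rmsec_v,
        rp2=r_squared(pred.y, yp_hat),
        rmsep=rmsep_v,
        rpd=rpd(pred.y, rmsep_v),
        rer=rer(pred.y, rmsep_v),
        sep_over_sec=rmsep_v / rmsec_v if rmsec_v > 0 else float("inf"),
        rcv2=None if cv is None else cv.best_rcv2,
        rmsecv=None if cv is None else cv.best_rmsecv,
        lvs=getattr(model, "n_lv", None),
        re_cal=relative_errors(cal.y, yc_hat),
        re_pred=relative_errors(pred.y, yp_hat),
    )
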