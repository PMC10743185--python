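"""End-to-end calibration workflow with logged provenance.

Fixed stage order: Monte Carlo outlier scan → preprocessing → Kennard–Stone
split → variable-selection chain (OPS variant and/or SPA) → PLS or MLR fit
→ evaluation report.  A manifest (config, config hash, seed, stage log)
and all intermediate artifacts are written to the output directory; reruns
with the same config and seed are byte-identical.

Leakage policy: the Kennard–Stone distances are computed on a provisional
whole-set preprocessing pass, but the preprocessing statistics actually
used for modeling are re-fit on the calibration rows only and replayed on
the prediction rows.  The one documented exception is SPA's
validation-set-driven subset choice, which scores candidate subsets on the
prediction set (the historical definition of the method).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .errors import ValidationError
from .metrics import EvalReport, evaluate
from .ops_select import OPSConfig, SelectionResult, auto_ops, feed_ops, i_ops
from .preprocess import PreprocessConfig, apply_pipeline
from .regression import cross_validate_pls, fit_mlr, fit_pls
from .sampling import flag_outliers, kennard_stone_split, monte_carlo_outlier_scan
from .spa_select import spa_select
from .spectra_io import load_spectra, save_spectra
from .synthetic import SyntheticSpec, generate_dataset

_SELECTIONS = ("none", "autoops", "feedops", "iops", "spa",
               "autoops+spa", "feedops+spa", "iops+spa")


@dataclass
class WorkflowConfig:
    """Everything needed to reproduce one workflow run."""

    input_path: str | None = None          # spectra CSV with a y column, or
    synthetic: SyntheticSpec | None = None  # a generator scenario
    preprocess_steps: list = field(default_factory=lambda: [("mean_center", {})])
    split_ratio: float = 0.75
    outlier_scan: bool = True
    outlier_iterations: int | None = None
    outlier_train_fraction: float = 0.75
    outlier_n_lv: int = 5
    outlier_k: float = 3.0
    selection: str = "none"
    ops: OPSConfig = field(default_factory=OPSConfig)
    iops_interval: int = 100
    spa_min_vars: int = 2
    spa_max_vars: int | None = None
    model: str = "pls"
    n_lv: int | None = None               # None: choose by cross-validation
    max_lv: int = 10
    cv_folds: int = 10
    cv_scheme: str = "venetian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.selection not in _SELECTIONS:
            raise ValidationError(
                f"selection must be one of {_SELECTIONS}, got {self.selection!r}"
            )
        if self.model not in ("pls", "mlr"):
            raise ValidationError("model must be 'pls' or 'mlr'")
        if self.model == "mlr" and self.selection == "none":
            raise ValidationError("MLR requires a variable-selection stage")
        if self.input_path is None and self.synthetic is None:
            raise ValidationError("provide input_path or a synthetic scenario")


@dataclass
class WorkflowResult:
    report: EvalReport
    selections: list[SelectionResult]
    selected_indices: np.ndarray
    outlier_indices: np.ndarray
    manifest: dict
    outdir: Path | None


def _to_jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def config_hash(cfg: WorkflowConfig) -> str:
    blob = json.dumps(_to_jsonable(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_workflow(cfg: WorkflowConfig, outdir=None) -> WorkflowResult:
    """Execute the full workflow; optionally persist artifacts to ``outdir``."""
    log: list[str] = []

    # ---- data ----------------------------------------------------------
    if cfg.input_path is not None:
        data = load_spectra(cfg.input_path)
        if data.y is None:
            raise ValidationError("input file has no reference (y) column")
    else:
        data, _truth = generate_dataset(cfg.synthetic, seed=cfg.seed)
    log.append(f"data: {data.n_samples} samples x {data.n_wavelengths} variables")

    # ---- Monte Carlo outlier scan (on mean-centered spectra) -----------
    outliers = np.array([], dtype=int)
    if cfg.outlier_scan:
        diag = monte_carlo_outlier_scan(
            data.X, data.y,
            iterations=cfg.outlier_iterations,
            train_fraction=cfg.outlier_train_fraction,
            n_lv=cfg.outlier_n_lv,
            seed=cfg.seed,
        )
        diag = flag_outliers(diag, k=cfg.outlier_k)
        outliers = diag.flagged
        if outliers.size:
            keep = np.setdiff1d(np.arange(data.n_samples), outliers)
            data = data.subset(keep)
        log.append(f"outliers: removed {outliers.size} -> {data.n_samples} samples")

    # ---- preprocessing + Kennard–Stone split ---------------------------
    prep = PreprocessConfig(steps=list(cfg.preprocess_steps))
    provisional, _ = apply_pipeline(data, prep)          # for KS distances only
    split = kennard_stone_split(provisional.X, cfg.split_ratio)
    cal_raw = data.subset(split.calibration_indices)
    pred_raw = data.subset(split.prediction_indices)
    cal, fitted = apply_pipeline(cal_raw, prep)          # stats from calibration only
    pred, _ = apply_pipeline(pred_raw, prep, fitted=fitted)
    log.append(
        f"split: {cal.n_samples} calibration / {pred.n_samples} prediction "
        f"(ratio {cfg.split_ratio})"
    )

    # ---- variable-selection chain --------------------------------------
    selections: list[SelectionResult] = []
    selected = np.arange(cal.n_wavelengths)
    stages = [s for s in cfg.selection.split("+") if s != "none"]
    for stage in stages:
        Xs = cal.X[:, selected]
        if stage == "autoops":
            res = auto_ops(Xs, cal.y, cfg.ops)
        elif stage == "feedops":
            res = feed_ops(Xs, cal.y, cfg.ops)
        elif stage == "iops":
            res = i_ops(Xs, cal.y, cfg.iops_interval, cfg.ops)
        elif stage == "spa":
            spa = spa_select(
                Xs, cal.y, pred.X[:, selected], pred.y,
                min_vars=cfg.spa_min_vars, max_vars=cfg.spa_max_vars,
            )
            res = SelectionResult(
                method="spa", ranking=None, subsets=[],
                chosen_indices=np.sort(spa.chosen_indices),
                rmsecv=spa.rmse, rcv2=float("nan"),
                extras={"winning_start": spa.winning_start,
                        "rmse_curve": spa.rmse_curve,
                        "curve_sizes": spa.curve_sizes},
            )
        else:  # pragma: no cover - guarded by WorkflowConfig
            raise ValidationError(f"unknown selection stage {stage!r}")
        prev = selected.size
        selected = selected[res.chosen_indices]
        selections.append(res)
        log.append(f"{stage}: {prev} -> {selected.size} variables")

    cal_sel = cal.select_variables(selected)
    pred_sel = pred.select_variables(selected)

    # ---- model fit + evaluation ----------------------------------------
    if cfg.model == "pls":
        max_lv = min(cfg.max_lv, cal_sel.n_samples - 1, cal_sel.n_wavelengths)
        cv = cross_validate_pls(
            cal_sel.X, cal_sel.y, max_lv=max_lv, folds=cfg.cv_folds,
            scheme=cfg.cv_scheme, seed=cfg.seed,
        )
        n_lv = cfg.n_lv if cfg.n_lv is not None else cv.chosen_lv
        model = fit_pls(cal_sel.X, cal_sel.y, min(n_lv, max_lv))
        log.append(f"pls: {model.n_lv} latent variables")
    else:
        if cal_sel.n_samples <= cal_sel.n_wavelengths + 1:
            raise ValidationError(
                "MLR needs n_cal > n_vars + 1 after selection "
                f"({cal_sel.n_samples} samples, {cal_sel.n_wavelengths} variables)"
            )
        model = fit_mlr(cal_sel.X, cal_sel.y)
        cv = None
        log.append(f"mlr: {cal_sel.n_wavelengths} variables")
    report = evaluate(model, cal_sel, pred_sel, cv=cv)

    manifest = {
        "package": "nirselect",
        "version": __version__,
        "seed": cfg.seed,
        "config": _to_jsonable(cfg),
        "config_sha256": config_hash(cfg),
        "stages": log,
        "selected_wavelengths_nm": cal.wavelengths[selected].tolist(),
        "outliers_removed": outliers.tolist(),
    }

    out = None
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "report.csv")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(out / "selected_wavelengths.csv", "w") as fh:
            fh.write("index,wavelength\n")
            for i, w in zip(selected, cal.wavelengths[selected]):
                fh.write(f"{i},{w:.6g}\n")
        _save_model(model, out / "model.txt")
        save_spectra(cal_sel, out / "calibration_preprocessed.csv")
        save_spectra(pred_sel, out / "prediction_preprocessed.csv")

    return WorkflowResult(
        report=report,
        selections=selections,
        selected_indices=selected,
        outlier_indices=outliers,
        manifest=manifest,
        outdir=out,
    )


def _save_model(model, path) -> None:
    """Plain-text parameter file (documented, human-readable)."""
    with open(path, "w") as fh:
        if hasattr(model, "b"):   # PLS
            fh.write(f"type pls\nn_lv {model.n_lv}\ny_mean {model.y_mean!r}\n")
            fh.write("x_means " + " ".join(repr(float(v)) for v in model.x_means) + "\n")
            fh.write("b " + " ".join(repr(float(v)) for v in model.b) + "\n")
        else:                      # MLR
            fh.write(f"type mlr\nintercept {model.intercept!r}\n")
            fh.write("indices " + " ".join(str(i) for i in model.variable_indices) + "\n")
            fh.write("coefficients "
                     + " ".join(repr(float(v)) for v in model.coefficients) + "\n")
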