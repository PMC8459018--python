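"""End-to-end orchestration: simulate -> calibrate -> segment -> select -> train -> validate -> report.

A single :class:`RunConfig` (YAML-serializable) drives the whole analysis
with one seed. The imaging path streams scene by scene — render, two-point
calibrate, classify, extract ROIs, average the rotated duplicate — so raw
cubes never need to be held or persisted together; the fast path skips the
imaging stage and simulates per-kernel mean spectra directly.

Per analyte, every configured pretreatment code is swept and only the model
with the best cross-validation error (lowest SECV; configurable to lowest
SEP) is kept. Reports mirror the usual NIR calibration tables: one row per
analyte with pretreatment, T outliers, factor count, applicability range
and SEC/RSQ/SECV/SEP (+ percent forms), plus a variety-level summary of the
predictions on the non-selected samples with ANOVA/Tukey letters.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import composition, mpls, segmentation, selection, valstats
from .cube import absorbance_from_raw
from .simulate import (
    NoiseConfig,
    assay_panel,
    default_band_grid,
    default_signatures,
    generate_reference_panel,
    generate_scene,
    generate_spectra,
    scene_batches,
    spectra_matrix,
)
from .varieties import IMAGED_KERNEL_COUNTS, PRETREATMENT_SWEEP, WALNUT_PROFILES

log = logging.getLogger("nutspec.pipeline")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run (defaults = study settings)."""

    seed: int = 1
    n_per_variety: dict | int | None = None   # None -> imaged kernel counts
    imaging: bool = True
    scene_shape: tuple[int, int] = (256, 320)
    area_range: tuple[float, float] = (300.0, 900.0)
    group_size: int = 10
    subrange: tuple[float, float] = (950.0, 1650.0)
    analytes: tuple[str, ...] = ("total_fat", "SFA", "MUFA", "PUFA")
    codes: tuple[str, ...] = PRETREATMENT_SWEEP
    selection_code: str = "SNV 2,5,5,1"
    var_target: float = 0.99
    h_threshold: float = 3.0
    nh_threshold: float = 0.9
    t_threshold: float = 2.5
    n_folds: int = 6
    f_max: int | None = None
    alpha: float = 0.05
    model_choice: str = "secv"
    lda_pixels_per_class: int = 1500
    min_roi_area: int = 50
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    def __post_init__(self) -> None:
        if not self.analytes:
            raise ValueError("analyte list is empty")
        if self.model_choice not in ("secv", "sep"):
            raise ValueError("model_choice must be 'secv' or 'sep'")
        if isinstance(self.noise, dict):
            self.noise = NoiseConfig(**self.noise)
        self.scene_shape = tuple(self.scene_shape)
        self.area_range = tuple(float(v) for v in self.area_range)
        self.subrange = tuple(self.subrange)
        self.analytes = tuple(self.analytes)
        self.codes = tuple(self.codes)

    @property
    def counts(self) -> dict | int:
        return IMAGED_KERNEL_COUNTS if self.n_per_variety is None else self.n_per_variety

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["noise"] = dataclasses.asdict(self.noise)
        payload["scene_shape"] = list(self.scene_shape)
        payload["area_range"] = list(self.area_range)
        payload["subrange"] = list(self.subrange)
        payload["analytes"] = list(self.analytes)
        payload["codes"] = list(self.codes)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)


def simulate_panel(cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """True-composition panel plus its assay-noise-overlaid measured twin."""
    counts = cfg.counts
    profiles = WALNUT_PROFILES
    if isinstance(counts, dict):  # a partial dict selects those varieties only
        profiles = tuple(p for p in WALNUT_PROFILES if p.name in counts)
    panel = generate_reference_panel(profiles, counts, cfg.seed)
    measured = assay_panel(panel, cfg.noise, cfg.seed)
    return panel, measured


def train_segmentation_lda(cube_abs, truth_mask, n_per_class: int, seed: int):
    """Fit the stepwise LDA on labelled pixels sampled from one scene."""
    rng = np.random.default_rng([int(seed), 404])
    flat = cube_abs.data.reshape(-1, cube_abs.n_bands)
    labels = (np.asarray(truth_mask) > 0).ravel()
    picks = []
    for cls in (0, 1):
        idx = np.nonzero(labels == cls)[0]
        take = min(n_per_class, idx.size)
        picks.append(rng.choice(idx, size=take, replace=False))
    sel = np.concatenate(picks)
    return segmentation.train_stepwise_lda(
        flat[sel], labels[sel].astype(int), cube_abs.wavelengths
    )


def _acquisition_spectra(acq, lda, cfg):
    """Classify one acquisition and return {sample_id: mean spectrum} + diag."""
    cube = absorbance_from_raw(acq.raw, acq.frames, *cfg.subrange)
    mask = segmentation.classify_pixels(lda, cube)
    truth = acq.truth.mask > 0
    accuracy = float((mask.astype(bool) == truth).mean())
    rois = segmentation.extract_objects(mask, cfg.min_roi_area)
    roi_to_truth = segmentation.match_rois_to_truth(rois, acq.truth.mask)
    spectra = {
        acq.truth.sample_ids[roi_to_truth[roi.kernel_id]]: segmentation.mean_spectrum(cube, roi)
        for roi in rois
    }
    return spectra, cube.wavelengths, accuracy, len(rois)


def imaged_spectra(cfg: RunConfig, panel: pd.DataFrame):
    """Stream scenes through calibration + segmentation; returns spectra + diagnostics."""
    signatures = default_signatures(default_band_grid())
    records, diagnostics = [], []
    lda = None
    wl = None
    for scene_no, rows in enumerate(scene_batches(panel, cfg.group_size)):
        pair = generate_scene(
            rows, signatures, cfg.noise, seed=cfg.seed * 10_000 + scene_no,
            shape=cfg.scene_shape, area_range=cfg.area_range,
        )
        if lda is None:
            first_abs = absorbance_from_raw(pair.a.raw, pair.a.frames, *cfg.subrange)
            lda = train_segmentation_lda(
                first_abs, pair.a.truth.mask, cfg.lda_pixels_per_class, cfg.seed
            )
            log.info("stepwise LDA selected wavelengths: %s",
                     np.round(lda.selected_wavelengths, 2).tolist())
        merged: dict[str, np.ndarray] = {}
        for tag, acq in (("a", pair.a), ("b", pair.b)):
            spectra, wl, accuracy, n_rois = _acquisition_spectra(acq, lda, cfg)
            diagnostics.append(
                {"scene": scene_no, "acquisition": tag, "pixel_accuracy": accuracy,
                 "kernels_found": n_rois, "kernels_true": len(rows)}
            )
            for sid, spec in spectra.items():
                merged.setdefault(sid, []).append(spec)
        for _, row in rows.iterrows():
            sid = row["sample_id"]
            if sid not in merged:
                raise RuntimeError(f"kernel {sid} lost during segmentation")
            spec = np.mean(merged[sid], axis=0)
            records.append({"sample_id": sid, "variety": row["variety"],
                            **{f"{w:.2f}": v for w, v in zip(wl, spec)}})
    return pd.DataFrame(records), pd.DataFrame(diagnostics), lda


def select_spectra(cfg: RunConfig, spectra_table: pd.DataFrame):
    """Pretreat with the selection code and run H/NH sample selection."""
    from .pretreat import FittedPretreatment, parse_code

    X, wl = spectra_matrix(spectra_table)
    fp = FittedPretreatment(parse_code(cfg.selection_code))
    Xp, _ = fp.fit(X, wl)
    result = selection.select_samples(
        Xp, cfg.var_target, cfg.h_threshold, cfg.nh_threshold
    )
    labels = result.set_labels(len(spectra_table))
    group_of = {}
    for gi, grp in enumerate(result.groups):
        for m in grp.members:
            group_of[m] = gi
    frame = pd.DataFrame(
        {"sample_id": spectra_table["sample_id"], "variety": spectra_table["variety"],
         "h": result.h_values, "group": [group_of.get(i, -1) for i in range(len(labels))],
         "set": labels}
    )
    return result, frame


def _split(spectra_table, sel_frame, measured_panel):
    X, wl = spectra_matrix(spectra_table)
    chem = measured_panel.set_index("sample_id")
    ids = spectra_table["sample_id"].to_numpy()
    out = {}
    for name in ("CAL", "VAL"):
        mask = (sel_frame["set"] == name).to_numpy()
        out[name] = (X[mask], ids[mask])
    return out, wl, chem


def train_models(cfg: RunConfig, spectra_table, measured_panel, sel_frame):
    """Sweep pretreatment codes per analyte; keep the best model by SECV/SEP."""
    sets, wl, chem = _split(spectra_table, sel_frame, measured_panel)
    X_cal, ids_cal = sets["CAL"]
    X_val, ids_val = sets["VAL"]
    models = {}
    for analyte in cfg.analytes:
        if analyte not in chem.columns:
            raise ValueError(f"unknown analyte {analyte!r}")
        y_cal = chem.loc[ids_cal, analyte].to_numpy(dtype=float)
        best = None
        for code in cfg.codes:
            model = mpls.fit(
                X_cal, wl, y_cal, code=code, f_max=cfg.f_max, n_folds=cfg.n_folds,
                t_threshold=cfg.t_threshold, seed=cfg.seed, analyte=analyte,
            )
            if cfg.model_choice == "sep" and len(ids_val) >= 3:
                y_val = chem.loc[ids_val, analyte].to_numpy(dtype=float)
                score, _, _ = valstats.sep(y_val, model.predict(X_val, wl))
            else:
                score = model.secv
            if best is None or score < best[0]:
                best = (score, model)
        models[analyte] = best[1]
        log.info("%s: best code %s, %d factors, SECV %.4f",
                 analyte, best[1].pretreatment.code.serialize(), best[1].n_factors,
                 best[1].secv)
    return models


def validate_models(cfg: RunConfig, models, spectra_table, measured_panel, sel_frame):
    """External validation of the kept models; one report row per analyte."""
    sets, wl, chem = _split(spectra_table, sel_frame, measured_panel)
    X_cal, ids_cal = sets["CAL"]
    X_val, ids_val = sets["VAL"]
    reports = []
    for analyte, model in models.items():
        y_cal = chem.loc[ids_cal, analyte].to_numpy(dtype=float)
        y_val = chem.loc[ids_val, analyte].to_numpy(dtype=float)
        if len(ids_val) >= 3:
            y_hat_val = model.predict(X_val, wl)
        else:  # too few validation kernels for an external SEP
            log.warning("%s: only %d validation samples; SEP not estimated",
                        analyte, len(ids_val))
            y_val = np.arange(3, dtype=float)
            y_hat_val = np.full(3, np.nan)
        report = valstats.build_report(model, y_cal[model.kept_indices], y_val, y_hat_val)
        reports.append(report)
        log.info("%s: SEP %.4f (bias %.4f)", analyte, report.sep, report.bias)
    return reports


def predict_nonselected(cfg, models, spectra_table, sel_frame):
    """Apply the kept models to the non-selected kernels (screening use-case)."""
    X, wl = spectra_matrix(spectra_table)
    mask = (sel_frame["set"] == "NONSEL").to_numpy()
    if not mask.any():
        return pd.DataFrame()
    preds = {"sample_id": spectra_table["sample_id"].to_numpy()[mask],
             "variety": spectra_table["variety"].to_numpy()[mask]}
    for analyte, model in models.items():
        preds[analyte] = model.predict(X[mask], wl)
    return pd.DataFrame(preds)


def _write_figure(spectra_table: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    X, wl = spectra_matrix(spectra_table)
    fig, ax = plt.subplots(figsize=(7, 4))
    for variety, grp in spectra_table.groupby("variety"):
        Xi, _ = spectra_matrix(grp)
        ax.plot(wl, Xi.mean(axis=0), label=variety)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("absorbance (log 1/R)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage and write a self-contained run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "models").mkdir(exist_ok=True)
    (outdir / "reports").mkdir(exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        cfg.to_yaml(outdir / "config.yaml")
        timings = {}

        def _stage(name, fn):
            t0 = time.perf_counter()
            out = fn()
            timings[name] = time.perf_counter() - t0
            log.info("stage %-10s %.2f s", name, timings[name])
            return out

        panel, measured = _stage("simulate", lambda: simulate_panel(cfg))
        panel.to_csv(outdir / "panel_truth.csv", index=False, float_format="%.6f")
        measured.to_csv(outdir / "panel_measured.csv", index=False, float_format="%.6f")

        if cfg.imaging:
            spectra_table, diag, _ = _stage("segment", lambda: imaged_spectra(cfg, panel))
            diag.to_csv(outdir / "reports" / "segmentation_diagnostics.csv",
                        index=False, float_format="%.6f")
        else:
            spectra_table = _stage(
                "spectra", lambda: generate_spectra(panel, None, cfg.noise, cfg.seed)
            )
        spectra_table.to_csv(outdir / "spectra.csv", index=False, float_format="%.8f")

        _, sel_frame = _stage("select", lambda: select_spectra(cfg, spectra_table))
        sel_frame.to_csv(outdir / "selection.csv", index=False, float_format="%.6f")

        models = _stage(
            "train", lambda: train_models(cfg, spectra_table, measured, sel_frame)
        )
        for analyte, model in models.items():
            model.save(outdir / "models" / f"{analyte.replace(':', '_')}.json")
        reports = _stage(
            "validate", lambda: validate_models(cfg, models, spectra_table, measured, sel_frame)
        )
        valstats.write_reports(
            reports, outdir / "reports" / "models_report.csv",
            outdir / "reports" / "models_report.json",
        )

        nonsel = _stage(
            "apply", lambda: predict_nonselected(cfg, models, spectra_table, sel_frame)
        )
        if len(nonsel):
            nonsel.to_csv(outdir / "reports" / "nonselected_predictions.csv",
                          index=False, float_format="%.6f")
            summary = composition.summary_with_letters(
                nonsel, tuple(models.keys()), cfg.alpha
            )
            summary.to_csv(outdir / "reports" / "variety_predictions.csv",
                           index=False, float_format="%.6f")
        _stage("figure", lambda: _write_figure(spectra_table, outdir / "reports" / "mean_spectra.png"))
        return {
            "outdir": outdir,
            "panel": panel,
            "measured": measured,
            "spectra": spectra_table,
            "selection": sel_frame,
            "models": models,
            "reports": reports,
            "timings": timings,
        }
    finally:
        log.removeHandler(handler)
        handler.close()
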