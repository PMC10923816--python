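"""End-to-end orchestration: calibrate -> gate -> average -> boundary ->
{linecross, dmm, beamography, evsla} -> fusion, plus the model-training
and cohort-evaluation harnesses.

Everything is deterministic under fixed seeds; a repeated run writes a
byte-identical JSON report (timings go to a separate log, not the
report).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np

from . import beamography as bg
from . import dmm as dmm_mod
from . import evsla as evsla_mod
from . import linecross as lc
from .calibration import (BoundaryModel, CalibrationRecord, average_scans,
                          estimate_boundary, stability_gate,
                          two_phantom_calibrate)
from .core import (AntennaArray, Ellipse, EmibrainError, FrequencySweep,
                   ImageGrid, IntensityImage, PropagationModel,
                   ScatteringDataset, to_time_domain)
from .fusion import (FusionOutput, fuse_decisions, fuse_images,
                     quadrant_from_image, render_overlay)
from .hvg import channel_metric_matrices
from .synthetic import (COHORT_NF, CohortPatient, calibration_phantom,
                        forward_scatter, generate_cohort, make_phantom)


class StageError(EmibrainError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Tunable pipeline parameters (see docs/methods.md for rationale)."""

    sweep: FrequencySweep = field(
        default_factory=lambda: FrequencySweep.default(n=COHORT_NF))
    grid: ImageGrid = field(default_factory=ImageGrid.default)
    array: AntennaArray = field(default_factory=AntennaArray.default_ring)
    prop: PropagationModel = field(default_factory=PropagationModel)
    stability_threshold_db: float = -20.0
    window: str = "hamming"
    pad_factor: int = 4
    linecross_half_width: float = 0.006
    fusion_threshold: float = 0.5
    fusion_min_agree: int = 3
    fusion_sigma_px: float = 2.0
    fusion_dilate_px: int = 2
    # reliability weights for the fused heatmap, in the fixed modality
    # order (linecross, dmm, beamography, evsla): back-propagation is
    # the sharpest localizer on this forward model
    fusion_weights: tuple[float, ...] = (1.0, 1.0, 2.0, 1.0)
    evsla_sep_range: tuple[int, int] = (1, 3)
    crossing_half_width: float = 0.010
    dmm_typing_radius: float = 0.015


@dataclass
class ModelBundle:
    """Everything trained: boundary regressor, classifier ensemble, DMM
    healthy-null statistics and phase-sign convention."""

    boundary: BoundaryModel
    ensemble: lc.EnsembleBundle
    dmm_reference: dmm_mod.HealthyReference
    dmm_sign: float
    training_manifest: dict

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "ModelBundle":
        obj = joblib.load(path)
        if not isinstance(obj, cls):
            raise EmibrainError("not an emibrain model bundle")
        return obj


@dataclass
class PatientWorkup:
    """Everything the parallel algorithms share for one patient."""

    avg: ScatteringDataset
    stability: object
    boundary: Ellipse
    boundary_estimate: object
    reference: ScatteringDataset       # healthy model on estimated boundary
    matrices: dict
    diff: lc.DifferentialFeatureSet
    bg_image: IntensityImage
    csd: bg.ClutterSuppressedData
    features: np.ndarray


def _patient_features(patient: CohortPatient, config: PipelineConfig
                      ) -> tuple[np.ndarray, ScatteringDataset, dict]:
    """Calibrate, gate, average one patient; return the differential
    feature vector (global aggregates only), the averaged calibrated
    dataset and the metric matrices."""
    calibrated = [two_phantom_calibrate(s, patient.calibration)
                  for s in patient.scans]
    report = stability_gate(calibrated, config.stability_threshold_db)
    avg = average_scans([calibrated[k] for k in report.kept_indices])
    tds = to_time_domain(avg, config.window, config.pad_factor)
    mats = channel_metric_matrices(tds, config.array, avg.channel_mask)
    feats = lc.differential_matrices(mats, config.array)
    return feats.features, avg, {"matrices": mats, "diff": feats,
                                 "stability": report}


def patient_workup(patient: CohortPatient, boundary_model: BoundaryModel,
                   config: PipelineConfig) -> PatientWorkup:
    """Calibrate, gate, average, estimate the boundary, synthesize the
    healthy reference, run beamography, and build the classifier
    feature vector.

    The 48 features per patient are: 39 global differential-matrix
    aggregates, 3 crossing-line signed differential means at the
    back-propagation peak, and 6 residual-signal HVG summaries (mean
    node metric over all channels and over the crossing channels, for
    degree/strength/entropy, computed on the background-model residual
    — the residual waveform flips nearly in sign between hemorrhage
    and ischemia, and the visibility graph is sign-sensitive).
    """
    _, avg, aux = _patient_features(patient, config)
    best = estimate_boundary(avg, boundary_model)
    ref_ph = make_phantom(0, "healthy", grid=config.grid,
                          boundary=best.ellipse, prop=config.prop)
    reference = forward_scatter(ref_ph, config.array, config.sweep,
                                config.prop)
    bg_img, csd = bg.beamography_image(avg, config.array, config.prop,
                                       config.grid, best.ellipse, reference)
    crossing = lc.crossing_channels(config.array, bg_img.peak(),
                                    config.crossing_half_width)
    cross_feats = np.asarray(
        [lc.crossing_mean(aux["diff"].matrix(m), crossing)
         for m in ("degree", "strength", "entropy")])
    residual = avg.copy_with(s=avg.s - reference.s)
    res_tds = to_time_domain(residual, config.window, config.pad_factor)
    res_mats = channel_metric_matrices(res_tds, config.array,
                                       avg.channel_mask)
    res_feats = []
    for m in ("degree", "strength", "entropy"):
        res_feats.append(float(np.nanmean(res_mats[m])))
        res_feats.append(lc.crossing_mean(res_mats[m], crossing))
    features = np.concatenate([aux["diff"].features, cross_feats,
                               np.asarray(res_feats)])
    return PatientWorkup(avg, aux["stability"], best.ellipse, best,
                         reference, aux["matrices"], aux["diff"],
                         bg_img, csd, features)


def train_models(seed: int = 0, n_train: int = 120,
                 config: PipelineConfig | None = None, *,
                 n_boundary: int = 400, snr_db: float = 30.0,
                 class_mix: dict | None = None) -> ModelBundle:
    """Train every data-driven stage on a dedicated synthetic cohort.

    The classifier ensemble learns from per-patient differential
    features; the DMM healthy null is estimated from the healthy
    training patients; the DMM phase-sign convention is verified on one
    noise-free hemorrhagic phantom and recorded.
    """
    config = config or PipelineConfig()
    class_mix = class_mix or {"healthy": 1 / 3, "ICH": 1 / 3, "IS": 1 / 3}
    from .calibration import train_boundary_model
    boundary = train_boundary_model(
        n_boundary, seed + 1, sweep=config.sweep, grid=config.grid,
        array=config.array, prop=config.prop, snr_db=snr_db)

    cohort, _ = generate_cohort(n_train, class_mix, seed=seed + 2,
                                sweep=config.sweep, grid=config.grid,
                                array=config.array, prop=config.prop,
                                snr_db=snr_db)
    feats, labels = [], []
    dmm_stats = []
    profile_ref = None
    for p in cohort:
        w = patient_workup(p, boundary, config)
        feats.append(w.features)
        labels.append(p.stroke_class)
        if profile_ref is None:
            profile_ref = dmm_mod.SensitivityProfile.from_reference(
                p.calibration.synthesized_low)
        if p.stroke_class == "healthy":
            delta = dmm_mod.mirror_reference(w.avg)
            _, mass, _ = dmm_mod.dmm_image(delta, profile_ref,
                                           w.boundary, config.grid)
            dmm_stats.append(mass)
    ensemble = lc.train_ensemble(np.stack(feats), labels, seed)
    dmm_reference = dmm_mod.HealthyReference.from_stats(dmm_stats)

    # verify the phase-sign convention on one noise-free ICH phantom:
    # typing uses the background-reference residual at the known target
    ph = make_phantom(seed + 3, "ICH", grid=config.grid)
    ds = forward_scatter(ph, config.array, config.sweep, config.prop)
    healthy = make_phantom(0, "healthy", grid=config.grid,
                           boundary=ph.boundary, prop=config.prop)
    ref_ds = forward_scatter(healthy, config.array, config.sweep,
                             config.prop)
    delta = dmm_mod.background_reference(ds, ref_ds)
    xx, yy = config.grid.mesh()
    c = ph.inclusion.center
    search = (ph.boundary.contains(xx, yy)
              & (np.hypot(xx - c[0], yy - c[1]) <= 0.02))
    peak, _ = dmm_mod.refine_peak(delta, profile_ref, config.grid,
                                  config.sweep, config.prop, search)
    stat = dmm_mod.dmm_phase_stat(delta, profile_ref, peak,
                                  config.sweep, config.prop)
    sign = 1.0 if stat.real > 0 else -1.0
    manifest = {"seed": seed, "n_train": n_train, "n_boundary": n_boundary,
                "snr_db": snr_db, "boundary_val_mae_m":
                boundary.validation_mae_m}
    return ModelBundle(boundary, ensemble, dmm_reference, sign, manifest)


@dataclass
class PatientReport:
    fusion: FusionOutput
    images: dict[str, IntensityImage]
    boundary: Ellipse
    report: dict
    timings: dict[str, float]


def process_patient(patient: CohortPatient, models: ModelBundle,
                    config: PipelineConfig | None = None) -> PatientReport:
    """Run the full detection/localization/classification pipeline."""
    config = config or PipelineConfig()
    timings: dict[str, float] = {}

    def _stage(name, fn, *a, **kw):
        t0 = time.perf_counter()
        try:
            out = fn(*a, **kw)
        except EmibrainError:
            raise
        except Exception as e:
            raise StageError(name, e) from e
        timings[name] = time.perf_counter() - t0
        return out

    workup = _stage("preprocess", patient_workup, patient,
                    models.boundary, config)
    avg = workup.avg
    boundary = workup.boundary
    bg_img, csd = workup.bg_image, workup.csd

    ens_result = _stage("classify", lc.classify_ensemble, workup.features,
                        models.ensemble)
    # corridor-weight polarity follows the classifier's call: on this
    # forward model IS raises crossing-line entropy, ICH lowers it
    polarity = {"ICH": "neg", "IS": "pos"}.get(ens_result.label, "abs")
    lc_img = _stage("linecross", lc.linecross_map,
                    workup.diff.d_entropy, config.array, boundary,
                    config.grid, config.linecross_half_width,
                    polarity).image

    profile = dmm_mod.SensitivityProfile.from_reference(
        patient.calibration.synthesized_low)
    dmm_result = _stage("dmm", dmm_mod.dmm_analyze, avg, profile,
                        models.dmm_reference, boundary, config.grid,
                        config.prop, models.dmm_sign,
                        background_ds=workup.reference,
                        affected=csd.affected,
                        typing_peak=bg_img.peak(),
                        typing_radius=config.dmm_typing_radius)

    ref_cal = two_phantom_calibrate(patient.calibration.low,
                                    patient.calibration)
    ev_img, _ = _stage("evsla", evsla_mod.evsla_image, avg, ref_cal,
                       config.array, boundary, config.grid,
                       config.evsla_sep_range)

    images = {"linecross": lc_img, "dmm": dmm_result.image,
              "beamography": bg_img, "evsla": ev_img}
    # collaborative lateralization: once a stroke is called, the mirror
    # ambiguity that symmetry-differencing leaves in every modality is
    # resolved with the distance-correlation side call — fuse only the
    # affected hemisphere
    fusion_inputs = images
    if ens_result.label != "healthy" or dmm_result.detect:
        xx, _ = config.grid.mesh()
        half = xx >= 0 if csd.affected == "left" else xx <= 0
        fusion_inputs = {
            name: IntensityImage(img.grid, img.values * half, img.modality)
            for name, img in images.items()}
    heat, dmask, k_used, fallback, degenerate = _stage(
        "fusion", fuse_images, list(fusion_inputs.values()), config.grid,
        config.fusion_threshold, config.fusion_min_agree,
        config.fusion_sigma_px, config.fusion_dilate_px,
        config.fusion_weights)
    fused_class, fused_probs, certainty = fuse_decisions(
        ens_result, dmm_result.stroke_type, dmm_result.detect)
    quadrant = quadrant_from_image(heat)

    fusion = FusionOutput(dmask, heat, fused_class, fused_probs, certainty,
                          quadrant, k_used, fallback, degenerate)
    report = {
        "patient": patient.patient_id,
        "fused_class": fused_class,
        "certainty": round(certainty, 9),
        "fused_probs": {c: round(float(p), 9) for c, p in
                        zip(models.ensemble.classes, fused_probs)},
        "quadrant": quadrant.quadrant,
        "peak_xy_m": [round(v, 6) for v in heat.peak()],
        "ensemble": {c: round(float(p), 9) for c, p in
                     zip(ens_result.classes, ens_result.fused)},
        "dmm": {"detect": dmm_result.detect,
                "type": dmm_result.stroke_type,
                "intensity_stat": round(dmm_result.intensity_stat, 9)},
        "affected_side": csd.affected,
        "boundary": {k: round(getattr(boundary, k), 6)
                     for k in ("cx", "cy", "a", "b")},
        "per_modality_peaks": {m: [round(v, 6) for v in img.peak()]
                               for m, img in images.items()},
        "scans_kept": [int(k) for k in workup.stability.kept_indices],
        "agreement_k": k_used,
        "agreement_fallback": fallback,
    }
    return PatientReport(fusion, images, boundary, report, timings)


def write_report(pr: PatientReport, out_dir) -> Path:
    """Write report.json (deterministic), per-stage images and the render."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "report.json"
    with open(path, "w") as fh:
        json.dump(pr.report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    for name, img in pr.images.items():
        img.to_csv(out / f"{name}.csv")
    pr.fusion.heatmap.to_csv(out / "fused.csv")
    render_overlay(pr.fusion.heatmap, pr.fusion.fused_class,
                   out / "fused.png")
    with open(out / "run.log", "w") as fh:
        for stage, dt in pr.timings.items():
            fh.write(f"{stage}: {dt:.3f} s\n")
    return path


def save_patient_dir(patient: CohortPatient, out_dir) -> Path:
    """Persist one patient's scans and calibration records as Touchstone
    files plus the antenna geometry CSV."""
    from .core import write_antenna_csv, write_touchstone

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k, scan in enumerate(patient.scans):
        write_touchstone(scan, out / f"scan_{k:03d}.s{scan.na}p")
    cal = patient.calibration
    na = cal.low.na
    write_touchstone(cal.low, out / f"cal_low_measured.s{na}p")
    write_touchstone(cal.high, out / f"cal_high_measured.s{na}p")
    write_touchstone(cal.synthesized_low, out / f"cal_low_synth.s{na}p")
    write_touchstone(cal.synthesized_high, out / f"cal_high_synth.s{na}p")
    write_antenna_csv(patient.scans[0].array, out / "geometry.csv")
    props = {"low_props": list(cal.low_props),
             "high_props": list(cal.high_props),
             "patient_id": patient.patient_id}
    with open(out / "patient.json", "w") as fh:
        json.dump(props, fh, indent=2, sort_keys=True)
    return out


def load_patient_dir(path) -> CohortPatient:
    """Load a patient directory written by :func:`save_patient_dir`."""
    from .core import read_antenna_csv, read_touchstone

    p = Path(path)
    array = read_antenna_csv(p / "geometry.csv")
    scans = [read_touchstone(f, array)
             for f in sorted(p.glob("scan_*.s*p"))]
    if not scans:
        raise EmibrainError(f"no scan_*.sNp files in {p}")
    na = array.na
    with open(p / "patient.json") as fh:
        meta = json.load(fh)
    cal = CalibrationRecord(
        low=read_touchstone(p / f"cal_low_measured.s{na}p", array),
        high=read_touchstone(p / f"cal_high_measured.s{na}p", array),
        low_props=tuple(meta["low_props"]),
        high_props=tuple(meta["high_props"]),
        synthesized_low=read_touchstone(p / f"cal_low_synth.s{na}p", array),
        synthesized_high=read_touchstone(p / f"cal_high_synth.s{na}p",
                                         array))
    return CohortPatient(meta.get("patient_id", p.name), "unknown", None,
                         scans, cal, None, 0)


def run_pipeline(input_dir, models: ModelBundle,
                 config: PipelineConfig | None = None,
                 out_dir=None) -> PatientReport:
    """File-level entry point: load a patient directory, process it, and
    write the report and per-stage artifacts."""
    config = config or PipelineConfig()
    patient = load_patient_dir(input_dir)
    pr = process_patient(patient, models, config)
    if out_dir is not None:
        write_report(pr, out_dir)
    return pr


def evaluate_cohort(cohort: list[CohortPatient], models: ModelBundle,
                    config: PipelineConfig | None = None) -> dict:
    """Score classification and quadrant localization against truth."""
    config = config or PipelineConfig()
    n = len(cohort)
    class_ok = 0
    quad_ok = 0
    n_diseased = 0
    peak_errors = []
    rows = []
    for p in cohort:
        pr = process_patient(p, models, config)
        ok_c = pr.report["fused_class"] == p.stroke_class
        class_ok += ok_c
        row = {"patient": p.patient_id, "truth": p.stroke_class,
               "pred": pr.report["fused_class"],
               "quadrant_pred": pr.report["quadrant"],
               "quadrant_truth": p.quadrant}
        if p.stroke_class != "healthy":
            n_diseased += 1
            quad_ok += pr.report["quadrant"] == p.quadrant
            cx, cy = p.phantom.inclusion.center
            px, py = pr.fusion.heatmap.peak()
            row["peak_error_m"] = float(np.hypot(px - cx, py - cy))
            peak_errors.append(row["peak_error_m"])
        rows.append(row)
    return {
        "n": n,
        "class_accuracy": class_ok / n,
        "quadrant_accuracy": quad_ok / n_diseased if n_diseased else
        float("nan"),
        "median_peak_error_m": float(np.median(peak_errors))
        if peak_errors else float("nan"),
        "per_patient": rows,
    }
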