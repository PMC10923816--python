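"""Two-phantom calibration, scan-stability gating, and boundary estimation.

Calibration: measuring two homogeneous reference phantoms with known
dielectric properties pins down, per channel and frequency, the complex
affine map m(S) = g S + o that carries measured onto model-predicted
("synthesized") responses.  The same map applied to patient data
removes any per-channel affine distortion — in particular the per-port
gain/offset drift of cables and switches — exactly.

Boundary estimation (the stand-in for the clinical deep network): a
gradient-boosted regressor maps the 16 reflection-coefficient
magnitude spectra |S_ii(f)| to the head ellipse (cx, cy, a, b),
trained on seeded synthetic phantoms with randomized geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import HistGradientBoostingRegressor

from .core import (MAX_S_MAGNITUDE, AntennaArray, DimensionError, Ellipse,
                   EmibrainError, FrequencySweep, ImageGrid,
                   PropagationModel, ScatteringDataset)

SEMI_AXIS_BOUNDS = (0.060, 0.120)   # anatomical clamp for a, b (m)


class UnstableAcquisitionError(EmibrainError):
    pass


# --------------------------------------------------------------------------
# two-phantom calibration
# --------------------------------------------------------------------------


@dataclass
class CalibrationRecord:
    """Measured + model-predicted responses of the two reference phantoms."""

    low: ScatteringDataset
    high: ScatteringDataset
    low_props: tuple[float, float]
    high_props: tuple[float, float]
    synthesized_low: ScatteringDataset
    synthesized_high: ScatteringDataset

    def __post_init__(self):
        a = self.low
        for other in (self.high, self.synthesized_low, self.synthesized_high):
            if other.s.shape != a.s.shape:
                raise DimensionError("calibration datasets must share "
                                     "sweep and array dimensions")


def two_phantom_calibrate(patient: ScatteringDataset,
                          cal: CalibrationRecord,
                          degenerate_rtol: float = 1e-6,
                          gain_outlier: float = 50.0
                          ) -> ScatteringDataset:
    """Map patient data through the per-channel affine calibration.

    For each channel and frequency, solve g, o from
    g * low_measured + o = synthesized_low and the same for high, then
    apply m(S) = g S + o to the patient data.  Channels where the two
    references are numerically indistinguishable — or whose solved gain
    is a wild outlier (reference separation below the noise) — are
    flagged uncalibratable in ``channel_mask`` and zeroed.
    """
    if patient.s.shape != cal.low.s.shape:
        raise DimensionError("patient and calibration data must share "
                             "sweep and array")
    dm = cal.high.s - cal.low.s
    dsyn = cal.synthesized_high.s - cal.synthesized_low.s
    scale = np.sqrt(np.mean(np.abs(cal.high.s) ** 2))
    degenerate = np.abs(dm) < degenerate_rtol * scale
    g = np.where(degenerate, 1.0, dsyn / np.where(degenerate, 1.0, dm))
    o = cal.synthesized_low.s - g * cal.low.s
    out = g * patient.s + o
    bad = degenerate.any(axis=2)
    g_med = np.median(np.abs(g))
    if g_med > 0:
        bad |= (np.abs(g) > gain_outlier * g_med).any(axis=2)
    bad |= (np.abs(out) > MAX_S_MAGNITUDE).any(axis=2)
    mask = patient.valid_mask() & ~bad
    out[~mask] = 0.0
    return patient.copy_with(s=out, channel_mask=mask,
                             label=f"{patient.label}-cal")


# --------------------------------------------------------------------------
# stability gating and averaging
# --------------------------------------------------------------------------


@dataclass
class StabilityReport:
    deltas_db: np.ndarray        # consecutive-pair RMS deltas, dB
    threshold_db: float
    kept_indices: np.ndarray
    dropped_indices: np.ndarray


def stability_gate(scans: list[ScatteringDataset],
                   threshold_db: float = -35.0) -> StabilityReport:
    """Drop scans inside runs of excessive consecutive-scan change.

    The RMS delta between each consecutive pair, relative to the mean
    signal power of the series, is expressed in dB.  A scan is dropped
    when *every* delta adjacent to it exceeds the threshold (a single
    corrupted scan raises both of its neighboring deltas).  If nothing
    survives, the acquisition is declared unstable.
    """
    if len(scans) < 2:
        raise DimensionError("stability gating needs at least 2 scans")
    stack = np.stack([s.s for s in scans])
    power = np.mean(np.abs(stack) ** 2)
    n = len(scans)
    deltas = np.empty(n - 1)
    with np.errstate(divide="ignore"):
        for k in range(n - 1):
            d = np.mean(np.abs(stack[k + 1] - stack[k]) ** 2)
            deltas[k] = 10.0 * np.log10(d / power) if d > 0 else -np.inf
    exceed = deltas > threshold_db
    dropped = []
    for k in range(n):
        adj = []
        if k > 0:
            adj.append(exceed[k - 1])
        if k < n - 1:
            adj.append(exceed[k])
        if adj and all(adj):
            dropped.append(k)
    kept = np.array([k for k in range(n) if k not in set(dropped)],
                    dtype=int)
    if kept.size == 0:
        raise UnstableAcquisitionError(
            f"all {n} scans exceed the {threshold_db} dB stability "
            "threshold: unstable acquisition")
    return StabilityReport(deltas, threshold_db, kept,
                           np.asarray(dropped, dtype=int))


def average_scans(scans: list[ScatteringDataset]) -> ScatteringDataset:
    """Complex mean over the kept scans."""
    if not scans:
        raise DimensionError("cannot average an empty scan list")
    mean = np.mean(np.stack([s.s for s in scans]), axis=0)
    return scans[0].copy_with(s=mean,
                              label=f"mean-of-{len(scans)}-scans")


# --------------------------------------------------------------------------
# boundary estimation (Algorithm-I stand-in)
# --------------------------------------------------------------------------

N_FEATURE_FREQS = 21


@dataclass
class BoundaryEstimate:
    ellipse: Ellipse
    fit_residual: float
    clamped: bool = False


@dataclass
class BoundaryModel:
    """Reflection-magnitude -> head-ellipse regressor (one booster per
    target parameter), with its training manifest."""

    models: list
    feature_freqs: np.ndarray
    validation_mae_m: float
    seed: int
    n_train: int

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "BoundaryModel":
        obj = joblib.load(path)
        if not isinstance(obj, cls):
            raise EmibrainError("not a boundary model artifact")
        return obj


def reflection_features(ds: ScatteringDataset,
                        feature_freqs: np.ndarray) -> np.ndarray:
    """|S_ii| for every antenna interpolated onto a fixed frequency grid."""
    f = ds.sweep.frequencies
    na = ds.na
    feats = np.empty(na * feature_freqs.size)
    for i in range(na):
        mag = np.abs(ds.s[i, i, :])
        feats[i * feature_freqs.size:(i + 1) * feature_freqs.size] = (
            np.interp(feature_freqs, f, mag))
    return feats


def train_boundary_model(n_train: int = 600, seed: int = 0, *,
                         sweep: FrequencySweep | None = None,
                         grid: ImageGrid | None = None,
                         array: AntennaArray | None = None,
                         prop: PropagationModel | None = None,
                         snr_db: float = 30.0,
                         validation_fraction: float = 0.15
                         ) -> BoundaryModel:
    """Train the ellipse regressor on seeded random synthetic phantoms.

    Phantoms span randomized semi-axes, small center offsets and all
    three stroke classes; features are noisy reflection magnitudes so
    the model tolerates measurement noise at inference.
    """
    from .synthetic import NoiseModel, add_noise, forward_scatter, make_phantom

    sweep = sweep or FrequencySweep.default(n=41)
    grid = grid or ImageGrid.default()
    array = array or AntennaArray.default_ring()
    prop = prop or PropagationModel()
    rng = np.random.default_rng(seed)
    feature_freqs = np.linspace(sweep.frequencies[0], sweep.frequencies[-1],
                                N_FEATURE_FREQS)
    x = np.empty((n_train, array.na * N_FEATURE_FREQS))
    y = np.empty((n_train, 4))
    classes = ("healthy", "ICH", "IS")
    for m in range(n_train):
        a = rng.uniform(0.065, 0.095)
        b = rng.uniform(0.080, 0.115)
        cx = rng.uniform(-0.005, 0.005)
        cy = rng.uniform(-0.005, 0.005)
        boundary = Ellipse(cx, cy, a, b)
        cls = classes[rng.integers(0, 3)]
        ph = make_phantom(int(rng.integers(0, 2**31 - 1)), cls, grid=grid,
                          boundary=boundary, prop=prop)
        ds = forward_scatter(ph, array, sweep, prop)
        if np.isfinite(snr_db):
            noise = NoiseModel.draw(rng, array.na, snr_db=snr_db,
                                    gain_std=0.0, offset_scale=0.0)
            ds = add_noise(ds, noise, int(rng.integers(0, 2**31 - 1)))
        x[m] = reflection_features(ds, feature_freqs)
        y[m] = (cx, cy, a, b)
    n_val = max(1, int(round(validation_fraction * n_train)))
    xt, xv = x[:-n_val], x[-n_val:]
    yt, yv = y[:-n_val], y[-n_val:]
    models = []
    pred = np.empty_like(yv)
    for c in range(4):
        reg = HistGradientBoostingRegressor(random_state=seed,
                                            max_iter=300)
        reg.fit(xt, yt[:, c])
        models.append(reg)
        pred[:, c] = reg.predict(xv)
    mae = float(np.mean(np.abs(pred[:, 2:] - yv[:, 2:])))
    return BoundaryModel(models, feature_freqs, mae, seed, n_train)


def estimate_boundary(ds: ScatteringDataset,
                      model: BoundaryModel) -> BoundaryEstimate:
    """Predict the head ellipse from calibrated reflection coefficients.

    Out-of-bounds semi-axes are clamped to the anatomical range and the
    estimate flagged.
    """
    if model is None or not model.models:
        raise EmibrainError("boundary model is untrained")
    feats = reflection_features(ds, model.feature_freqs)[None, :]
    cx, cy, a, b = (float(m.predict(feats)[0]) for m in model.models)
    lo, hi = SEMI_AXIS_BOUNDS
    clamped = not (lo <= a <= hi and lo <= b <= hi)
    if clamped:
        import warnings
        warnings.warn("boundary prediction outside anatomical bounds; "
                      "clamped", stacklevel=2)
    a, b = float(np.clip(a, lo, hi)), float(np.clip(b, lo, hi))
    return BoundaryEstimate(Ellipse(cx, cy, a, b), model.validation_mae_m,
                            clamped)
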