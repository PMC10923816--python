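"""Two-phantom calibration, stability gating, averaging, boundary model."""

import numpy as np
import pytest

from emibrain.calibration import (CalibrationRecord, UnstableAcquisitionError,
                                  average_scans, estimate_boundary,
                                  stability_gate, two_phantom_calibrate)
from emibrain.synthetic import (NoiseModel, add_noise, calibration_phantom,
                                forward_scatter, make_phantom)


@pytest.fixture(scope="module")
def cal_pair(config):
    low = forward_scatter(calibration_phantom("low", grid=config.grid,
                                              prop=config.prop),
                          config.array, config.sweep, config.prop)
    high = forward_scatter(calibration_phantom("high", grid=config.grid,
                                               prop=config.prop),
                           config.array, config.sweep, config.prop)
    return low, high


def _record(low_m, high_m, low_s, high_s):
    return CalibrationRecord(low=low_m, high=high_m,
                             low_props=(38.0, 0.55), high_props=(52.0, 0.95),
                             synthesized_low=low_s, synthesized_high=high_s)


def test_identity_distortion_gives_identity_calibration(cal_pair,
                                                        healthy_forward):
    low, high = cal_pair
    _, patient = healthy_forward
    cal = _record(low, high, low, high)
    out = two_phantom_calibrate(patient, cal)
    good = out.valid_mask()
    assert good.mean() > 0.99
    assert np.max(np.abs(out.s[good] - patient.s[good])) < 1e-9


def test_calibrating_low_reference_returns_synthesized(cal_pair,
                                                       healthy_forward):
    low, high = cal_pair
    rng = np.random.default_rng(0)
    drift = NoiseModel.draw(rng, 16, snr_db=np.inf)
    low_m = add_noise(low, drift, seed=1)
    high_m = add_noise(high, drift, seed=2)
    cal = _record(low_m, high_m, low, high)
    out = two_phantom_calibrate(low_m, cal)
    good = out.valid_mask()
    assert np.max(np.abs(out.s[good] - low.s[good])) < 1e-12


def test_affine_distortion_removed_exactly(cal_pair, ich_forward):
    """Known per-port gains and offsets, then calibration: recovered to
    better than 1e-9 relative error (the affine map is inverted)."""
    low, high = cal_pair
    _, patient = ich_forward
    rng = np.random.default_rng(1)
    drift = NoiseModel.draw(rng, 16, snr_db=np.inf, gain_std=0.1,
                            offset_scale=1e-3)
    cal = _record(add_noise(low, drift, seed=1),
                  add_noise(high, drift, seed=2), low, high)
    distorted = add_noise(patient, drift, seed=3)
    out = two_phantom_calibrate(distorted, cal)
    good = out.valid_mask()
    scale = np.max(np.abs(patient.s))
    assert good.mean() > 0.99
    assert np.max(np.abs(out.s[good] - patient.s[good])) < 1e-9 * scale


def test_degenerate_channels_flagged(cal_pair, healthy_forward):
    low, high = cal_pair
    _, patient = healthy_forward
    high_bad = high.copy_with(s=high.s.copy())
    high_bad.s[3, 7, :] = low.s[3, 7, :]   # indistinguishable references
    high_bad.s[7, 3, :] = low.s[7, 3, :]
    cal = _record(low, high_bad, low, high)
    out = two_phantom_calibrate(patient, cal)
    assert not out.valid_mask()[3, 7]
    assert np.all(out.s[3, 7] == 0)
    assert out.valid_mask()[4, 8]


# --------------------------------------------------------------- stability


def test_identical_scans_all_kept(healthy_forward):
    _, ds = healthy_forward
    report = stability_gate([ds] * 20, threshold_db=-35.0)
    assert list(report.kept_indices) == list(range(20))
    assert np.all(np.isneginf(report.deltas_db))


def test_injected_jump_dropped_exactly(healthy_forward):
    """A single scan corrupted by a +20 dB jump is the only one dropped."""
    _, ds = healthy_forward
    rng = np.random.default_rng(2)
    scans = []
    for k in range(10):
        s = ds.s.copy()
        if k == 4:
            rms = np.sqrt(np.mean(np.abs(ds.s) ** 2))
            s = s + rms * 10.0 * (rng.standard_normal(s.shape)
                                  + 1j * rng.standard_normal(s.shape))
        scans.append(ds.copy_with(s=s))
    report = stability_gate(scans, threshold_db=-20.0)
    assert list(report.dropped_indices) == [4]
    assert 4 not in report.kept_indices


def test_boundary_threshold_scans_kept(healthy_forward):
    """Two scans whose delta sits 1 dB below the gate are both kept."""
    _, ds = healthy_forward
    power = np.mean(np.abs(ds.s) ** 2)
    target_db = -21.0   # threshold -20 -> delta below gate
    amp = np.sqrt(power * 10 ** (target_db / 10))
    other = ds.copy_with(s=ds.s + amp)
    report = stability_gate([ds, other], threshold_db=-20.0)
    assert list(report.kept_indices) == [0, 1]


def test_all_unstable_raises(healthy_forward):
    _, ds = healthy_forward
    rng = np.random.default_rng(3)
    rms = np.sqrt(np.mean(np.abs(ds.s) ** 2))
    scans = [ds.copy_with(s=ds.s + rms * (rng.standard_normal(ds.s.shape)
                                          + 1j * rng.standard_normal(
                                              ds.s.shape)))
             for _ in range(6)]
    with pytest.raises(UnstableAcquisitionError):
        stability_gate(scans, threshold_db=-35.0)


# --------------------------------------------------------------- averaging


def test_average_identities(healthy_forward):
    _, ds = healthy_forward
    assert np.max(np.abs(average_scans([ds, ds, ds]).s - ds.s)) < 1e-15
    neg = ds.copy_with(s=-ds.s)
    assert np.max(np.abs(average_scans([ds, neg]).s)) == 0


def test_averaging_reduces_noise_13db(healthy_forward):
    """Averaging 20 i.i.d. noisy scans lowers the noise floor by
    10 log10(20) ~= 13 dB (Monte-Carlo over 30 repetitions)."""
    _, ds = healthy_forward
    noise = NoiseModel.ideal(ds.na)
    noise.snr_db = 30.0
    gains = []
    for rep in range(30):
        scans = [add_noise(ds, noise, seed=1000 * rep + k)
                 for k in range(20)]
        avg = average_scans(scans)
        single = np.mean(np.abs(scans[0].s - ds.s) ** 2)
        averaged = np.mean(np.abs(avg.s - ds.s) ** 2)
        gains.append(10 * np.log10(single / averaged))
    assert abs(np.mean(gains) - 10 * np.log10(20)) < 1.0


def test_average_empty_raises():
    with pytest.raises(Exception):
        average_scans([])


# ---------------------------------------------------------------- boundary


def test_boundary_estimate_accuracy(models, config):
    """Held-out phantoms: mean absolute semi-axis error <= 3 mm."""
    rng = np.random.default_rng(99)
    errors = []
    for _ in range(60):
        from emibrain.core import Ellipse
        a = rng.uniform(0.068, 0.092)
        b = rng.uniform(0.084, 0.112)
        ph = make_phantom(int(rng.integers(2**31 - 1)), "healthy",
                          grid=config.grid, prop=config.prop,
                          boundary=Ellipse(0.0, 0.0, a, b))
        ds = forward_scatter(ph, config.array, config.sweep, config.prop)
        est = estimate_boundary(ds, models.boundary).ellipse
        errors.extend([abs(est.a - a), abs(est.b - b)])
    assert np.mean(errors) <= 0.003
    assert models.boundary.validation_mae_m <= 0.003


def test_boundary_estimate_deterministic(models, healthy_forward):
    _, ds = healthy_forward
    e1 = estimate_boundary(ds, models.boundary).ellipse
    e2 = estimate_boundary(ds, models.boundary).ellipse
    assert e1 == e2


def test_boundary_never_outside_anatomical_bounds(models, config):
    """Predictions are clamped into [60, 120] mm semi-axes even for
    out-of-distribution inputs."""
    ds = forward_scatter(
        calibration_phantom("low", grid=config.grid, prop=config.prop),
        config.array, config.sweep, config.prop)
    est = estimate_boundary(ds, models.boundary).ellipse
    assert 0.060 <= est.a <= 0.120 and 0.060 <= est.b <= 0.120


def test_untrained_boundary_model_raises(healthy_forward):
    _, ds = healthy_forward
    with pytest.raises(Exception):
        estimate_boundary(ds, None)
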