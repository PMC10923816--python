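"""Synthetic S-parameter generator: phantoms, Born forward model, noise.

The physical device is replaced by a desk-scale linear surrogate: a 2-D
scalar-Helmholtz Born (single-scattering) model in the homogeneous
coupling background.  A head is a two-layer phantom — coupling medium
outside an elliptical boundary, a homogeneous brain-average interior,
and optionally a single circular stroke inclusion.  Hemorrhage (ICH)
raises permittivity and conductivity, ischemia (IS) lowers both.

All randomness is seeded; identical seeds reproduce phantoms, noise and
whole cohorts bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import hankel1

from .core import (EPS0, AntennaArray, DimensionError, Ellipse,
                   FrequencySweep, GeometryError, ImageGrid,
                   PropagationModel, ScatteringDataset, quadrant_of_point)
from .greens import antenna_grid_greens, greens

# default stroke dielectric contrasts relative to the brain-average
# interior (the sign is the physics; the magnitudes are package
# assumptions, see docs/methods.md)
ICH_CONTRAST = (+18.0, +0.8)   # (delta eps_r, delta sigma S/m)
IS_CONTRAST = (-12.0, -0.4)

# homogeneous brain-average interior at ~1 GHz (between white and grey
# matter values)
BRAIN_EPS_R = 42.0
BRAIN_SIGMA = 0.75

# homogeneous reference (calibration) disk phantoms: dielectric
# properties below / above the head average
CAL_LOW_PROPS = (38.0, 0.55)
CAL_HIGH_PROPS = (52.0, 0.95)
CAL_DISK_RADIUS = 0.085

# desk-scale cohort default: 41 frequency points across the device band
COHORT_NF = 41

STROKE_CLASSES = ("healthy", "ICH", "IS")


@dataclass(frozen=True)
class StrokeInclusion:
    """Single circular dielectric inclusion (the stroke)."""

    stroke_class: str
    center: tuple[float, float]
    radius: float
    delta_eps: float
    delta_sigma: float

    def __post_init__(self):
        if self.stroke_class not in ("ICH", "IS"):
            raise ValueError(f"unknown stroke class {self.stroke_class!r}")
        if self.stroke_class == "ICH" and not (
                self.delta_eps > 0 and self.delta_sigma > 0):
            raise ValueError("ICH requires positive dielectric contrast")
        if self.stroke_class == "IS" and not (
                self.delta_eps < 0 and self.delta_sigma < 0):
            raise ValueError("IS requires negative dielectric contrast")


@dataclass
class HeadPhantom:
    """Gridded dielectric map: eps_r / sigma per pixel, plus ground truth.

    The maps are frequency-constant; dispersion enters only through the
    sigma/(omega eps0) term of the complex permittivity.
    """

    grid: ImageGrid
    eps_r: np.ndarray
    sigma: np.ndarray
    boundary: Ellipse
    inclusion: StrokeInclusion | None
    seed: int | None = None
    label: str = ""

    @property
    def stroke_class(self) -> str:
        return self.inclusion.stroke_class if self.inclusion else "healthy"

    def complex_permittivity(self, f: float) -> np.ndarray:
        return self.eps_r + 1j * self.sigma / (2 * np.pi * f * EPS0)


def _fill_maps(grid: ImageGrid, boundary: Ellipse | None,
               interior: tuple[float, float],
               background: tuple[float, float],
               inclusion: StrokeInclusion | None
               ) -> tuple[np.ndarray, np.ndarray]:
    xx, yy = grid.mesh()
    eps = np.full(grid.shape, background[0])
    sig = np.full(grid.shape, background[1])
    if boundary is not None:
        inside = boundary.contains(xx, yy)
        eps[inside] = interior[0]
        sig[inside] = interior[1]
    if inclusion is not None:
        cx, cy = inclusion.center
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= inclusion.radius ** 2
        eps[disk] += inclusion.delta_eps
        sig[disk] += inclusion.delta_sigma
    return eps, sig


def make_phantom(seed: int, stroke_class: str = "healthy", *,
                 grid: ImageGrid | None = None,
                 boundary: Ellipse | None = None,
                 prop: PropagationModel | None = None,
                 interior: tuple[float, float] = (BRAIN_EPS_R, BRAIN_SIGMA),
                 ich_contrast: tuple[float, float] = ICH_CONTRAST,
                 is_contrast: tuple[float, float] = IS_CONTRAST,
                 radius_range: tuple[float, float] = (0.0075, 0.025),
                 center_fraction: float = 0.8,
                 max_retries: int = 200) -> HeadPhantom:
    """Deterministic head phantom; diseased classes get a random inclusion.

    The inclusion center is drawn uniformly inside ``center_fraction`` of
    the boundary ellipse and the radius uniformly from ``radius_range``;
    draws whose disk would cross the boundary are rejected and retried.
    """
    if stroke_class not in STROKE_CLASSES:
        raise ValueError(f"unknown stroke class {stroke_class!r}")
    grid = grid or ImageGrid.default()
    boundary = boundary or Ellipse(0.0, 0.0, 0.080, 0.100)
    prop = prop or PropagationModel()
    rng = np.random.default_rng(seed)
    inclusion = None
    if stroke_class != "healthy":
        d_eps, d_sig = ich_contrast if stroke_class == "ICH" else is_contrast
        for _ in range(max_retries):
            r = rng.uniform(*radius_range)
            x = rng.uniform(boundary.cx - boundary.a, boundary.cx + boundary.a)
            y = rng.uniform(boundary.cy - boundary.b, boundary.cy + boundary.b)
            if not boundary.contains(x, y, scale=center_fraction):
                continue
            sa, sb = boundary.a - r, boundary.b - r
            if sa <= 0 or sb <= 0:
                continue
            dx, dy = x - boundary.cx, y - boundary.cy
            if (dx / sa) ** 2 + (dy / sb) ** 2 > 1.0:
                continue  # disk would cross the boundary
            inclusion = StrokeInclusion(stroke_class, (x, y), r, d_eps, d_sig)
            break
        else:
            raise GeometryError("could not place inclusion inside boundary")
    eps, sig = _fill_maps(grid, boundary, interior,
                          (prop.eps_b, prop.sigma_b), inclusion)
    return HeadPhantom(grid, eps, sig, boundary, inclusion, seed=seed,
                       label=f"{stroke_class}-seed{seed}")


def scatterer_only_phantom(center: tuple[float, float], radius: float,
                           delta: tuple[float, float], *,
                           grid: ImageGrid | None = None,
                           boundary: Ellipse | None = None,
                           prop: PropagationModel | None = None
                           ) -> HeadPhantom:
    """Phantom whose interior equals the background: only the inclusion
    scatters.  Useful for point-target oracles."""
    grid = grid or ImageGrid.default()
    boundary = boundary or Ellipse(0.0, 0.0, 0.080, 0.100)
    prop = prop or PropagationModel()
    cls = "ICH" if delta[0] > 0 else "IS"
    inc = StrokeInclusion(cls, tuple(center), radius, *delta)
    eps, sig = _fill_maps(grid, None, (prop.eps_b, prop.sigma_b),
                          (prop.eps_b, prop.sigma_b), inc)
    return HeadPhantom(grid, eps, sig, boundary, inc,
                       label=f"scatterer-{cls}")


def calibration_phantom(which: str, *, grid: ImageGrid | None = None,
                        prop: PropagationModel | None = None,
                        radius: float = CAL_DISK_RADIUS) -> HeadPhantom:
    """Homogeneous reference disk with properties below ('low') or above
    ('high') the head average."""
    grid = grid or ImageGrid.default()
    prop = prop or PropagationModel()
    props = {"low": CAL_LOW_PROPS, "high": CAL_HIGH_PROPS}[which]
    disk = Ellipse(0.0, 0.0, radius, radius)
    eps, sig = _fill_maps(grid, disk, props,
                          (prop.eps_b, prop.sigma_b), None)
    return HeadPhantom(grid, eps, sig, disk, None, label=f"cal-{which}")


# --------------------------------------------------------------------------
# Born forward model
# --------------------------------------------------------------------------


def forward_scatter(phantom: HeadPhantom, array: AntennaArray,
                    sweep: FrequencySweep, prop: PropagationModel
                    ) -> ScatteringDataset:
    """Born single-scattering S-parameters for a gridded phantom.

    S_ij(f) = G(r_i, r_j) + k_b^2 sum_pixels G(r_i, r') chi(r')
              G(r', r_j) dA,  chi = (eps_c - eps_c_b) / eps_c_b.

    The direct antenna-to-antenna coupling G(r_i, r_j) (zero on the
    diagonal) stands in for the incident/background response.  The
    kernel is symmetric, so reciprocity S_ij = S_ji holds exactly.
    """
    grid = phantom.grid
    lam_min = float(prop.wavelength(sweep.frequencies[-1]))
    if grid.pixel > lam_min / 10 + 1e-12:
        raise GeometryError(
            f"grid pixel {grid.pixel * 1e3:.2f} mm exceeds lambda/10 = "
            f"{lam_min / 10 * 1e3:.2f} mm at the top frequency")
    ax, ay = array.positions[:, 0], array.positions[:, 1]
    if np.any(phantom.boundary.contains(ax, ay)):
        raise GeometryError("antenna lies inside the head boundary")

    g_all = antenna_grid_greens(array, grid, sweep, prop)  # (Nf, Na, Npix)
    nz = ((phantom.eps_r != prop.eps_b) |
          (phantom.sigma != prop.sigma_b)).ravel()
    nz_idx = np.flatnonzero(nz)
    da = grid.pixel_area
    ks = prop.wavenumber(sweep.frequencies)
    na = array.na
    s = np.empty((na, na, sweep.nf), dtype=complex)
    eps_flat = phantom.eps_r.ravel()[nz_idx]
    sig_flat = phantom.sigma.ravel()[nz_idx]
    # direct coupling, identical structure at each frequency
    d_ant = np.linalg.norm(array.positions[None] - array.positions[:, None],
                           axis=2)
    np.fill_diagonal(d_ant, 1.0)
    for m, f in enumerate(sweep.frequencies):
        k = ks[m]
        direct = 0.25j * hankel1(0, k * d_ant)
        np.fill_diagonal(direct, 0.0)
        if nz_idx.size:
            w = 2 * np.pi * f * EPS0
            eps_c = eps_flat + 1j * sig_flat / w
            eps_cb = prop.eps_b + 1j * prop.sigma_b / w
            chi = (eps_c - eps_cb) / eps_cb
            gn = g_all[m][:, nz_idx]
            sc = (k * k * da) * ((gn * chi) @ gn.T)
            sm = direct + sc
        else:
            sm = direct
        s[:, :, m] = 0.5 * (sm + sm.T)  # enforce exact reciprocity
    return ScatteringDataset(s, sweep, array, label=phantom.label)


# --------------------------------------------------------------------------
# measurement noise and drift
# --------------------------------------------------------------------------


@dataclass
class NoiseModel:
    """Additive complex Gaussian noise plus per-port affine drift.

    ``gains`` are per-port complex gain errors g_i (applied as g_i g_j),
    ``offsets`` are per-channel complex leakage offsets (constant over
    frequency), so each channel sees the affine map S -> g_i g_j S + o_ij
    that the two-phantom calibration inverts exactly.  ``jump_scan``
    marks one scan of a repeat series as motion-corrupted.
    """

    snr_db: float
    gains: np.ndarray
    offsets: np.ndarray
    jump_scan: int | None = None
    jump_db: float = 20.0

    def __post_init__(self):
        if not (np.isfinite(self.snr_db) or np.isposinf(self.snr_db)):
            raise ValueError("snr_db must be finite or +inf")
        if np.any(self.gains == 0):
            raise ValueError("drift gains must be nonzero")

    @classmethod
    def ideal(cls, na: int) -> "NoiseModel":
        return cls(np.inf, np.ones(na, dtype=complex),
                   np.zeros((na, na), dtype=complex))

    @classmethod
    def draw(cls, rng: np.random.Generator, na: int, *,
             snr_db: float = 30.0, gain_std: float = 0.05,
             offset_scale: float = 2e-4, jump_scan: int | None = None,
             jump_db: float = 20.0) -> "NoiseModel":
        gains = 1.0 + gain_std * (rng.standard_normal(na)
                                  + 1j * rng.standard_normal(na)) / np.sqrt(2)
        off = offset_scale * (rng.standard_normal((na, na))
                              + 1j * rng.standard_normal((na, na))
                              ) / np.sqrt(2)
        off = 0.5 * (off + off.T)  # leakage is reciprocal
        return cls(snr_db, gains, off, jump_scan=jump_scan, jump_db=jump_db)


def add_noise(ds: ScatteringDataset, noise: NoiseModel, seed: int,
              scan_index: int | None = None) -> ScatteringDataset:
    """Apply drift, then additive noise at the requested per-channel SNR.

    SNR is defined against the per-channel RMS of the input over
    frequency.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    s = (noise.gains[:, None, None] * noise.gains[None, :, None] * ds.s
         + noise.offsets[:, :, None])
    if np.isfinite(noise.snr_db):
        rms = np.sqrt(np.mean(np.abs(ds.s) ** 2, axis=2, keepdims=True))
        sigma = rms * 10 ** (-noise.snr_db / 20.0)
        n = (rng.standard_normal(s.shape)
             + 1j * rng.standard_normal(s.shape)) / np.sqrt(2)
        s = s + sigma * n
    if scan_index is not None and scan_index == noise.jump_scan:
        rms_all = np.sqrt(np.mean(np.abs(ds.s) ** 2))
        amp = rms_all * 10 ** (noise.jump_db / 20.0)
        j = (rng.standard_normal(s.shape)
             + 1j * rng.standard_normal(s.shape)) / np.sqrt(2)
        s = s + amp * j
    return ds.copy_with(s=s, label=f"{ds.label}+noise")


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------


@dataclass
class CohortPatient:
    patient_id: str
    stroke_class: str
    phantom: HeadPhantom
    scans: list
    calibration: "object"          # calibration.CalibrationRecord
    quadrant: str | None
    seed: int


def _class_counts(n: int, class_mix: dict[str, float]) -> list[str]:
    total = sum(class_mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class_mix must sum to 1, got {total}")
    items = sorted(class_mix.items())
    exact = {c: n * p for c, p in items}
    counts = {c: int(np.floor(v)) for c, v in exact.items()}
    rem = n - sum(counts.values())
    for c, _ in sorted(items, key=lambda kv: exact[kv[0]] - counts[kv[0]],
                       reverse=True)[:rem]:
        counts[c] += 1
    labels = [c for c, k in sorted(counts.items()) for _ in range(k)]
    return labels


def generate_cohort(n_patients: int, class_mix: dict[str, float],
                    scans_per_patient: int = 20, seed: int = 0, *,
                    sweep: FrequencySweep | None = None,
                    grid: ImageGrid | None = None,
                    array: AntennaArray | None = None,
                    prop: PropagationModel | None = None,
                    snr_db: float = 30.0,
                    outlier_prob: float = 0.25,
                    radius_range: tuple[float, float] = (0.0075, 0.025),
                    boundary_a_range: tuple[float, float] = (0.070, 0.092),
                    boundary_b_range: tuple[float, float] = (0.088, 0.112),
                    manifest_path=None
                    ) -> tuple[list[CohortPatient], pd.DataFrame]:
    """Seeded synthetic patient cohort with repeat scans and references.

    Per patient: a randomized head ellipse and (for diseased classes) a
    random inclusion, ``scans_per_patient`` noisy scan replicates under
    one per-session drift realization (optionally with one
    motion-corrupted outlier scan), and measurements of the two
    homogeneous calibration phantoms under the same drift.
    """
    from .calibration import CalibrationRecord  # local: avoid import cycle

    sweep = sweep or FrequencySweep.default(n=COHORT_NF)
    grid = grid or ImageGrid.default()
    array = array or AntennaArray.default_ring()
    prop = prop or PropagationModel()
    rng = np.random.default_rng(seed)

    labels = _class_counts(n_patients, class_mix)
    rng.shuffle(labels)

    ideal_low = forward_scatter(calibration_phantom("low", grid=grid,
                                                    prop=prop),
                                array, sweep, prop)
    ideal_high = forward_scatter(calibration_phantom("high", grid=grid,
                                                     prop=prop),
                                 array, sweep, prop)

    patients: list[CohortPatient] = []
    rows = []
    for p in range(n_patients):
        p_seed = int(rng.integers(0, 2**31 - 1))
        p_rng = np.random.default_rng(p_seed)
        a = p_rng.uniform(*boundary_a_range)
        b = p_rng.uniform(*boundary_b_range)
        boundary = Ellipse(0.0, 0.0, a, b)
        phantom = make_phantom(int(p_rng.integers(0, 2**31 - 1)),
                               labels[p], grid=grid, boundary=boundary,
                               prop=prop, radius_range=radius_range)
        ideal = forward_scatter(phantom, array, sweep, prop)
        jump = (int(p_rng.integers(1, scans_per_patient))
                if (outlier_prob > 0 and p_rng.uniform() < outlier_prob
                    and scans_per_patient > 2) else None)
        noise = NoiseModel.draw(p_rng, array.na, snr_db=snr_db,
                                jump_scan=jump)
        scans = [add_noise(ideal, noise, int(p_rng.integers(0, 2**31 - 1)),
                           scan_index=k)
                 for k in range(scans_per_patient)]
        # reference sweeps are acquired as the average of the same number
        # of repeats as the patient series, so their noise floor is
        # 10 log10(n_scans) dB lower
        cal_snr = snr_db + 10.0 * np.log10(max(scans_per_patient, 1))
        cal_noise = NoiseModel(cal_snr, noise.gains, noise.offsets)
        cal = CalibrationRecord(
            low=add_noise(ideal_low, cal_noise,
                          int(p_rng.integers(0, 2**31 - 1))),
            high=add_noise(ideal_high, cal_noise,
                           int(p_rng.integers(0, 2**31 - 1))),
            low_props=CAL_LOW_PROPS, high_props=CAL_HIGH_PROPS,
            synthesized_low=ideal_low, synthesized_high=ideal_high)
        inc = phantom.inclusion
        quadrant = (quadrant_of_point(inc.center).quadrant
                    if inc is not None else None)
        pid = f"p{p:03d}"
        patients.append(CohortPatient(pid, labels[p], phantom, scans, cal,
                                      quadrant, p_seed))
        rows.append({
            "patient_id": pid, "class": labels[p],
            "cx": inc.center[0] if inc else np.nan,
            "cy": inc.center[1] if inc else np.nan,
            "radius": inc.radius if inc else np.nan,
            "quadrant": quadrant or "", "seed": p_seed,
        })
    manifest = pd.DataFrame(rows)
    if manifest_path is not None:
        manifest.to_csv(manifest_path, index=False)
    return patients, manifest
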