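"""Shared domain types, geometry conventions and file I/O.

Coordinate convention (used everywhere in the package): head-centered,
x in meters toward the patient's *left*, y in meters toward *anterior*
(the face).  The sagittal mirror line is the y-axis.  Images are stored
as ``values[iy, ix]`` with both axes ascending.

Measurement currency: a complex scattering tensor ``S[i, j, k]`` holding
the ratio of the wave received at antenna i to the wave transmitted at
antenna j, at frequency ``sweep.frequencies[k]``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import get_window

# vacuum constants (SI)
MU0 = 4e-7 * np.pi
EPS0 = 8.8541878128e-12
C0 = 1.0 / np.sqrt(MU0 * EPS0)

MAX_S_MAGNITUDE = 10.0  # sanity bound for linear S-parameter ratios


class EmibrainError(Exception):
    """Base class for all package errors."""


class TouchstoneParseError(EmibrainError):
    pass


class DimensionError(EmibrainError):
    pass


class GeometryError(EmibrainError):
    pass


# --------------------------------------------------------------------------
# frequency sweep
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FrequencySweep:
    """Strictly ascending frequency grid in Hz."""

    frequencies: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 1 or f.size < 2:
            raise DimensionError("sweep needs at least 2 frequency points")
        if not np.all(f > 0):
            raise ValueError("frequencies must be positive")
        if not np.all(np.diff(f) > 0):
            raise ValueError("frequencies must be strictly ascending")
        object.__setattr__(self, "frequencies", f)

    @classmethod
    def default(cls, f_start: float = 0.7e9, f_stop: float = 1.8e9,
                n: int = 201) -> "FrequencySweep":
        return cls(np.linspace(f_start, f_stop, n))

    @property
    def nf(self) -> int:
        return self.frequencies.size

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        d = np.diff(self.frequencies)
        return bool(np.all(np.abs(d - d[0]) <= rtol * d[0]))


# --------------------------------------------------------------------------
# antenna array
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AntennaArray:
    """Planar antenna ring around the head.

    ``positions[k]`` is (x, y) in meters; ``angles_deg[k]`` is the
    placement angle measured counterclockwise from +x.  The sagittal
    mirror line is fixed as the y-axis, so no antenna may sit at
    x == 0 (a mirrored layout must pair every element).
    """

    positions: np.ndarray
    angles_deg: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.positions, dtype=float)
        a = np.asarray(self.angles_deg, dtype=float)
        if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] != a.size:
            raise DimensionError("positions must be (Na, 2) matching angles")
        if p.shape[0] % 2 != 0:
            raise GeometryError("antenna count must be even for mirror pairing")
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "angles_deg", a)

    @classmethod
    def default_ring(cls, n: int = 16, semi_x: float = 0.110,
                     semi_y: float = 0.130, angle_offset_deg: float = 11.25
                     ) -> "AntennaArray":
        """Uniform elliptical ring; the default offset of 11.25 degrees keeps
        every element off the sagittal axis."""
        ang = angle_offset_deg + np.arange(n) * (360.0 / n)
        rad = np.deg2rad(ang)
        pos = np.stack([semi_x * np.cos(rad), semi_y * np.sin(rad)], axis=1)
        return cls(pos, ang)

    @property
    def na(self) -> int:
        return self.positions.shape[0]

    @property
    def mirror(self) -> np.ndarray:
        """Index map k -> k' of the antenna mirrored across the y-axis."""
        return _mirror_table(self)

    def hemisphere(self, k: int) -> str:
        """'left' (+x) or 'right' (−x) of the sagittal axis."""
        return "left" if self.positions[k, 0] > 0 else "right"

    @property
    def left_indices(self) -> np.ndarray:
        return np.flatnonzero(self.positions[:, 0] > 0)

    @property
    def right_indices(self) -> np.ndarray:
        return np.flatnonzero(self.positions[:, 0] < 0)


_MIRROR_CACHE: dict[bytes, np.ndarray] = {}


def _mirror_table(array: AntennaArray) -> np.ndarray:
    key = array.positions.tobytes()
    tab = _MIRROR_CACHE.get(key)
    if tab is not None:
        return tab
    pos = array.positions
    scale = float(np.max(np.abs(pos))) or 1.0
    if np.any(np.abs(pos[:, 0]) < 1e-9 * scale):
        raise GeometryError("antenna lies on the sagittal axis; "
                            "mirror pairing undefined")
    mirrored = pos * np.array([-1.0, 1.0])
    d = np.linalg.norm(pos[None, :, :] - mirrored[:, None, :], axis=2)
    tab = np.argmin(d, axis=1)
    if np.any(d[np.arange(array.na), tab] > 1e-6 * scale):
        raise GeometryError("layout is not mirror-symmetric about the y-axis")
    if np.any(tab[tab] != np.arange(array.na)) or np.any(tab == np.arange(array.na)):
        raise GeometryError("mirror pairing is not a fixed-point-free involution")
    _MIRROR_CACHE[key] = tab
    return tab


def mirror_index(k: int, array: AntennaArray) -> int:
    """Antenna index mirrored across the sagittal (y) axis.

    An involution with no fixed point for any valid layout.
    """
    return int(_mirror_table(array)[k])


# --------------------------------------------------------------------------
# scattering dataset
# --------------------------------------------------------------------------


@dataclass
class ScatteringDataset:
    """Complex S-parameter tensor (Na, Na, Nf) with its sweep and array.

    ``channel_mask`` marks channels usable downstream (False = flagged
    uncalibratable or missing); None means all channels valid.
    """

    s: np.ndarray
    sweep: FrequencySweep
    array: AntennaArray
    label: str = ""
    channel_mask: np.ndarray | None = None

    def __post_init__(self):
        s = np.asarray(self.s, dtype=complex)
        na, nf = self.array.na, self.sweep.nf
        if s.shape != (na, na, nf):
            raise DimensionError(
                f"S tensor shape {s.shape} != ({na}, {na}, {nf})")
        if not np.all(np.isfinite(s)):
            raise ValueError("S tensor contains non-finite entries")
        if np.max(np.abs(s)) > MAX_S_MAGNITUDE:
            raise ValueError(
                f"|S| exceeds sanity bound {MAX_S_MAGNITUDE}; not a "
                "linear-ratio S-parameter dataset")
        self.s = s

    def copy_with(self, **kw) -> "ScatteringDataset":
        return replace(self, **kw)

    @property
    def na(self) -> int:
        return self.array.na

    def valid_mask(self) -> np.ndarray:
        if self.channel_mask is None:
            return np.ones((self.na, self.na), dtype=bool)
        return self.channel_mask


# --------------------------------------------------------------------------
# propagation model
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PropagationModel:
    """Homogeneous lossy background (the coupling medium).

    Defaults match a coupling medium with relative permittivity 45 and
    conductivity 0.15 S/m.  Sign convention e^{-j omega t}: complex
    permittivity eps' + j sigma/(omega eps0), so Im(k) > 0 and the
    outgoing 2-D Green's function (j/4) H0^(1)(k r) decays with range.
    """

    eps_b: float = 45.0
    sigma_b: float = 0.15

    def complex_permittivity(self, f) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        return self.eps_b + 1j * self.sigma_b / (2 * np.pi * f * EPS0)

    def wavenumber(self, f) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        k = 2 * np.pi * f * np.sqrt(MU0 * EPS0 * self.complex_permittivity(f))
        return k

    def wavelength(self, f) -> np.ndarray:
        return 2 * np.pi / np.real(self.wavenumber(f))


# --------------------------------------------------------------------------
# image grid and intensity images
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageGrid:
    """Regular head-centered 2-D lattice; ``x``/``y`` are pixel centers."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))

    @classmethod
    def default(cls, half_x: float = 0.12, half_y: float = 0.14,
                pixel: float = 0.002) -> "ImageGrid":
        # pixel centers as signed multiples of the pitch: bitwise
        # negation-symmetric, so mirror tests on the lattice are exact
        nx = int(round(2 * half_x / pixel)) + 1
        ny = int(round(2 * half_y / pixel)) + 1
        return cls((np.arange(nx) - (nx - 1) // 2) * pixel,
                   (np.arange(ny) - (ny - 1) // 2) * pixel)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.y.size, self.x.size)

    @property
    def pixel(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def pixel_area(self) -> float:
        return float((self.x[1] - self.x[0]) * (self.y[1] - self.y[0]))

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x, self.y)

    def points(self) -> np.ndarray:
        """Flattened (N, 2) array of pixel-center coordinates."""
        xx, yy = self.mesh()
        return np.stack([xx.ravel(), yy.ravel()], axis=1)


MODALITIES = ("linecross", "dmm", "beamography", "evsla", "fused")


@dataclass
class IntensityImage:
    """Non-negative stroke-likelihood map on an :class:`ImageGrid`."""

    grid: ImageGrid
    values: np.ndarray
    modality: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.shape:
            raise DimensionError("image values do not match grid shape")
        if np.any(v < 0):
            raise ValueError("intensity values must be non-negative")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        self.values = v

    def normalized(self) -> "IntensityImage":
        m = self.values.max()
        v = self.values / m if m > 0 else self.values.copy()
        return IntensityImage(self.grid, v, self.modality)

    def peak(self) -> tuple[float, float]:
        iy, ix = np.unravel_index(np.argmax(self.values), self.values.shape)
        return float(self.grid.x[ix]), float(self.grid.y[iy])

    def to_csv(self, path) -> None:
        np.savetxt(path, self.values, delimiter=",")


# --------------------------------------------------------------------------
# ellipse boundary
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned-by-default ellipse (cx, cy, a, b, rotation in degrees)."""

    cx: float
    cy: float
    a: float
    b: float
    rotation_deg: float = 0.0

    def contains(self, x, y, scale: float = 1.0):
        """Vectorized point-in-ellipse test, with an optional uniform
        shrink factor (scale < 1 tests against a smaller ellipse)."""
        th = np.deg2rad(self.rotation_deg)
        dx, dy = np.asarray(x) - self.cx, np.asarray(y) - self.cy
        u = np.cos(th) * dx + np.sin(th) * dy
        v = -np.sin(th) * dx + np.cos(th) * dy
        return (u / (self.a * scale)) ** 2 + (v / (self.b * scale)) ** 2 <= 1.0

    def normalized_radius(self, x, y):
        th = np.deg2rad(self.rotation_deg)
        dx, dy = np.asarray(x) - self.cx, np.asarray(y) - self.cy
        u = np.cos(th) * dx + np.sin(th) * dy
        v = -np.sin(th) * dx + np.cos(th) * dy
        return np.sqrt((u / self.a) ** 2 + (v / self.b) ** 2)

    def polygon(self, n: int = 90) -> np.ndarray:
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        th = np.deg2rad(self.rotation_deg)
        u, v = self.a * np.cos(t), self.b * np.sin(t)
        x = self.cx + np.cos(th) * u - np.sin(th) * v
        y = self.cy + np.sin(th) * u + np.cos(th) * v
        return np.stack([x, y], axis=1)


# --------------------------------------------------------------------------
# quadrant convention
# --------------------------------------------------------------------------

QUADRANTS = ("anterior-left", "anterior-right",
             "posterior-left", "posterior-right")


@dataclass(frozen=True)
class QuadrantCall:
    quadrant: str
    peak: tuple[float, float]
    on_axis: bool = False


def quadrant_of_point(p: Sequence[float]) -> QuadrantCall:
    """Quadrant of a head-centered point: +y anterior, +x patient-left.

    Points on an axis are broken toward anterior, then left, and flagged.
    """
    x, y = float(p[0]), float(p[1])
    on_axis = (x == 0.0) or (y == 0.0)
    ant = "anterior" if y >= 0 else "posterior"
    side = "left" if x >= 0 else "right"
    return QuadrantCall(f"{ant}-{side}", (x, y), on_axis)


# --------------------------------------------------------------------------
# Touchstone v1 I/O
# --------------------------------------------------------------------------


def write_touchstone(ds: ScatteringDataset, path) -> None:
    """Write a Touchstone v1 .sNp file (Hz, S, real/imaginary)."""
    if not np.all(np.isfinite(ds.s)):
        raise ValueError("refusing to write non-finite S-parameters")
    n = ds.na
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"! emibrain scattering dataset: {ds.label}\n")
        fh.write(f"! {n} ports, {ds.sweep.nf} frequency points\n")
        fh.write("# HZ S RI R 50\n")
        for k, f in enumerate(ds.sweep.frequencies):
            m = ds.s[:, :, k]
            if n == 2:
                # 2-port files use column ordering S11 S21 S12 S22
                vals = [m[0, 0], m[1, 0], m[0, 1], m[1, 1]]
                row = " ".join(f"{v.real:.15e} {v.imag:.15e}" for v in vals)
                fh.write(f"{f:.10e} {row}\n")
            else:
                fh.write(f"{f:.10e}\n")
                for i in range(n):
                    row = m[i]
                    for start in range(0, n, 4):
                        chunk = row[start:start + 4]
                        fh.write(" ".join(
                            f"{v.real:.15e} {v.imag:.15e}" for v in chunk))
                        fh.write("\n")


def read_touchstone(path, array: AntennaArray | None = None,
                    label: str | None = None) -> ScatteringDataset:
    """Read a Touchstone v1 .sNp file written in RI format.

    The port count is taken from the file extension (.sNp).  If ``array``
    is given its size must match; otherwise a default ring of N antennas
    is attached.  Files with descending frequencies are re-sorted
    ascending.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if not (suffix.startswith(".s") and suffix.endswith("p")):
        raise TouchstoneParseError(f"{path.name}: not a .sNp file")
    try:
        n = int(suffix[2:-1])
    except ValueError:
        raise TouchstoneParseError(f"{path.name}: cannot parse port count "
                                   f"from extension {suffix!r}") from None
    if array is not None and array.na != n:
        raise DimensionError(
            f"file has {n} ports but array has {array.na} antennas")

    unit_scale = {"HZ": 1.0, "KHZ": 1e3, "MHZ": 1e6, "GHZ": 1e9}
    scale = 1.0
    fmt = "RI"
    tokens: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("!", 1)[0].strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].upper().split()
                for p in parts:
                    if p in unit_scale:
                        scale = unit_scale[p]
                    elif p in ("RI", "MA", "DB"):
                        fmt = p
                continue
            for tok in line.split():
                try:
                    tokens.append(float(tok))
                except ValueError:
                    raise TouchstoneParseError(
                        f"{path.name}:{lineno}: bad token {tok!r}") from None
    per_block = 1 + 2 * n * n
    if len(tokens) % per_block != 0:
        raise TouchstoneParseError(
            f"{path.name}: token count {len(tokens)} is not a whole number "
            f"of {n}-port frequency blocks")
    nf = len(tokens) // per_block
    data = np.asarray(tokens, dtype=float).reshape(nf, per_block)
    freqs = data[:, 0] * scale
    pairs = data[:, 1:].reshape(nf, n * n, 2)
    if fmt == "RI":
        vals = pairs[..., 0] + 1j * pairs[..., 1]
    elif fmt == "MA":
        vals = pairs[..., 0] * np.exp(1j * np.deg2rad(pairs[..., 1]))
    else:  # DB
        vals = 10 ** (pairs[..., 0] / 20.0) * np.exp(
            1j * np.deg2rad(pairs[..., 1]))
    s = vals.reshape(nf, n, n)
    if n == 2:
        # undo 2-port column ordering (S11 S21 S12 S22)
        s = s.transpose(0, 2, 1)
    s = np.moveaxis(s, 0, 2)  # -> (n, n, nf)
    order = np.argsort(freqs)
    if not np.array_equal(order, np.arange(nf)):
        freqs = freqs[order]
        s = s[:, :, order]
    if array is None:
        array = AntennaArray.default_ring(n)
    return ScatteringDataset(s, FrequencySweep(freqs), array,
                             label=label or path.stem)


# --------------------------------------------------------------------------
# antenna geometry CSV
# --------------------------------------------------------------------------


def write_antenna_csv(array: AntennaArray, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["index", "x_m", "y_m", "angle_deg"])
        for k in range(array.na):
            w.writerow([k, repr(float(array.positions[k, 0])),
                        repr(float(array.positions[k, 1])),
                        repr(float(array.angles_deg[k]))])


def read_antenna_csv(path) -> AntennaArray:
    rows = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.append((int(rec["index"]), float(rec["x_m"]),
                         float(rec["y_m"]), float(rec["angle_deg"])))
    rows.sort()
    pos = np.array([[r[1], r[2]] for r in rows])
    ang = np.array([r[3] for r in rows])
    return AntennaArray(pos, ang)


# --------------------------------------------------------------------------
# frequency -> time conversion
# --------------------------------------------------------------------------


@dataclass
class TimeDomainSignals:
    """Real per-channel time signals ``x[i, j, :]`` on a uniform grid."""

    t: np.ndarray
    x: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.t.size


def to_time_domain(ds: ScatteringDataset, window: str = "hamming",
                   pad_factor: int = 4) -> TimeDomainSignals:
    """Band-limited inverse transform of each channel's spectrum.

    The measured band [f0, f1] is windowed, placed at its physical
    offset in a zero-padded half-spectrum, hermitian-extended, and
    inverse-FFT'd; the result is real by construction.  ``pad_factor``
    stretches the half-spectrum length (finer time sampling).
    """
    if not ds.sweep.is_uniform():
        raise ValueError("non-uniform frequency grid: resample explicitly "
                         "before time conversion")
    if pad_factor < 1:
        raise ValueError("pad_factor must be >= 1")
    nf = ds.sweep.nf
    df = ds.sweep.df
    n0 = int(round(ds.sweep.frequencies[0] / df))
    if window in (None, "none"):
        w = np.ones(nf)
    else:
        w = get_window(window, nf, fftbins=False)
    half_len = pad_factor * (n0 + nf)
    spec = np.zeros(ds.s.shape[:2] + (half_len,), dtype=complex)
    spec[:, :, n0:n0 + nf] = ds.s * w
    x = np.fft.irfft(spec, axis=2)  # length 2*(half_len - 1), real
    n_t = x.shape[2]
    dt = 1.0 / (n_t * df)
    t = np.arange(n_t) * dt
    return TimeDomainSignals(t, x)
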