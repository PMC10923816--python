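"""Algorithm V: Expected-Value-based Stroke Localization (EVSLA).

Unsupervised localization from statistics on mirror-symmetric antenna
patches.  For each same-hemisphere antenna pair (i, j) with small
circular separation, the quadrilateral through antennas i, j,
mirror(j), mirror(i) straddles the sagittal axis; clipping it to each
half-plane (and to the head boundary) yields a mirror-symmetric pair
of 4-sided patches bounded by channels (i, j) on one side and
(mirror(i), mirror(j)) on the other.

Each patch carries an anomaly statistic: the HVG-entropy dissimilarity
of its bounding channels between patient and calibration reference,
differenced against the mirror patch and floored at zero; patches
below the collection median are deactivated.  The per-pixel expected
value of the active statistical fields forms the image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely import contains_xy
from shapely.geometry import Polygon

from .core import (AntennaArray, Ellipse, ImageGrid, IntensityImage,
                   ScatteringDataset, to_time_domain)
from .hvg import channel_metric_matrices

MIN_PATCH_AREA = 1e-4  # m^2 (1 cm^2): drop degenerate clipped patches

# absolute activation floor for the dissimilarity statistic (entropy is
# O(1) nats; float-level left/right residue must never activate a patch)
ACTIVATION_FLOOR = 1e-6


@dataclass
class PatchPair:
    """Mirror-symmetric pair of quadrilateral patches."""

    i: int
    j: int
    left: Polygon
    right: Polygon
    channels_left: tuple[tuple[int, int], ...]
    channels_right: tuple[tuple[int, int], ...]


@dataclass
class StatisticalField:
    polygon: Polygon
    statistic: float
    active: bool


def _circular_sep(i: int, j: int, na: int) -> int:
    return min(abs(i - j), na - abs(i - j))


def make_patch_pairs(array: AntennaArray, boundary: Ellipse,
                     sep_range: tuple[int, int] = (1, 3),
                     min_area: float = MIN_PATCH_AREA) -> list[PatchPair]:
    """Symmetric patch pairs for all same-hemisphere close antenna pairs.

    The quad (i, j, mirror(j), mirror(i)) is clipped to the head
    boundary; its intersections with the left (x >= 0) and right
    (x <= 0) half-planes form the pair.  Degenerate patches (area under
    ``min_area``) are dropped.
    """
    perm = array.mirror
    head = Polygon(boundary.polygon(180))
    ext = 10 * max(abs(boundary.cx) + boundary.a,
                   abs(boundary.cy) + boundary.b, 0.2)
    left_half = Polygon([(0, -ext), (ext, -ext), (ext, ext), (0, ext)])
    right_half = Polygon([(0, -ext), (0, ext), (-ext, ext), (-ext, -ext)])
    pairs: list[PatchPair] = []
    left_idx = set(array.left_indices.tolist())
    for i in sorted(left_idx):
        for j in sorted(left_idx):
            if j <= i:
                continue
            if not sep_range[0] <= _circular_sep(i, j, array.na) <= sep_range[1]:
                continue
            mi, mj = int(perm[i]), int(perm[j])
            quad = Polygon([tuple(array.positions[k])
                            for k in (i, j, mj, mi)])
            if not quad.is_valid:
                quad = quad.buffer(0)
            clipped = quad.intersection(head)
            lp = clipped.intersection(left_half)
            rp = clipped.intersection(right_half)
            if lp.area < min_area or rp.area < min_area:
                continue
            pairs.append(PatchPair(
                i, j, lp, rp,
                channels_left=((i, j), (j, i)),
                channels_right=((mi, mj), (mj, mi))))
    return pairs


def _channel_stat(entropy: np.ndarray, ref_entropy: np.ndarray,
                  channels) -> float:
    vals = [abs(entropy[i, j] - ref_entropy[i, j]) for i, j in channels
            if np.isfinite(entropy[i, j]) and np.isfinite(ref_entropy[i, j])]
    return float(np.mean(vals)) if vals else 0.0


def patch_statistics(entropy: np.ndarray, ref_entropy: np.ndarray,
                     pairs: list[PatchPair]) -> list[StatisticalField]:
    """Anomaly statistic per patch: bounding-channel entropy dissimilarity
    vs the calibration reference, mirror-differenced, floored at 0, and
    median-gated (only above-median patches stay active)."""
    fields: list[StatisticalField] = []
    raw: list[float] = []
    for p in pairs:
        s_left = _channel_stat(entropy, ref_entropy, p.channels_left)
        s_right = _channel_stat(entropy, ref_entropy, p.channels_right)
        stat_l = max(0.0, s_left - s_right)
        stat_r = max(0.0, s_right - s_left)
        fields.append(StatisticalField(p.left, stat_l, False))
        fields.append(StatisticalField(p.right, stat_r, False))
        raw.extend([stat_l, stat_r])
    if not fields:
        return fields
    gate = max(float(np.median(raw)), ACTIVATION_FLOOR)
    for f in fields:
        f.active = f.statistic > gate
    return fields


def expected_value_image(fields: list[StatisticalField],
                         grid: ImageGrid | None = None) -> IntensityImage:
    """Per-pixel mean statistic of the active patches covering the pixel."""
    grid = grid or ImageGrid.default()
    xx, yy = grid.mesh()
    acc = np.zeros(grid.shape)
    cnt = np.zeros(grid.shape)
    for f in fields:
        if not f.active or f.polygon.is_empty:
            continue
        inside = contains_xy(f.polygon, xx, yy)
        acc[inside] += f.statistic
        cnt[inside] += 1.0
    vals = np.zeros(grid.shape)
    nz = cnt > 0
    vals[nz] = acc[nz] / cnt[nz]
    return IntensityImage(grid, vals, "evsla").normalized()


def patch_table(fields: list[StatisticalField]) -> pd.DataFrame:
    rows = []
    for f in fields:
        rows.append({"vertices": list(f.polygon.exterior.coords)
                     if not f.polygon.is_empty else [],
                     "statistic": f.statistic, "active": f.active})
    return pd.DataFrame(rows)


def evsla_image(patient: ScatteringDataset, reference: ScatteringDataset,
                array: AntennaArray | None = None,
                boundary: Ellipse | None = None,
                grid: ImageGrid | None = None,
                sep_range: tuple[int, int] = (1, 3),
                entropy_matrices: tuple[np.ndarray, np.ndarray] | None = None
                ) -> tuple[IntensityImage, list[StatisticalField]]:
    """Full Algorithm-V pass.

    ``reference`` is the calibration (healthy-baseline) dataset whose
    channel entropies anchor the dissimilarity statistic.  Precomputed
    (patient, reference) entropy matrices may be passed to avoid
    rebuilding the visibility graphs.
    """
    array = array or patient.array
    boundary = boundary or Ellipse(0.0, 0.0, 0.080, 0.100)
    grid = grid or ImageGrid.default()
    if entropy_matrices is None:
        ent = channel_metric_matrices(
            to_time_domain(patient), array, patient.channel_mask)["entropy"]
        ref_ent = channel_metric_matrices(
            to_time_domain(reference), array,
            reference.channel_mask)["entropy"]
    else:
        ent, ref_ent = entropy_matrices
    pairs = make_patch_pairs(array, boundary, sep_range)
    fields = patch_statistics(ent, ref_ent, pairs)
    return expected_value_image(fields, grid), fields
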