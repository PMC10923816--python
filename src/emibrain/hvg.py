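"""Weighted horizontal visibility graphs and node-level metrics.

Two samples (i, j) of a series x are linked iff every intermediate
sample is strictly lower than both: x_k < min(x_i, x_j) for all
i < k < j.  Construction is stack-based and O(n) amortized.  Edge
weights are the amplitude differences |x_i - x_j| (floored at a tiny
eps so strengths stay positive), which makes node *strength* distinct
from node *degree* and gives each node an incident-weight entropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import AntennaArray, DimensionError, TimeDomainSignals

EPS_W = 1e-12  # weight floor: keeps strengths positive, entropies defined

METRICS = ("degree", "strength", "entropy")


@dataclass
class HVGraph:
    """Horizontal visibility graph: ``edges[(m, 2)]`` with i < j rows."""

    n: int
    edges: np.ndarray
    weights: np.ndarray


@dataclass
class GraphMetrics:
    degree: np.ndarray
    strength: np.ndarray
    entropy: np.ndarray

    @property
    def mean_degree(self) -> float:
        return float(self.degree.mean())

    @property
    def mean_strength(self) -> float:
        return float(self.strength.mean())

    @property
    def mean_entropy(self) -> float:
        return float(self.entropy.mean())


def build_hvg(x) -> HVGraph:
    """Stack-based horizontal visibility graph of a real series.

    Each element is pushed once and popped at most once, so the
    construction is linear-time; ties are handled so that an equal
    earlier sample is occluded by the later one.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise DimensionError("series must be 1-D with at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains NaN or infinite values")
    n = x.size
    src: list[int] = []
    dst: list[int] = []
    stack: list[int] = []
    for j in range(n):
        xj = x[j]
        while stack and x[stack[-1]] < xj:
            src.append(stack.pop())
            dst.append(j)
        if stack:
            src.append(stack[-1])
            dst.append(j)
            if x[stack[-1]] == xj:
                stack.pop()
        stack.append(j)
    edges = np.stack([np.asarray(src, dtype=np.intp),
                      np.asarray(dst, dtype=np.intp)], axis=1)
    weights = np.abs(x[edges[:, 0]] - x[edges[:, 1]]) + EPS_W
    return HVGraph(n, edges, weights)


def graph_metrics(g: HVGraph) -> GraphMetrics:
    """Per-node degree, strength and incident-weight entropy (nats)."""
    if g.n == 0 or g.edges.size == 0:
        raise DimensionError("empty graph has no metrics")
    deg = np.zeros(g.n)
    strength = np.zeros(g.n)
    np.add.at(deg, g.edges[:, 0], 1.0)
    np.add.at(deg, g.edges[:, 1], 1.0)
    np.add.at(strength, g.edges[:, 0], g.weights)
    np.add.at(strength, g.edges[:, 1], g.weights)
    # H_i = -sum_j p_ij ln p_ij over incident edges, p_ij = w_ij / s_i
    wlogw = g.weights * np.log(g.weights)
    swl = np.zeros(g.n)
    np.add.at(swl, g.edges[:, 0], wlogw)
    np.add.at(swl, g.edges[:, 1], wlogw)
    ent = np.log(strength) - swl / strength
    ent[deg <= 1] = 0.0
    ent = np.maximum(ent, 0.0)  # clip tiny negative rounding residue
    return GraphMetrics(deg, strength, ent)


def series_metrics(x) -> tuple[float, float, float]:
    """Mean node (degree, strength, entropy) of the HVG of a series."""
    m = graph_metrics(build_hvg(x))
    return m.mean_degree, m.mean_strength, m.mean_entropy


def channel_metric_matrices(tds: TimeDomainSignals,
                            array: AntennaArray | None = None,
                            channel_mask: np.ndarray | None = None
                            ) -> dict[str, np.ndarray]:
    """All three Na x Na channel-metric matrices in one pass.

    ``M[metric][i, j]`` is the mean node metric of the HVG of channel
    (i, j)'s time signal.  Masked channels become NaN.  A degenerate
    all-constant dataset (flat HVGs everywhere) is flagged with a
    warning but still returned.
    """
    na = tds.x.shape[0]
    out = {m: np.full((na, na), np.nan) for m in METRICS}
    for i in range(na):
        for j in range(na):
            if channel_mask is not None and not channel_mask[i, j]:
                continue
            d, s, e = series_metrics(tds.x[i, j])
            out["degree"][i, j] = d
            out["strength"][i, j] = s
            out["entropy"][i, j] = e
    if (np.nanstd(out["degree"]) < 1e-9
            and np.nanstd(out["strength"]) < 1e-9):
        warnings.warn("degenerate flat signals: constant metric matrices",
                      stacklevel=2)
    return out


def channel_metric_matrix(tds: TimeDomainSignals, metric: str,
                          array: AntennaArray | None = None,
                          channel_mask: np.ndarray | None = None
                          ) -> np.ndarray:
    """Single channel-metric matrix; see :func:`channel_metric_matrices`."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    return channel_metric_matrices(tds, array, channel_mask)[metric]
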