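"""Algorithm II: graph-similarity classification and line-crossing maps.

A healthy head is approximately mirror-symmetric about the sagittal
plane, so the channel-metric matrix M of a healthy scan nearly commutes
with the mirror permutation P.  The *differential* matrix
D = M - P M P^T isolates the asymmetry a unilateral stroke introduces.
Features summarizing the three differential matrices (degree, strength,
entropy) feed a four-classifier probability ensemble (random forest,
k-nearest-neighbors, Gaussian naive Bayes, SVM), and the per-channel
differential entropies weight ray corridors between antenna pairs to
form a localization map: rays crossing the stroke carry larger
differential entropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import (AntennaArray, DimensionError, Ellipse, ImageGrid,
                   IntensityImage, TimeDomainSignals, to_time_domain)
from .hvg import METRICS, channel_metric_matrices

CLASS_ORDER = ("healthy", "ICH", "IS")


@dataclass
class DifferentialFeatureSet:
    """Hemisphere-differential matrices and their summary features."""

    d_degree: np.ndarray
    d_strength: np.ndarray
    d_entropy: np.ndarray
    features: np.ndarray

    def matrix(self, metric: str) -> np.ndarray:
        return {"degree": self.d_degree, "strength": self.d_strength,
                "entropy": self.d_entropy}[metric]


def mirror_permutation(array: AntennaArray) -> np.ndarray:
    """Permutation matrix P of the sagittal mirror pairing."""
    perm = array.mirror
    p = np.zeros((array.na, array.na))
    p[np.arange(array.na), perm] = 1.0
    return p


def _differential(m: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """D = M - P M P^T, computed pairwise-complete under NaN masking."""
    mm = m[np.ix_(perm, perm)]
    return m - mm


def _matrix_features(d: np.ndarray, left: np.ndarray,
                     right: np.ndarray) -> np.ndarray:
    """13 summary features of one differential matrix.

    Unsigned magnitude summaries (Frobenius norm, max, mean of
    |entries|) quantify how asymmetric the scan is; the two *signed*
    statistics carry the contrast polarity.  Because the mirror
    involution maps D to -D entry-for-entry, any permutation-invariant
    unsigned feature is blind to the sign of the dielectric contrast —
    but the signed mean over the dominant hemisphere's channels (the
    side with the larger aggregate |D|) is side-invariant and keeps the
    sign.  The remaining 8 features are the left-hemisphere row-wise
    asymmetry norms.
    """
    df = np.where(np.isfinite(d), d, 0.0)
    a = np.abs(df)
    n_fin = max(np.isfinite(d).sum(), 1)
    feats = [np.sqrt(np.sum(a ** 2)), np.max(a), np.sum(a) / n_fin]
    halves = {}
    for name, idx in (("left", left), ("right", right)):
        sub = df[np.ix_(idx, idx)]
        halves[name] = sub
    dom = max(halves, key=lambda h: np.sum(np.abs(halves[h])))
    sub = halves[dom]
    feats.append(np.mean(sub))
    flat = sub.ravel()
    top = flat[np.argsort(np.abs(flat))[-8:]]
    feats.append(np.mean(top))
    for k in np.sort(left):
        feats.append(np.sqrt(np.sum(a[k] ** 2)))
    return np.asarray(feats)


def differential_matrices(metric_matrices: dict[str, np.ndarray],
                          array: AntennaArray) -> DifferentialFeatureSet:
    """Differential matrices D = M - P M P^T and their feature vector."""
    perm = array.mirror
    left = np.sort(array.left_indices)
    right = np.sort(array.right_indices)
    ds = {}
    feats = []
    for metric in METRICS:
        d = _differential(metric_matrices[metric], perm)
        ds[metric] = d
        feats.append(_matrix_features(d, left, right))
    return DifferentialFeatureSet(ds["degree"], ds["strength"],
                                  ds["entropy"], np.concatenate(feats))


def crossing_channels(array: AntennaArray, peak: tuple[float, float],
                      half_width: float = 0.010) -> list[tuple[int, int]]:
    """Unordered antenna pairs whose transmit-receive segment passes
    within ``half_width`` of the given point."""
    pk = np.asarray(peak, dtype=float)
    pos = array.positions
    na = array.na
    crossing = []
    for i in range(na):
        for j in range(i + 1, na):
            seg = pos[j] - pos[i]
            t = np.clip(((pk - pos[i]) @ seg) / (seg @ seg), 0.0, 1.0)
            if np.linalg.norm(pk - (pos[i] + t * seg)) <= half_width:
                crossing.append((i, j))
    return crossing


def crossing_mean(m: np.ndarray, crossing: list[tuple[int, int]]) -> float:
    """Mean of a channel matrix over the given unordered pairs
    (symmetrized, NaN-masked entries skipped)."""
    vals = [0.5 * (m[i, j] + m[j, i]) for i, j in crossing
            if np.isfinite(m[i, j]) and np.isfinite(m[j, i])]
    return float(np.mean(vals)) if vals else 0.0


def crossing_line_features(diff: DifferentialFeatureSet,
                           array: AntennaArray,
                           peak: tuple[float, float],
                           half_width: float = 0.010) -> np.ndarray:
    """Signed mean differential over stroke-crossing channels.

    For each metric, averages the signed D entries of all channels
    whose transmit-receive segment passes within ``half_width`` of the
    estimated stroke location.  On this forward model the sign of the
    crossing-line differential entropy separates hemorrhage (negative)
    from ischemia (positive), which the global unsigned summaries
    cannot: the mirror involution maps D to -D, so every location-blind
    permutation-invariant feature is sign-symmetric.
    """
    crossing = crossing_channels(array, peak, half_width)
    return np.asarray([crossing_mean(diff.matrix(metric), crossing)
                       for metric in METRICS])


def extract_features(ds, array: AntennaArray, *, window: str = "hamming",
                     pad_factor: int = 4) -> DifferentialFeatureSet:
    """Calibrated dataset -> time domain -> HVG metrics -> differentials."""
    tds = to_time_domain(ds, window=window, pad_factor=pad_factor)
    mats = channel_metric_matrices(tds, array, ds.channel_mask)
    return differential_matrices(mats, array)


# --------------------------------------------------------------------------
# classifier ensemble
# --------------------------------------------------------------------------


@dataclass
class EnsembleBundle:
    scaler: StandardScaler
    classifiers: dict
    classes: tuple[str, ...]
    n_features: int
    seed: int
    # per-classifier feature-index subsets (distance/density-based
    # classifiers use the top features ranked by forest importance)
    feature_subsets: dict | None = None

    def subset(self, name: str) -> np.ndarray | None:
        if not self.feature_subsets:
            return None
        return self.feature_subsets.get(name)


@dataclass
class ClassifierEnsembleResult:
    per_classifier: dict[str, np.ndarray]
    fused: np.ndarray
    label: str
    certainty: float
    classes: tuple[str, ...] = CLASS_ORDER


def train_ensemble(features: np.ndarray, labels, seed: int = 0,
                   select_k: int = 8) -> EnsembleBundle:
    """Fit the four probability classifiers on a labeled feature table.

    The random forest sees every feature; the distance- and
    density-based classifiers (kNN, naive Bayes, SVM) are fit on the
    ``select_k`` most forest-important features, which keeps them from
    drowning in the uninformative dimensions of the summary vector.
    Training is fully seeded.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if x.ndim != 2:
        raise DimensionError("features must be (n_samples, n_features)")
    present = [c for c in CLASS_ORDER if c in set(y)]
    if len(set(y)) < 2:
        raise ValueError("training set contains a single class")
    scaler = StandardScaler().fit(x)
    xs = scaler.transform(x)
    rf = RandomForestClassifier(n_estimators=300, max_features=0.3,
                                random_state=seed)
    rf.fit(xs, y)
    k = min(select_k, x.shape[1])
    sel = np.sort(np.argsort(rf.feature_importances_)[::-1][:k])
    clfs = {"random_forest": rf,
            "knn": KNeighborsClassifier(n_neighbors=5),
            "naive_bayes": GaussianNB(),
            "svm": SVC(kernel="rbf", C=10.0, gamma="scale",
                       probability=True, random_state=seed)}
    subsets = {"knn": sel, "naive_bayes": sel, "svm": sel}
    for name, clf in clfs.items():
        if name == "random_forest":
            continue
        clf.fit(xs[:, subsets[name]], y)
    return EnsembleBundle(scaler, clfs, tuple(present), x.shape[1], seed,
                          subsets)


def _aligned_proba(clf, xs: np.ndarray, classes: tuple[str, ...]
                   ) -> np.ndarray:
    p = clf.predict_proba(xs)[0]
    out = np.zeros(len(classes))
    for c, pi in zip(clf.classes_, p):
        out[classes.index(c)] = pi
    return out


def classify_ensemble(features: np.ndarray, bundle: EnsembleBundle
                      ) -> ClassifierEnsembleResult:
    """Certainty-weighted fusion of the four classifiers' probabilities.

    Each classifier contributes its probability vector weighted by its
    own confidence (max probability); the weighted mean is renormalized.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != bundle.n_features:
        raise DimensionError(
            f"feature dimension {x.shape[1]} != trained {bundle.n_features}")
    xs = bundle.scaler.transform(x)
    per = {}
    for name, clf in sorted(bundle.classifiers.items()):
        sub = bundle.subset(name)
        per[name] = _aligned_proba(clf, xs if sub is None else xs[:, sub],
                                   bundle.classes)
    probs = np.stack(list(per.values()))
    w = probs.max(axis=1)
    fused = (w[:, None] * probs).sum(axis=0)
    fused = fused / fused.sum()
    idx = int(np.argmax(fused))
    return ClassifierEnsembleResult(per, fused, bundle.classes[idx],
                                    float(fused[idx]),
                                    classes=bundle.classes)


# --------------------------------------------------------------------------
# line-crossing localization map
# --------------------------------------------------------------------------


@dataclass
class LineCrossingImage:
    image: IntensityImage
    channel_weights: np.ndarray


def linecross_map(d_entropy: np.ndarray, array: AntennaArray,
                  boundary: Ellipse | None, grid: ImageGrid | None = None,
                  half_width: float = 0.006,
                  polarity: str = "abs") -> LineCrossingImage:
    """Paint each antenna-pair ray corridor with its differential entropy.

    Every pixel within ``half_width`` of the segment between antennas i
    and j accumulates the corridor weight w_ij = max(0, D_entropy[i, j])
    under the chosen ``polarity``; the accumulated map is divided by
    the per-pixel ray-coverage count, restricted to the head boundary,
    and normalized to max 1.

    ``polarity`` resolves the sign of the differential: on this forward
    model an ischemic inclusion *raises* the entropy of crossing lines
    relative to their mirrors ('pos'), a hemorrhage *lowers* it
    ('neg'), so the caller can pass the classifier's call; 'abs' keeps
    the unsigned magnitude (no lateralization — the unsigned
    differential is exactly mirror-symmetric).
    """
    grid = grid or ImageGrid.default()
    if boundary is None:
        warnings.warn("no boundary estimate: using default head ellipse",
                      stacklevel=2)
        boundary = Ellipse(0.0, 0.0, 0.080, 0.100)
    na = array.na
    d = np.where(np.isfinite(d_entropy), d_entropy, 0.0)
    if polarity == "abs":
        w = np.abs(d)
    elif polarity == "pos":
        w = np.maximum(0.0, d)
    elif polarity == "neg":
        w = np.maximum(0.0, -d)
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    xx, yy = grid.mesh()
    acc = np.zeros(grid.shape)
    cov = np.zeros(grid.shape)
    used = np.zeros((na, na))
    for i in range(na):
        for j in range(i + 1, na):
            p0 = array.positions[i]
            p1 = array.positions[j]
            seg = p1 - p0
            ll = seg @ seg
            t = ((xx - p0[0]) * seg[0] + (yy - p0[1]) * seg[1]) / ll
            t = np.clip(t, 0.0, 1.0)
            dx = xx - (p0[0] + t * seg[0])
            dy = yy - (p0[1] + t * seg[1])
            corridor = dx * dx + dy * dy <= half_width ** 2
            wij = 0.5 * (w[i, j] + w[j, i])
            acc[corridor] += wij
            cov[corridor] += 1.0
            used[i, j] = used[j, i] = wij
    inside = boundary.contains(xx, yy)
    vals = np.zeros(grid.shape)
    nzc = cov > 0
    vals[nzc] = acc[nzc] / cov[nzc]
    vals[~inside] = 0.0
    img = IntensityImage(grid, vals, "linecross").normalized()
    return LineCrossingImage(img, used)
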