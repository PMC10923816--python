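"""Image fusion and classifier-decision fusion.

The four modality images are resampled onto a common grid, min-max
normalized, thresholded, and combined into an agreement region (pixels
where at least K modalities exceed the threshold, with K relaxed until
the region is non-empty).  Smoothed modalities restricted to the
dilated agreement mask form the fused heatmap; the heatmap peak gives
the quadrant call.  Decision fusion combines the classifier ensemble's
probability vector with the DMM detect/type call into one final class,
rendered red for hemorrhage and blue for ischemia.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import binary_dilation, gaussian_filter

from .core import (DimensionError, ImageGrid, IntensityImage, QuadrantCall,
                   quadrant_of_point)
from .linecross import CLASS_ORDER, ClassifierEnsembleResult

# pseudo-probability the DMM decision contributes to decision fusion
DMM_VOTE_HIT = 0.8
DMM_VOTE_MISS = 0.1


@dataclass
class FusionOutput:
    agreement_mask: np.ndarray
    heatmap: IntensityImage
    fused_class: str
    fused_probs: np.ndarray
    certainty: float
    quadrant: QuadrantCall
    k_used: int
    k_fallback: bool
    degenerate_images: list[int]


def coregister_normalize(images: list[IntensityImage],
                         grid: ImageGrid | None = None
                         ) -> tuple[list[IntensityImage], list[int]]:
    """Resample every modality onto the common grid (bilinear) and
    min-max normalize to [0, 1].

    Images already on the target grid pass through untouched.  A
    constant image has no usable range: it becomes all-zeros and its
    index is reported as degenerate.
    """
    if not images:
        raise DimensionError("no images to fuse")
    grid = grid or images[0].grid
    out = []
    degenerate = []
    for idx, im in enumerate(images):
        if (np.array_equal(im.grid.x, grid.x)
                and np.array_equal(im.grid.y, grid.y)):
            v = im.values.copy()
        else:
            interp = RegularGridInterpolator(
                (im.grid.y, im.grid.x), im.values, method="linear",
                bounds_error=False, fill_value=0.0)
            xx, yy = grid.mesh()
            v = interp(np.stack([yy.ravel(), xx.ravel()], axis=1)
                       ).reshape(grid.shape)
        lo, hi = v.min(), v.max()
        if hi - lo <= 0:
            v = np.zeros(grid.shape)
            degenerate.append(idx)
        else:
            v = (v - lo) / (hi - lo)
        out.append(IntensityImage(grid, v, im.modality))
    return out, degenerate


def agreement_region(images: list[IntensityImage], threshold: float = 0.5,
                     min_agree: int = 3) -> tuple[np.ndarray, int, bool]:
    """Pixels where at least K modalities exceed the threshold.

    K starts at ``min_agree`` and is decremented until the mask is
    non-empty (or K = 1); returns (mask, K used, fallback flag).
    """
    votes = sum((im.values > threshold).astype(int) for im in images)
    k = min(min_agree, len(images))
    fallback = False
    while k > 1 and not np.any(votes >= k):
        k -= 1
        fallback = True
    return votes >= k, k, fallback


def smooth_dilate_overlay(images: list[IntensityImage], mask: np.ndarray,
                          sigma_px: float = 2.0, dilate_px: int = 2,
                          weights=None
                          ) -> tuple[IntensityImage, np.ndarray]:
    """Weighted mean of Gaussian-smoothed modalities inside the dilated
    mask (uniform weights by default)."""
    if not images:
        raise DimensionError("no images to fuse")
    grid = images[0].grid
    if dilate_px > 0:
        yy, xx = np.ogrid[-dilate_px:dilate_px + 1, -dilate_px:dilate_px + 1]
        disk = xx ** 2 + yy ** 2 <= dilate_px ** 2
        dmask = binary_dilation(mask, structure=disk)
    else:
        dmask = mask.copy()
    if weights is None:
        weights = np.ones(len(images))
    weights = np.asarray(weights, dtype=float)
    sm = sum(w * gaussian_filter(im.values, sigma_px)
             for w, im in zip(weights, images)) / weights.sum()
    vals = np.where(dmask, sm, 0.0)
    return IntensityImage(grid, vals, "fused").normalized(), dmask


def fuse_decisions(ensemble: ClassifierEnsembleResult, dmm_type: str,
                   dmm_detect: bool) -> tuple[str, np.ndarray, float]:
    """Certainty-weighted fusion of the ensemble and the DMM decision.

    The DMM call is mapped to a pseudo-probability vector (detected
    type 0.8, others 0.1; not detected: healthy 0.8); the fused vector
    is the certainty-weighted mean with the ensemble probabilities.
    """
    classes = ensemble.classes
    dmm_vec = np.full(len(classes), DMM_VOTE_MISS)
    target = dmm_type if (dmm_detect and dmm_type in classes) else "healthy"
    if target in classes:
        dmm_vec[classes.index(target)] = DMM_VOTE_HIT
    dmm_vec = dmm_vec / dmm_vec.sum()
    w_ens = ensemble.certainty
    w_dmm = float(dmm_vec.max())
    fused = w_ens * ensemble.fused + w_dmm * dmm_vec
    fused = fused / fused.sum()
    idx = int(np.argmax(fused))
    return classes[idx], fused, float(fused[idx])


def fuse_images(images: list[IntensityImage],
                grid: ImageGrid | None = None, threshold: float = 0.5,
                min_agree: int = 3, sigma_px: float = 2.0,
                dilate_px: int = 2,
                weights=None) -> tuple[IntensityImage, np.ndarray,
                                       int, bool, list[int]]:
    """Co-register, normalize, smooth, agree: the full image-fusion chain.

    Agreement is computed on the smoothed (re-normalized) modalities so
    that a sharply peaked modality still overlaps its broad companions;
    the heatmap is the weighted mean of the smoothed modalities inside
    the dilated agreement mask.
    """
    normed, degenerate = coregister_normalize(images, grid)
    smoothed, _ = coregister_normalize(
        [IntensityImage(im.grid, gaussian_filter(im.values, sigma_px),
                        im.modality) for im in normed], grid)
    mask, k_used, fallback = agreement_region(
        [im for i, im in enumerate(smoothed) if i not in degenerate]
        or smoothed, threshold, min_agree)
    heat, dmask = smooth_dilate_overlay(normed, mask, sigma_px, dilate_px,
                                        weights)
    return heat, dmask, k_used, fallback, degenerate


CLASS_COLORS = {"ICH": (0.85, 0.10, 0.10), "IS": (0.10, 0.25, 0.85),
                "healthy": (0.35, 0.35, 0.35)}


def render_overlay(heatmap: IntensityImage, fused_class: str, path,
                   phantom_eps=None) -> None:
    """PNG render: heatmap colored by class (red=ICH, blue=IS), optionally
    over the known synthetic permittivity map."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = heatmap.grid
    extent = [g.x[0] * 100, g.x[-1] * 100, g.y[0] * 100, g.y[-1] * 100]
    fig, ax = plt.subplots(figsize=(5, 5.5))
    if phantom_eps is not None:
        ax.imshow(phantom_eps, origin="lower", extent=extent,
                  cmap="gray", alpha=0.8)
    color = CLASS_COLORS.get(fused_class, (0.3, 0.3, 0.3))
    rgba = np.zeros(heatmap.values.shape + (4,))
    rgba[..., :3] = color
    rgba[..., 3] = heatmap.values
    ax.imshow(rgba, origin="lower", extent=extent)
    ax.set_xlabel("x (cm, patient left +)")
    ax.set_ylabel("y (cm, anterior +)")
    ax.set_title(f"fused: {fused_class}")
    fig.savefig(path, dpi=110)
    plt.close(fig)


def quadrant_from_image(img: IntensityImage) -> QuadrantCall:
    return quadrant_of_point(img.peak())
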