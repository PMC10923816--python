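"""2-D background Green's function and a per-session evaluation cache.

The scalar Helmholtz Green's function of the homogeneous lossy
background, with the e^{-j omega t} convention, is

    G(r, r') = (j/4) H0^(1)(k_b |r - r'|)

It is the kernel of both the Born forward model and the beamography
back-propagation, so antenna-to-grid evaluations are cached per
(array, grid, sweep, background) combination.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np
from scipy.special import hankel1

from .core import AntennaArray, FrequencySweep, ImageGrid, PropagationModel


def greens(k: complex, src: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """G(obs, src) for one wavenumber; src (M,2), obs (N,2) -> (M, N)."""
    d = np.linalg.norm(obs[None, :, :] - src[:, None, :], axis=2)
    return 0.25j * hankel1(0, k * d)


_CACHE: OrderedDict[tuple, np.ndarray] = OrderedDict()
_CACHE_MAX = 3


def _key(array: AntennaArray, grid: ImageGrid, sweep: FrequencySweep,
         prop: PropagationModel) -> tuple:
    return (array.positions.tobytes(), grid.x.tobytes(), grid.y.tobytes(),
            sweep.frequencies.tobytes(), prop.eps_b, prop.sigma_b)


def antenna_grid_greens(array: AntennaArray, grid: ImageGrid,
                        sweep: FrequencySweep, prop: PropagationModel
                        ) -> np.ndarray:
    """Cached G(r_antenna, r_pixel) tensor of shape (Nf, Na, Npix).

    Pixels coincident with an antenna (possible only for grids that
    extend past the ring) get G = 0 to avoid the log singularity.
    """
    key = _key(array, grid, sweep, prop)
    g = _CACHE.get(key)
    if g is not None:
        _CACHE.move_to_end(key)
        return g
    pts = grid.points()
    d = np.linalg.norm(pts[None, :, :] - array.positions[:, None, :], axis=2)
    singular = d < 1e-12
    d = np.where(singular, 1.0, d)
    ks = prop.wavenumber(sweep.frequencies)
    g = np.empty((sweep.nf, array.na, pts.shape[0]), dtype=complex)
    for m, k in enumerate(ks):
        gm = 0.25j * hankel1(0, k * d)
        gm[singular] = 0.0
        g[m] = gm
    _CACHE[key] = g
    while len(_CACHE) > _CACHE_MAX:
        _CACHE.popitem(last=False)
    return g


def clear_cache() -> None:
    _CACHE.clear()
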