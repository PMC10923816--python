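"""Distance correlation, clutter subtraction, back-propagation imaging."""

import numpy as np
import pytest

from emibrain import beamography as bg
from emibrain.core import Ellipse
from emibrain.synthetic import (forward_scatter, make_phantom,
                                scatterer_only_phantom)


# ---------------------------------------------------- distance correlation


def test_dcor_identity_and_bounds():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(40)
    assert abs(bg.distance_correlation(x, x) - 1.0) < 1e-12
    y = rng.standard_normal(40)
    d = bg.distance_correlation(x, y)
    assert 0.0 <= d <= 1.0


def test_dcor_constant_input_is_nan():
    x = np.ones(20)
    y = np.arange(20.0)
    assert np.isnan(bg.distance_correlation(x, y))


def test_dcor_affine_invariance():
    rng = np.random.default_rng(1)
    x = rng.standard_normal(50)
    y = 3.0 * x - 2.0
    assert abs(bg.distance_correlation(x, y) - 1.0) < 1e-9


def test_dcor_accepts_complex_sequences():
    rng = np.random.default_rng(2)
    z = rng.standard_normal(30) + 1j * rng.standard_normal(30)
    assert abs(bg.distance_correlation(z, z) - 1.0) < 1e-12


# ------------------------------------------------------------ side finding


def test_symmetric_dataset_is_ambiguous(config, healthy_forward):
    """Without an external reference the mirror comparison is symmetric
    and the call defaults to 'left' with the ambiguity flag raised."""
    _, ds = healthy_forward
    side, scores = bg.affected_side(ds, config.array)
    assert side == "left" and scores.ambiguous
    assert abs(scores.left - scores.right) < 0.01


def test_lateral_stroke_side_detected(config, models):
    """Off-axis inclusions decorrelate their own hemisphere's channels
    from the healthy model reference."""
    correct = 0
    cases = 0
    for seed in (5, 16, 23, 31):
        for cls in ("ICH", "IS"):
            ph = make_phantom(seed, cls, grid=config.grid, prop=config.prop)
            if abs(ph.inclusion.center[0]) < 0.015:
                continue  # near-axis: side genuinely ill-defined
            ds = forward_scatter(ph, config.array, config.sweep, config.prop)
            ref_ph = make_phantom(0, "healthy", grid=config.grid,
                                  boundary=ph.boundary, prop=config.prop)
            ref = forward_scatter(ref_ph, config.array, config.sweep,
                                  config.prop)
            side, _ = bg.affected_side(ds, config.array, ref)
            truth = "left" if ph.inclusion.center[0] > 0 else "right"
            correct += side == truth
            cases += 1
    assert cases >= 4
    assert correct == cases


# ------------------------------------------------------------- subtraction


def test_symmetric_dataset_nulls_out(config, healthy_forward):
    _, ds = healthy_forward
    csd = bg.symmetry_subtract(ds, "left")
    scale = np.max(np.abs(ds.s))
    assert np.max(np.abs(csd.delta.s)) < 1e-9 * scale


def test_mirror_antisymmetry_of_delta(config, ich_forward):
    _, ds = ich_forward
    csd = bg.symmetry_subtract(ds, "left")
    perm = config.array.mirror
    mirrored = csd.delta.s[np.ix_(perm, perm)]
    assert np.allclose(mirrored, -csd.delta.s, atol=1e-12)


def test_healthy_side_channels_downweighted(config, ich_forward):
    _, ds = ich_forward
    csd = bg.symmetry_subtract(ds, "left")
    right = config.array.right_indices
    left = config.array.left_indices
    assert np.all(csd.weights[np.ix_(right, right)] == 0.5)
    assert np.all(csd.weights[np.ix_(left, left)] == 1.0)
    assert np.all(csd.weights[np.ix_(left, right)] == 1.0)


def test_average_subtract_properties(config, ich_forward):
    _, ds = ich_forward
    csd = bg.symmetry_subtract(ds, "left")
    out = bg.average_subtract(csd)
    # per-frequency channel mean is zero
    assert np.max(np.abs(out.delta.s.mean(axis=(0, 1)))) < 1e-12 * np.max(
        np.abs(ds.s))
    # idempotent
    twice = bg.average_subtract(out)
    assert np.allclose(twice.delta.s, out.delta.s, atol=1e-15)
    # constant-across-channels input nulls out
    const = ds.copy_with(s=np.broadcast_to(
        ds.s[0, 0][None, None, :], ds.s.shape).copy())
    nulled = bg.average_subtract(bg.ClutterSuppressedData(
        const, np.ones((16, 16)), "left"))
    assert np.max(np.abs(nulled.delta.s)) < 1e-15


def test_symmetry_subtract_recovers_scattered_signal(config):
    """Symmetric clutter cancels exactly: the mirror-differenced data of
    an off-axis target equals the scattered-only signal minus its own
    mirror image (clutter contributes nothing), and its magnitude is
    bounded by twice the scattered-only magnitude."""
    from emibrain.synthetic import HeadPhantom, StrokeInclusion

    full = make_phantom(0, "healthy", grid=config.grid, prop=config.prop)
    center, radius = (0.045, 0.03), 0.006
    xx, yy = config.grid.mesh()
    disk = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius ** 2
    eps = full.eps_r.copy()
    sig = full.sigma.copy()
    eps[disk] += 18.0
    sig[disk] += 0.8
    inc = StrokeInclusion("ICH", center, radius, 18.0, 0.8)
    diseased = HeadPhantom(config.grid, eps, sig, full.boundary, inc)
    ds = forward_scatter(diseased, config.array, config.sweep, config.prop)
    s_scat = ds.s - forward_scatter(full, config.array, config.sweep,
                                    config.prop).s
    csd = bg.symmetry_subtract(ds, "left")
    perm = config.array.mirror
    expected = s_scat - s_scat[np.ix_(perm, perm)]
    scale = np.max(np.abs(s_scat))
    assert np.max(np.abs(csd.delta.s - expected)) < 1e-12 * scale
    assert np.max(np.abs(csd.delta.s)) <= 2.0 * scale + 1e-12 * scale
    assert np.max(np.abs(csd.delta.s)) >= 0.5 * scale


# ---------------------------------------------------------- backprojection


def _point_delta(config, r0, delta=(18.0, 0.8), radius=0.004):
    ph = scatterer_only_phantom(r0, radius, delta, grid=config.grid,
                                prop=config.prop)
    ds = forward_scatter(ph, config.array, config.sweep, config.prop)
    bg_only = make_phantom(0, "healthy", grid=config.grid,
                           interior=(config.prop.eps_b,
                                     config.prop.sigma_b),
                           prop=config.prop)
    s0 = forward_scatter(bg_only, config.array, config.sweep,
                         config.prop).s
    return ds.copy_with(s=ds.s - s0)


def test_point_scatterer_recovered_within_one_pixel(config):
    truth = (0.03, 0.04)
    delta = _point_delta(config, truth)
    csd = bg.ClutterSuppressedData(delta, np.ones((16, 16)), "left")
    img = bg.backpropagate(csd, config.array, config.sweep, config.prop,
                           config.grid, Ellipse(0, 0, 0.08, 0.10))
    px, py = img.peak()
    assert np.hypot(px - truth[0], py - truth[1]) <= config.grid.pixel


def test_zero_delta_zero_image(config, healthy_forward):
    _, ds = healthy_forward
    zero = ds.copy_with(s=np.zeros_like(ds.s))
    csd = bg.ClutterSuppressedData(zero, np.ones((16, 16)), "left")
    img = bg.backpropagate(csd, config.array, config.sweep, config.prop,
                           config.grid)
    assert np.all(img.values == 0)


def test_two_scatterers_resolved(config):
    d1 = _point_delta(config, (0.04, 0.04))
    d2 = _point_delta(config, (-0.03, -0.05))
    both = d1.copy_with(s=d1.s + d2.s)
    csd = bg.ClutterSuppressedData(both, np.ones((16, 16)), "left")
    img = bg.backpropagate(csd, config.array, config.sweep, config.prop,
                           config.grid, Ellipse(0, 0, 0.08, 0.10))
    v = img.values
    for truth in ((0.04, 0.04), (-0.03, -0.05)):
        ix = int(np.argmin(np.abs(config.grid.x - truth[0])))
        iy = int(np.argmin(np.abs(config.grid.y - truth[1])))
        win = v[iy - 2:iy + 3, ix - 2:ix + 3]
        # local maximum within 2 pixels of each target
        assert win.max() > 0.5
        wy, wx = np.unravel_index(np.argmax(win), win.shape)
        assert abs(wy - 2) <= 2 and abs(wx - 2) <= 2


def test_global_phase_shift_leaves_image_unchanged(config):
    delta = _point_delta(config, (0.02, -0.03))
    csd1 = bg.ClutterSuppressedData(delta, np.ones((16, 16)), "left")
    shifted = delta.copy_with(s=delta.s * np.exp(1j * 0.7))
    csd2 = bg.ClutterSuppressedData(shifted, np.ones((16, 16)), "left")
    kw = dict(grid=config.grid)
    i1 = bg.backpropagate(csd1, config.array, config.sweep, config.prop,
                          **kw)
    i2 = bg.backpropagate(csd2, config.array, config.sweep, config.prop,
                          **kw)
    assert np.allclose(i1.values, i2.values, atol=1e-9)


def test_symmetric_phantom_image_is_faint(config, healthy_forward,
                                          ich_forward):
    """Null property: the symmetric phantom's unnormalized image is at
    most 5% of a matched diseased phantom's."""
    _, healthy_ds = healthy_forward
    ich_ph, ich_ds = ich_forward

    def unnormalized_max(ds, boundary):
        side, sc = bg.affected_side(ds, config.array)
        csd = bg.average_subtract(bg.symmetry_subtract(ds, side, sc))
        from emibrain.greens import antenna_grid_greens
        g = antenna_grid_greens(config.array, config.grid, config.sweep,
                                config.prop)
        acc = np.zeros(g.shape[2], dtype=complex)
        for m in range(config.sweep.nf):
            gm = g[m] / np.abs(g[m])
            gc = np.conj(gm)
            acc += np.einsum("ip,ip->p", gc,
                             (csd.weights * csd.delta.s[:, :, m]) @ gc)
        return np.abs(acc).max()

    assert (unnormalized_max(healthy_ds, None)
            <= 0.05 * unnormalized_max(ich_ds, None))
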