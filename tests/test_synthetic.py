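"""Forward-model identities, phantom generation, noise and cohorts."""

import numpy as np
import pytest

from emibrain.core import (Ellipse, FrequencySweep, GeometryError,
                           ImageGrid, quadrant_of_point)
from emibrain.greens import greens
from emibrain.synthetic import (NoiseModel, add_noise, calibration_phantom,
                                forward_scatter, generate_cohort,
                                make_phantom, scatterer_only_phantom)


# ---------------------------------------------------------------- phantoms


def test_healthy_phantom_has_no_inclusion(grid, prop):
    ph = make_phantom(1, "healthy", grid=grid, prop=prop)
    assert ph.inclusion is None
    assert ph.stroke_class == "healthy"


def test_phantom_deterministic(grid, prop):
    a = make_phantom(1, "ICH", grid=grid, prop=prop)
    b = make_phantom(1, "ICH", grid=grid, prop=prop)
    assert a.inclusion == b.inclusion
    assert np.array_equal(a.eps_r, b.eps_r)


def test_contrast_signs(grid, prop):
    ich = make_phantom(2, "ICH", grid=grid, prop=prop).inclusion
    iss = make_phantom(2, "IS", grid=grid, prop=prop).inclusion
    assert ich.delta_eps > 0 and ich.delta_sigma > 0
    assert iss.delta_eps < 0 and iss.delta_sigma < 0


def test_inclusion_center_distribution_uniform_over_quadrants(grid, prop):
    """Monte-Carlo check: centers drawn uniformly inside 80% of the
    boundary land in each quadrant with frequency 25 +/- 5 %."""
    counts = {q: 0 for q in ("anterior-left", "anterior-right",
                             "posterior-left", "posterior-right")}
    n = 1000
    for seed in range(n):
        ph = make_phantom(seed, "ICH", grid=grid, prop=prop)
        counts[quadrant_of_point(ph.inclusion.center).quadrant] += 1
    for q, c in counts.items():
        assert 0.20 <= c / n <= 0.30, (q, c / n)


def test_inclusion_always_inside_boundary(grid, prop):
    for seed in range(50):
        ph = make_phantom(seed, "IS", grid=grid, prop=prop)
        inc = ph.inclusion
        b = ph.boundary
        # the whole disk must fit inside the ellipse
        th = np.linspace(0, 2 * np.pi, 36)
        rim_x = inc.center[0] + inc.radius * np.cos(th)
        rim_y = inc.center[1] + inc.radius * np.sin(th)
        assert np.all(b.contains(rim_x, rim_y))


# ------------------------------------------------------------ forward model


def test_zero_contrast_gives_zero_scattering(array, sweep, grid, prop):
    """A phantom identical to the background scatters nothing: only the
    direct antenna-to-antenna coupling remains."""
    ph = make_phantom(0, "healthy", grid=grid,
                      interior=(prop.eps_b, prop.sigma_b), prop=prop)
    ds = forward_scatter(ph, array, sweep, prop)
    d = np.linalg.norm(array.positions[None] - array.positions[:, None],
                       axis=2)
    np.fill_diagonal(d, 1.0)
    for m in (0, sweep.nf - 1):
        from scipy.special import hankel1
        direct = 0.25j * hankel1(0, prop.wavenumber(sweep.frequencies[m])
                                 * d)
        np.fill_diagonal(direct, 0.0)
        assert np.max(np.abs(ds.s[:, :, m] - direct)) < 1e-12


def test_reciprocity_exact(ich_forward):
    _, ds = ich_forward
    assert np.max(np.abs(ds.s - ds.s.transpose(1, 0, 2))) == 0.0


def test_single_scatterer_channel_ratio(array, sweep, grid, prop):
    """Closed-form oracle: for one scattering pixel at r0, the ratio
    S_ij / S_kl equals G_i(r0) G_j(r0) / (G_k(r0) G_l(r0))."""
    r0 = (0.030, -0.022)  # on a pixel center; radius below the pitch
    ph = scatterer_only_phantom(r0, 0.0012, (18.0, 0.8), grid=grid,
                                prop=prop)
    npix = int(np.sum(ph.eps_r != prop.eps_b))
    assert npix == 1  # radius below the pixel pitch marks one pixel
    iy, ix = np.unravel_index(int(np.argmax(ph.eps_r)), ph.eps_r.shape)
    r_pix = np.array([[grid.x[ix], grid.y[iy]]])
    ds = forward_scatter(ph, array, sweep, prop)
    ph0 = make_phantom(0, "healthy", grid=grid,
                       interior=(prop.eps_b, prop.sigma_b), prop=prop)
    scat = ds.s - forward_scatter(ph0, array, sweep, prop).s
    for m in (0, sweep.nf // 2, sweep.nf - 1):
        g = greens(prop.wavenumber(sweep.frequencies[m]),
                   array.positions, r_pix)[:, 0]
        for (i, j, k, l) in [(0, 5, 3, 11), (2, 9, 7, 14)]:
            lhs = scat[i, j, m] / scat[k, l, m]
            rhs = (g[i] * g[j]) / (g[k] * g[l])
            assert abs(lhs - rhs) < 1e-9 * abs(rhs)


def test_born_linearity_in_contrast(array, sweep, grid, prop):
    """Doubling the contrast of a small inclusion doubles its scattered
    contribution (the Born model is linear by construction)."""
    r0 = (0.02, 0.03)
    ph1 = scatterer_only_phantom(r0, 0.006, (6.0, 0.2), grid=grid,
                                 prop=prop)
    ph2 = scatterer_only_phantom(r0, 0.006, (12.0, 0.4), grid=grid,
                                 prop=prop)
    ph0 = make_phantom(0, "healthy", grid=grid,
                       interior=(prop.eps_b, prop.sigma_b), prop=prop)
    s0 = forward_scatter(ph0, array, sweep, prop).s
    s1 = forward_scatter(ph1, array, sweep, prop).s - s0
    s2 = forward_scatter(ph2, array, sweep, prop).s - s0
    # complex permittivity contrast is not exactly proportional to the
    # (eps, sigma) pair scaling, so compare against the chi ratio
    w = 2 * np.pi * 1e9 * 8.8541878128e-12
    # ratio check at one frequency via direct chi computation
    f = sweep.frequencies[sweep.nf // 2]
    w = 2 * np.pi * f * 8.8541878128e-12
    eb = prop.eps_b + 1j * prop.sigma_b / w
    chi1 = ((prop.eps_b + 6.0 + 1j * (prop.sigma_b + 0.2) / w) - eb) / eb
    chi2 = ((prop.eps_b + 12.0 + 1j * (prop.sigma_b + 0.4) / w) - eb) / eb
    m = sweep.nf // 2
    ratio = s2[0, 8, m] / s1[0, 8, m]
    assert abs(ratio - chi2 / chi1) < 1e-9 * abs(chi2 / chi1)


def test_scattering_monotone_in_radius(array, sweep, grid, prop):
    """Aggregate scattered magnitude grows with inclusion radius."""
    ph0 = make_phantom(0, "healthy", grid=grid,
                       interior=(prop.eps_b, prop.sigma_b), prop=prop)
    s0 = forward_scatter(ph0, array, sweep, prop).s
    norms = []
    for r in (0.005, 0.010, 0.015, 0.020, 0.025):
        ph = scatterer_only_phantom((0.02, 0.01), r, (18.0, 0.8),
                                    grid=grid, prop=prop)
        s = forward_scatter(ph, array, sweep, prop).s - s0
        norms.append(np.linalg.norm(s))
    assert all(a < b for a, b in zip(norms, norms[1:]))


def test_forward_rejects_coarse_grid(array, prop):
    coarse = ImageGrid.default(pixel=0.004)
    ph = make_phantom(0, "healthy", grid=coarse, prop=prop)
    with pytest.raises(GeometryError):
        forward_scatter(ph, array, FrequencySweep.default(n=11), prop)


def test_forward_rejects_antenna_inside_boundary(array, sweep, grid, prop):
    ph = make_phantom(0, "healthy", grid=grid, prop=prop,
                      boundary=Ellipse(0.0, 0.0, 0.118, 0.135))
    with pytest.raises(GeometryError):
        forward_scatter(ph, array, sweep, prop)


# ------------------------------------------------------------------- noise


def test_noise_identity_when_ideal(healthy_forward):
    _, ds = healthy_forward
    out = add_noise(ds, NoiseModel.ideal(ds.na), seed=0)
    assert np.array_equal(out.s, ds.s)


def test_noise_deterministic(healthy_forward):
    _, ds = healthy_forward
    rng = np.random.default_rng(0)
    noise = NoiseModel.draw(rng, ds.na, snr_db=30)
    a = add_noise(ds, noise, seed=42)
    b = add_noise(ds, noise, seed=42)
    assert np.array_equal(a.s, b.s)


def test_realized_snr_matches_request(healthy_forward):
    """Empirical SNR over 100 seeds within 0.5 dB of the request."""
    _, ds = healthy_forward
    noise = NoiseModel.ideal(ds.na)
    noise.snr_db = 30.0
    sig = np.mean(np.abs(ds.s) ** 2)
    noise_powers = []
    for seed in range(100):
        out = add_noise(ds, noise, seed=seed)
        noise_powers.append(np.mean(np.abs(out.s - ds.s) ** 2))
    realized = 10 * np.log10(sig / np.mean(noise_powers))
    # per-channel SNR definition: aggregate is close but not identical
    assert abs(realized - 30.0) < 0.5


def test_zero_gain_rejected():
    with pytest.raises(ValueError):
        NoiseModel(30.0, np.zeros(16, dtype=complex),
                   np.zeros((16, 16), dtype=complex))


# ------------------------------------------------------------------ cohort


def test_cohort_counting_and_manifest(config, tmp_path):
    cohort, manifest = generate_cohort(
        4, {"healthy": 0.5, "ICH": 0.25, "IS": 0.25}, seed=7,
        sweep=config.sweep, grid=config.grid, array=config.array,
        prop=config.prop, scans_per_patient=20,
        manifest_path=tmp_path / "manifest.csv")
    assert len(manifest) == 4
    assert sum(len(p.scans) for p in cohort) == 80
    assert sorted(manifest["class"].value_counts().to_dict().items()) == [
        ("ICH", 1), ("IS", 1), ("healthy", 2)]
    assert (tmp_path / "manifest.csv").exists()


def test_cohort_manifest_quadrants_consistent(default_cohort):
    cohort, manifest = default_cohort
    for p, (_, row) in zip(cohort, manifest.iterrows()):
        if p.stroke_class == "healthy":
            assert row["quadrant"] == ""
        else:
            assert (quadrant_of_point(p.phantom.inclusion.center).quadrant
                    == row["quadrant"])


def test_cohort_regeneration_bit_identical(config):
    kw = dict(sweep=config.sweep, grid=config.grid, array=config.array,
              prop=config.prop, scans_per_patient=3)
    a, ma = generate_cohort(2, {"ICH": 1.0}, seed=9, **kw)
    b, mb = generate_cohort(2, {"ICH": 1.0}, seed=9, **kw)
    assert ma.equals(mb)
    for pa, pb in zip(a, b):
        for sa, sb in zip(pa.scans, pb.scans):
            assert np.array_equal(sa.s, sb.s)


def test_cohort_rejects_bad_mix(config):
    with pytest.raises(ValueError):
        generate_cohort(2, {"ICH": 0.7}, seed=0, sweep=config.sweep,
                        grid=config.grid, array=config.array,
                        prop=config.prop)


def test_calibration_phantoms_bracket_head_average(grid, prop):
    low = calibration_phantom("low", grid=grid, prop=prop)
    high = calibration_phantom("high", grid=grid, prop=prop)
    from emibrain.synthetic import BRAIN_EPS_R
    inside = low.boundary.contains(0.0, 0.0)
    assert inside
    assert low.eps_r[70, 60] < BRAIN_EPS_R < high.eps_r[70, 60]
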