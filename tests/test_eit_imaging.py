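"""CEM forward model, sensitivity, and one-step difference reconstruction."""

import numpy as np
import pytest

from scan2fem.eit_imaging import (
    CemSystem,
    EitFrameSet,
    EitProtocol,
    ReconConfig,
    detect_breaths,
    filter_channels,
    forward_solve,
    global_signal,
    jacobian,
    reconstruct,
    tidal_image,
)
from scan2fem.errors import ConfigError, NoBreathsError, SolverError, TooFewChannelsError
from scan2fem.synthetic_phantom import lung_element_masks, make_eit_sequence


def test_protocol_measurements_deterministic(protocol):
    meas = protocol.measurements()
    assert np.array_equal(meas, protocol.measurements())
    pairs = protocol.injection_pairs()
    assert np.array_equal(pairs[0], [0, 5])  # skip-4: 5 positions apart
    # measurement pairs never touch the injecting electrodes
    for d, a, b in meas:
        assert len({a, b} & set(pairs[d])) == 0


def test_joint_sigma_contact_scaling_exact(electrode_mesh, protocol):
    """Scaling σ and 1/z_c together scales every voltage by the inverse."""
    v1 = forward_solve(electrode_mesh, 1.0, protocol, contact_impedance=1e-3)
    v2 = forward_solve(electrode_mesh, 2.0, protocol, contact_impedance=0.5e-3)
    assert np.abs(2 * v2 - v1).max() / np.abs(v1).max() < 1e-10


def test_sigma_doubling_approximately_halves(electrode_mesh, protocol):
    """With fixed contact impedance the halving holds to a few percent."""
    v1 = forward_solve(electrode_mesh, 1.0, protocol)
    v2 = forward_solve(electrode_mesh, 2.0, protocol)
    assert np.abs(2 * v2 - v1).max() / np.abs(v1).max() < 0.05


def test_reciprocity(electrode_mesh, protocol, homogeneous_system):
    """Swapping injection and measurement pairs gives equal voltages."""
    v = forward_solve(electrode_mesh, 1.0, protocol, system=homogeneous_system)
    meas = protocol.measurements()
    pairs = protocol.injection_pairs()
    pair_of = {tuple(p): d for d, p in enumerate(pairs)}
    vmap = {tuple(m): val for m, val in zip(meas, v)}
    checked = 0
    for (d, a, b), val in vmap.items():
        rec = vmap.get((pair_of[(a, b)], *pairs[d]))
        if rec is not None:
            assert abs(val - rec) <= 1e-8 * abs(val)
            checked += 1
    assert checked > 500


def test_forward_converges_under_refinement():
    """Homogeneous solves converge under 2× mesh refinement (< 2% at the
    finest pair).  Uses a small 8-electrode tube so the electrode discs
    can be resolved (h_electrode down to r/10) at test cost."""
    from scan2fem import ColoredSurface, ElectrodeSet, MeshConfig, fit_surface
    from scan2fem.belt_mesh import build_fem_mesh, remesh_surface

    th = np.linspace(0, 2 * np.pi, 360, endpoint=False)
    zz = np.linspace(-20.0, 20.0, 30)
    tg, zg = np.meshgrid(th, zz, indexing="ij")
    r = 40.0 + 1.5 * np.cos(np.pi * zg / 60.0)
    verts = np.column_stack(
        [(r * np.cos(tg)).ravel(), (r * np.sin(tg)).ravel(), zg.ravel()]
    )
    model = fit_surface(
        ColoredSurface(verts, [[0, 1, 2]], np.full((len(verts), 3), 255, np.uint8))
    )
    the = (np.arange(8) + 0.5) / 8 * 2 * np.pi
    es = ElectrodeSet(
        np.column_stack([42 * np.cos(the), 42 * np.sin(the), np.zeros(8)]),
        np.arange(1, 9), frozenset(), 8,
    )
    proto = EitProtocol(n_electrodes=8, skip=2)
    results = []
    for he, hb in ((2.0, 8.0), (1.0, 4.0), (0.5, 2.0)):
        cfg = MeshConfig(h_electrode=he, h_background=hb, electrode_radius=5.0, seed=0)
        labeled = remesh_surface(model, es, cfg, max_iter=60)
        mesh = build_fem_mesh(labeled, cfg)
        results.append(forward_solve(mesh, 1.0, proto))
    ref = results[-1]
    errs = [np.linalg.norm(v - ref) / np.linalg.norm(ref) for v in results[:-1]]
    assert errs[1] < 0.02
    assert errs[1] < errs[0]


def test_negative_sigma_rejected(electrode_mesh):
    with pytest.raises(SolverError):
        CemSystem(electrode_mesh, -1.0)


def test_jacobian_matches_central_differences(electrode_mesh, protocol, sensitivity):
    J, _ = sensitivity
    rng = np.random.default_rng(0)
    eps = 1e-4
    for e in rng.choice(electrode_mesh.n_elements, 3, replace=False):
        s_p = np.ones(electrode_mesh.n_elements)
        s_p[e] += eps
        s_m = np.ones(electrode_mesh.n_elements)
        s_m[e] -= eps
        fd = (
            forward_solve(electrode_mesh, s_p, protocol)
            - forward_solve(electrode_mesh, s_m, protocol)
        ) / (2 * eps)
        rel = np.linalg.norm(fd - J[:, e]) / np.linalg.norm(fd)
        assert rel < 0.01


def test_jacobian_euler_relation(electrode_mesh, protocol, sensitivity):
    """Σ_e J[m,e]·σ0[e] equals the σ-directional derivative (FD oracle)."""
    J, v0 = sensitivity
    eps = 1e-5
    v_up = forward_solve(electrode_mesh, 1.0 + eps, protocol)
    v_dn = forward_solve(electrode_mesh, 1.0 - eps, protocol)
    fd = (v_up - v_dn) / (2 * eps)
    total = J.sum(axis=1)  # σ0 = 1 per element
    assert np.linalg.norm(total - fd) / np.linalg.norm(fd) < 1e-3


def test_reconstruct_zero_difference_is_zero(sensitivity):
    J, v0 = sensitivity
    img = reconstruct(J, v0, v0.copy())
    assert np.abs(img).max() == 0.0


def test_reconstruct_large_lambda_shrinks_monotonically(sensitivity):
    J, v0 = sensitivity
    rng = np.random.default_rng(2)
    v1 = v0 * (1 + 0.01 * rng.normal(size=len(v0)))
    norms = [
        np.linalg.norm(reconstruct(J, v0, v1, ReconConfig(lam=lam)))
        for lam in (1e-2, 1e0, 1e4, 1e12)
    ]
    assert all(a > b for a, b in zip(norms, norms[1:]))
    assert norms[-1] < 1e-8 * norms[0]


def test_reconstruct_is_linear(sensitivity):
    J, v0 = sensitivity
    rng = np.random.default_rng(3)
    b1 = 0.01 * rng.normal(size=len(v0))
    b2 = 0.01 * rng.normal(size=len(v0))
    cfg = ReconConfig(lam=0.03)
    img12 = reconstruct(J, v0, v0 * (1 + b1 + b2), cfg)
    img1 = reconstruct(J, v0, v0 * (1 + b1), cfg)
    img2 = reconstruct(J, v0, v0 * (1 + b2), cfg)
    assert np.abs(img12 - (img1 + img2)).max() < 1e-10 * np.abs(img12).max() + 1e-12


def test_lambda_validation():
    with pytest.raises(ConfigError):
        ReconConfig(lam=0.0)
    with pytest.raises(ConfigError):
        ReconConfig(lam=-1.0)


def test_inclusion_reconstructed_in_correct_quadrant(electrode_mesh, protocol, sensitivity):
    """A -20% conductivity blob in one quadrant shows up in that quadrant."""
    J, v0 = sensitivity
    cents = electrode_mesh.tet_centroids()
    blob = (
        (np.hypot(cents[:, 0] - 50, cents[:, 1] - 50) < 25)
        & (np.abs(cents[:, 2]) < 30)
    )
    sigma = np.ones(electrode_mesh.n_elements)
    sigma[blob] = 0.8
    v1 = forward_solve(electrode_mesh, sigma, protocol)
    img = reconstruct(J, v0, v1, ReconConfig(lam=0.03))
    # weight by element volume to find the reconstructed minimum region
    quadrant = (cents[:, 0] > 0) & (cents[:, 1] > 0)
    vols = np.abs(electrode_mesh.tet_volumes())
    q_mean = np.average(img[quadrant], weights=vols[quadrant])
    rest_mean = np.average(img[~quadrant], weights=vols[~quadrant])
    assert q_mean < 0
    assert q_mean < rest_mean


def test_tidal_simulation_and_image(electrode_mesh, protocol, sensitivity):
    J, v0 = sensitivity
    frames = make_eit_sequence(
        electrode_mesh, protocol, breath_rate=0.25, depth=0.1,
        duration=30.0, noise_rel=0.005, seed=5,
    )
    peaks, troughs = detect_breaths(frames)
    assert len(peaks) in (7, 8)
    img = tidal_image(frames, J)
    left, right = lung_element_masks(electrode_mesh)
    bg = ~(left | right)
    assert img[left].mean() < 0
    assert img[right].mean() < 0
    assert img[left].mean() < img[bg].mean()
    assert img[right].mean() < img[bg].mean()


def test_constant_frames_raise_no_breaths(protocol):
    frames = EitFrameSet(np.ones((928, 100)), np.arange(100) / 48.0)
    with pytest.raises(NoBreathsError):
        detect_breaths(frames)


def test_filter_channels_masks_noisy_channel(protocol):
    rng = np.random.default_rng(8)
    n_meas, n_frames = 200, 300
    base = np.abs(rng.normal(1e-3, 2e-4, n_meas))[:, None]
    clean = base * (1 + 0.02 * np.sin(np.arange(n_frames) / 10)[None, :])
    frames = EitFrameSet(clean, np.arange(n_frames) / 48.0)
    assert filter_channels(frames).all()
    noisy = clean.copy()
    noisy[17] *= 1 + rng.normal(0, 2.0, n_frames)
    mask = filter_channels(EitFrameSet(noisy, np.arange(n_frames) / 48.0))
    assert not mask[17]
    assert mask.sum() >= n_meas - 2
    all_noisy = clean * (1 + rng.normal(0, 2.0, clean.shape))
    with pytest.raises(TooFewChannelsError):
        filter_channels(EitFrameSet(all_noisy, np.arange(n_frames) / 48.0))


def test_masked_channels_excluded_from_reconstruction(sensitivity):
    J, v0 = sensitivity
    rng = np.random.default_rng(4)
    v1 = v0 * (1 + 0.01 * rng.normal(size=len(v0)))
    v1_corrupt = v1.copy()
    mask = np.ones(len(v0), dtype=bool)
    mask[100:110] = False
    v1_corrupt[100:110] = 1e3  # garbage on masked channels must not matter
    img_a = reconstruct(J, v0, v1, ReconConfig(lam=0.03), channel_mask=mask)
    img_b = reconstruct(J, v0, v1_corrupt, ReconConfig(lam=0.03), channel_mask=mask)
    assert np.abs(img_a - img_b).max() == 0.0
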