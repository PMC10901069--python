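"""Synthetic thorax phantoms: colored scans, tracked points, EIT frames.

Generates every input the pipeline consumes without any acquisition
hardware: an elliptic-cylinder-plus-bumps thorax surface wearing the
32-sticker belt (six anchor colors at electrodes 7, 12, 17, 22, 27, 32),
infrared-tracker-style electrode points and contours, and simulated
tidal-breathing EIT voltage sequences from a two-lung conductivity
oscillation.  Everything is deterministic per seed.

Scanner noise is modeled as a smooth low-order random displacement field
plus a smaller i.i.d. jitter (summing in quadrature to
``vertex_noise_sd``): handheld scans err mainly through slowly varying
registration drift, which is what limits electrode localization, whereas
pure per-vertex noise would average away over each sticker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import interp1d
from scipy.spatial import cKDTree

from .electrode_id import ANCHOR_NUMBERS, ElectrodeSet
from .eit_imaging import EitFrameSet, EitProtocol, forward_solve
from .errors import Scan2FemError
from .scan_io import ColoredSurface

SKIN_RGB = (200, 160, 140)
ANCHOR_COLOR_BY_LABEL = {num: name for name, num in ANCHOR_NUMBERS.items()}


@dataclass
class PhantomSpec:
    """Study-like phantom geometry and noise settings.

    Defaults follow the adult-thorax regime of the validation subjects:
    belt perimeters 77-105 cm and axis ratios 1.1-1.5, a ~13 cm belt
    band, 12 mm fiducial stickers, and a 1 mm scan resolution.
    """

    perimeter: float = 1000.0
    axis_ratio: float = 1.2
    z_extent: float = 130.0
    bump_amplitude: float = 6.0
    vertex_noise_sd: float = 0.0
    color_noise_sd: float = 0.0
    n_electrodes: int = 32
    sticker_radius: float = 6.0
    resolution: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 600.0 <= self.perimeter <= 1300.0:
            raise ValueError("perimeter outside the plausible 600-1300 mm band")
        if not 1.0 <= self.axis_ratio <= 2.0:
            raise ValueError("axis_ratio must be in [1.0, 2.0]")
        if self.perimeter / self.n_electrodes < 2.2 * self.sticker_radius:
            raise Scan2FemError(
                "stickers would overlap: perimeter too small for "
                f"{self.n_electrodes} stickers of radius {self.sticker_radius} mm"
            )


@dataclass
class PhantomTruth:
    """Analytic ground truth behind a generated scan."""

    spec: PhantomSpec
    scale: float
    electrode_centers: np.ndarray  # (n, 3), labels 1..n in row order
    lung_centers: np.ndarray
    lung_semiaxes: np.ndarray

    def radius(self, theta, z) -> np.ndarray:
        return _radius_field(self.spec, self.scale, np.asarray(theta, float),
                             np.asarray(z, float))

    def surface_point(self, theta, z) -> np.ndarray:
        r = self.radius(theta, z)
        return np.stack([r * np.cos(theta), r * np.sin(theta), np.broadcast_to(z, np.shape(theta))], axis=-1)

    def electrode_set(self) -> ElectrodeSet:
        n = self.spec.n_electrodes
        return ElectrodeSet(
            self.electrode_centers, np.arange(1, n + 1), frozenset(), n
        )


def _ellipse_radius(axis_ratio: float, theta: np.ndarray) -> np.ndarray:
    a, b = axis_ratio, 1.0
    return a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)


def _bumps(spec: PhantomSpec, theta: np.ndarray, z: np.ndarray) -> np.ndarray:
    zt = 2.0 * z / max(spec.z_extent, 1e-9)  # in [-1, 1]
    return spec.bump_amplitude * (
        np.cos(2 * theta + 0.7) * np.cos(0.5 * np.pi * zt)
        + 0.6 * np.cos(3 * theta - 1.2) * (0.5 + 0.5 * np.sin(0.5 * np.pi * zt))
    )


def _radius_field(spec: PhantomSpec, scale: float, theta, z) -> np.ndarray:
    return scale * _ellipse_radius(spec.axis_ratio, theta) + _bumps(spec, theta, z)


def _mid_perimeter(spec: PhantomSpec, scale: float, n: int = 8192) -> float:
    th = np.linspace(0, 2 * np.pi, n + 1)
    r = _radius_field(spec, scale, th, np.zeros(n + 1))
    xy = np.column_stack([r * np.cos(th), r * np.sin(th)])
    return float(np.linalg.norm(np.diff(xy, axis=0), axis=1).sum())


def _solve_scale(spec: PhantomSpec) -> float:
    """Scale of the ellipse term so the mid-slice perimeter matches."""
    lo, hi = spec.perimeter / (2 * np.pi * spec.axis_ratio) * 0.5, spec.perimeter
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _mid_perimeter(spec, mid) < spec.perimeter:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _electrode_arc_positions(spec: PhantomSpec, scale: float) -> np.ndarray:
    """θ of the electrode centers: equal arc-length spacing on the belt."""
    n = 8192
    th = np.linspace(0, 2 * np.pi, n + 1)
    r = _radius_field(spec, scale, th, np.zeros(n + 1))
    xy = np.column_stack([r * np.cos(th), r * np.sin(th)])
    cum = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(xy, axis=0), axis=1))])
    total = cum[-1]
    targets = (np.arange(spec.n_electrodes) + 0.5) * total / spec.n_electrodes
    return np.interp(targets, cum, th)


def _correlated_noise(rng, theta, zt, sd: float, n_modes: int = 8) -> np.ndarray:
    """Smooth random displacement field with per-axis SD ``sd``."""
    disp = np.zeros((len(theta), 3))
    for _ in range(n_modes):
        k = rng.integers(1, 5)
        l = rng.integers(0, 3)
        phi, psi = rng.uniform(0, 2 * np.pi, 2)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        mode = np.cos(k * theta + phi) * np.cos(np.pi * l * zt / 2 + psi)
        disp += np.outer(mode, direction)
    std = disp.std(axis=0).mean()
    if std > 0:
        disp *= sd / std
    return disp


def make_scan(
    spec: PhantomSpec, add_disconnected_blob: bool = False
) -> tuple[ColoredSurface, PhantomTruth]:
    """Generate a colored belt scan and its analytic ground truth.

    The surface is a star-shaped tube r(θ, z) (ellipse of the requested
    perimeter/axis ratio plus low-order bumps) triangulated at the spec's
    resolution; 32 sticker discs sit at equal arc spacing on the
    mid-band, anchors colored per the belt scheme, the rest white.
    Vertex and color noise are seeded and applied after painting.
    """
    rng = np.random.default_rng(spec.seed)
    scale = _solve_scale(spec)
    n_theta = max(16, int(round(spec.perimeter / spec.resolution)))
    n_z = max(4, int(round(spec.z_extent / spec.resolution)) + 1)
    th = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    zz = np.linspace(-spec.z_extent / 2, spec.z_extent / 2, n_z)
    tg, zg = np.meshgrid(th, zz, indexing="ij")
    r = _radius_field(spec, scale, tg, zg)
    verts = np.column_stack(
        [(r * np.cos(tg)).ravel(), (r * np.sin(tg)).ravel(), zg.ravel()]
    )
    faces = []
    for i in range(n_theta):
        i2 = (i + 1) % n_theta
        base, base2 = i * n_z, i2 * n_z
        for j in range(n_z - 1):
            faces.append([base + j, base2 + j, base + j + 1])
            faces.append([base2 + j, base2 + j + 1, base + j + 1])
    faces = np.array(faces)

    el_theta = _electrode_arc_positions(spec, scale)
    el_r = _radius_field(spec, scale, el_theta, np.zeros_like(el_theta))
    centers = np.column_stack(
        [el_r * np.cos(el_theta), el_r * np.sin(el_theta), np.zeros_like(el_theta)]
    )

    colors = np.tile(np.array(SKIN_RGB, dtype=float), (len(verts), 1))
    d, idx = cKDTree(centers).query(verts)
    on_sticker = d <= spec.sticker_radius
    from .electrode_id import ANCHOR_RGB

    sticker_rgb = np.tile(np.array(ANCHOR_RGB["white"], dtype=float), (spec.n_electrodes, 1))
    for lab, name in ANCHOR_COLOR_BY_LABEL.items():
        if lab <= spec.n_electrodes:
            sticker_rgb[lab - 1] = ANCHOR_RGB[name]
    colors[on_sticker] = sticker_rgb[idx[on_sticker]]

    if spec.vertex_noise_sd > 0:
        zt = 2.0 * verts[:, 2] / spec.z_extent
        theta_v = np.arctan2(verts[:, 1], verts[:, 0])
        verts = verts + _correlated_noise(rng, theta_v, zt, 0.9 * spec.vertex_noise_sd)
        verts = verts + rng.normal(0, 0.436 * spec.vertex_noise_sd, verts.shape)
    if spec.color_noise_sd > 0:
        colors = colors + rng.normal(0, spec.color_noise_sd, colors.shape)
    colors = np.clip(colors, 0, 255).astype(np.uint8)

    if add_disconnected_blob:
        blob_c = np.array([0.0, 0.0, spec.z_extent]) + verts.max(axis=0)
        bt = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        blob_v = blob_c + 5.0 * np.column_stack(
            [np.cos(bt), np.sin(bt), np.zeros(8)]
        )
        blob_v = np.vstack([blob_v, blob_c])
        blob_f = np.array([[i, (i + 1) % 8, 8] for i in range(8)]) + len(verts)
        verts = np.vstack([verts, blob_v])
        faces = np.vstack([faces, blob_f])
        colors = np.vstack([colors, np.tile(np.uint8(SKIN_RGB), (9, 1))])

    a_mm = scale * spec.axis_ratio
    b_mm = scale
    truth = PhantomTruth(
        spec=spec,
        scale=scale,
        electrode_centers=centers,
        lung_centers=np.array(
            [[-0.45 * a_mm, 0.0, 0.0], [0.45 * a_mm, 0.0, 0.0]]
        ),
        lung_semiaxes=np.array(
            [
                [0.30 * a_mm, 0.55 * b_mm, 0.45 * spec.z_extent],
                [0.30 * a_mm, 0.55 * b_mm, 0.45 * spec.z_extent],
            ]
        ),
    )
    return ColoredSurface(verts, faces, colors), truth


def make_tracked_points(
    truth: PhantomTruth,
    noise_sd: float = 0.0,
    occlude: frozenset | set = frozenset(),
    seed: int = 0,
    contour_height_frac: float = 0.3,
    contour_spacing: float = 5.0,
):
    """Tracker-style ground truth: noisy electrode points plus contours.

    Returns ``(ElectrodeSet, [front_contour, back_contour])``; contours
    run across the front and back of the thorax above the belt, like a
    tracked pointer tip traversal.
    """
    rng = np.random.default_rng(seed)
    spec = truth.spec
    occlude = frozenset(int(x) for x in occlude)
    labels = [l for l in range(1, spec.n_electrodes + 1) if l not in occlude]
    pts = np.array([truth.electrode_centers[l - 1] for l in labels])
    if noise_sd > 0:
        pts = pts + rng.normal(0, noise_sd, pts.shape)
    electrodes = ElectrodeSet(pts, np.array(labels), occlude, spec.n_electrodes)

    z_c = contour_height_frac * spec.z_extent / 2
    contours = []
    for th0 in (0.0, np.pi):
        span = 1.0  # ±1 rad about the sternum/spine
        r_mid = float(truth.radius(np.array([th0]), np.array([z_c]))[0])
        n = max(8, int(2 * span * r_mid / contour_spacing))
        th = th0 + np.linspace(-span, span, n)
        r = truth.radius(th, np.full(n, z_c))
        c = np.column_stack([r * np.cos(th), r * np.sin(th), np.full(n, z_c)])
        if noise_sd > 0:
            c = c + rng.normal(0, noise_sd, c.shape)
        contours.append(c)
    return electrodes, contours


def lung_element_masks(mesh, truth: PhantomTruth | None = None):
    """Boolean element masks (left, right) of the two lung ellipsoids.

    Without ground truth the lungs are placed from the mesh bounding box
    (centers at ±45% of the x half-width).
    """
    cents = mesh.tet_centroids()
    if truth is not None:
        centers, semis = truth.lung_centers, truth.lung_semiaxes
    else:
        lo, hi = mesh.nodes.min(axis=0), mesh.nodes.max(axis=0)
        mid = 0.5 * (lo + hi)
        half = 0.5 * (hi - lo)
        centers = np.array(
            [
                [mid[0] - 0.45 * half[0], mid[1], mid[2]],
                [mid[0] + 0.45 * half[0], mid[1], mid[2]],
            ]
        )
        semis = np.tile([0.30 * half[0], 0.55 * half[1], 0.9 * half[2]], (2, 1))
    masks = []
    for c, s in zip(centers, semis):
        masks.append(np.sum(((cents - c) / s) ** 2, axis=1) < 1.0)
    left, right = masks
    # "left" = negative x side by construction
    return (left, right) if centers[0, 0] < centers[1, 0] else (right, left)


def make_eit_sequence(
    mesh,
    protocol: EitProtocol | None = None,
    breath_rate: float = 0.25,
    depth: float = 0.1,
    duration: float = 30.0,
    noise_rel: float = 0.0,
    seed: int = 0,
    truth: PhantomTruth | None = None,
    background_sigma: float = 1.0,
    contact_impedance: float = 1e-3,
    n_phases: int = 9,
) -> EitFrameSet:
    """Simulated tidal-breathing voltage frames on a FEM mesh.

    Both lung regions oscillate as
    σ_lung(t) = σ0 · (1 − depth · (1 + sin 2πft)/2); the forward model is
    solved at ``n_phases`` inflation levels and interpolated to the frame
    clock for speed, then multiplicative Gaussian noise is applied.
    """
    protocol = protocol or EitProtocol()
    rng = np.random.default_rng(seed)
    left, right = lung_element_masks(mesh, truth)
    lung = left | right
    levels = np.linspace(0.0, 1.0, n_phases)
    V = []
    for s in levels:
        sigma = np.full(mesh.n_elements, background_sigma)
        sigma[lung] = background_sigma * (1.0 - depth * s)
        V.append(forward_solve(mesh, sigma, protocol, contact_impedance))
    V = np.array(V)  # (n_phases, n_meas)
    t = np.arange(0.0, duration, 1.0 / protocol.frame_rate_hz)
    s_t = 0.5 * (1.0 + np.sin(2 * np.pi * breath_rate * t))
    if depth == 0:
        frames = np.tile(V[0][:, None], (1, len(t)))
    else:
        frames = interp1d(levels, V, axis=0, kind="cubic" if n_phases >= 4 else "linear")(s_t).T
    if noise_rel > 0:
        frames = frames * (1.0 + rng.normal(0, noise_rel, frames.shape))
    return EitFrameSet(frames, t, None, protocol)
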