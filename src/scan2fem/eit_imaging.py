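"""Complete-electrode-model EIT forward solver and difference imaging.

Forward model: linear (P1) finite elements on the subject-specific
tetrahedral mesh with the complete electrode model (CEM) — finite
electrode patches with contact impedance, current conservation and a
zero-mean electrode-potential gauge.  Difference images are produced by
a one-step Gauss-Newton update with standard Tikhonov regularization on
voltage data normalized by the baseline frame, the standard approach for
tidal-breathing lung imaging.

Units: mesh coordinates are mm (converted to meters internally),
conductivity in S/m, contact impedance in Ω·m², currents in A,
voltages in V.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.signal import find_peaks
from scipy.sparse.linalg import splu

from .belt_mesh import FemMesh
from .errors import ConfigError, NoBreathsError, SolverError, TooFewChannelsError

MM = 1e-3  # mm -> m


@dataclass
class EitProtocol:
    """Pairwise injection/measurement protocol of the 32-electrode belt.

    ``skip`` electrodes are skipped between the two injecting electrodes
    (skip-4: pairs (i, i+5 mod 32)).  Voltages are read on the same
    skip pattern, excluding any pair touching an injecting electrode.
    """

    n_electrodes: int = 32
    skip: int = 4
    current_amplitude: float = 3e-3
    frequency_hz: float = 195e3
    frame_rate_hz: float = 48.0

    def injection_pairs(self) -> np.ndarray:
        n = self.n_electrodes
        i = np.arange(n)
        return np.column_stack([i, (i + self.skip + 1) % n])

    def measurements(self) -> np.ndarray:
        """(m, 3) rows ``(drive_index, meas+, meas-)``, deterministic."""
        pairs = self.injection_pairs()
        rows = []
        for d, (src, snk) in enumerate(pairs):
            for a, b in pairs:
                if len({a, b} & {src, snk}) == 0:
                    rows.append((d, a, b))
        return np.array(rows, dtype=np.int64)

    @property
    def n_measurements(self) -> int:
        return len(self.measurements())


@dataclass
class EitFrameSet:
    """Time series of EIT measurement vectors.

    ``frames``: (n_measurements, n_frames) volts; ``timestamps`` seconds;
    ``channel_mask`` True for usable channels.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    channel_mask: np.ndarray | None = None
    protocol: EitProtocol | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float).reshape(-1)
        if self.frames.shape[1] != len(self.timestamps):
            raise ValueError("frames columns must match timestamps")
        if self.channel_mask is None:
            self.channel_mask = np.ones(self.frames.shape[0], dtype=bool)
        self.channel_mask = np.asarray(self.channel_mask, dtype=bool).reshape(-1)
        if len(self.channel_mask) != self.frames.shape[0]:
            raise ValueError("channel_mask length must equal measurement count")


@dataclass
class ReconConfig:
    """One-step Gauss-Newton settings.

    ``lam`` is the Tikhonov weight relative to the mean diagonal of the
    normalized Gauss-Newton operator (default from an L-curve sweep on
    synthetic two-lung data); ``contact_impedance`` in Ω·m² applies to
    every electrode.
    """

    lam: float = 0.03
    background_sigma: float = 1.0
    contact_impedance: float = 1e-3

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ConfigError("Tikhonov weight lam must be > 0")
        if self.background_sigma <= 0 or self.contact_impedance <= 0:
            raise ConfigError("conductivity and contact impedance must be > 0")


class CemSystem:
    """Assembled CEM FEM system for one conductivity distribution.

    Unknowns: node potentials, electrode potentials, and one Lagrange
    multiplier enforcing the zero-mean electrode-potential gauge.
    """

    def __init__(self, mesh: FemMesh, sigma: np.ndarray, contact_impedance: float = 1e-3):
        sigma = np.asarray(sigma, dtype=float)
        if sigma.ndim == 0:
            sigma = np.full(mesh.n_elements, float(sigma))
        if len(sigma) != mesh.n_elements:
            raise ValueError("sigma must have one value per element")
        if (sigma <= 0).any():
            raise SolverError("conductivity must be positive everywhere")
        self.mesh = mesh
        self.sigma = sigma
        self.labels = sorted(mesh.electrode_facets)
        self.n_el = len(self.labels)
        self.zc = float(contact_impedance)
        self._assemble()
        try:
            self.lu = splu(self.system.tocsc())
        except RuntimeError as exc:
            raise SolverError(f"singular CEM system: {exc}") from exc

    # -- assembly ------------------------------------------------------
    def _grads(self):
        """Per-tet P1 basis gradients (1/m) and volumes (m^3)."""
        nodes = self.mesh.nodes * MM
        tets = self.mesh.tets
        p0 = nodes[tets[:, 0]]
        mat = np.stack([nodes[tets[:, k]] - p0 for k in (1, 2, 3)], axis=2)
        vol = np.linalg.det(mat) / 6.0
        inv = np.linalg.inv(mat)
        # rows of inv(mat) are the gradients of the barycentric coords 1..3
        g = np.empty((len(tets), 4, 3))
        g[:, 1:, :] = inv
        g[:, 0, :] = -inv.sum(axis=1)
        return g, vol

    def _assemble(self):
        mesh = self.mesh
        n = mesh.n_nodes
        g, vol = self._grads()
        if (vol <= 0).any():
            raise SolverError("non-positive tet volume in CEM assembly")
        self.grads = g
        self.volumes = vol
        tets = mesh.tets
        w = self.sigma * vol
        size = n + self.n_el + 1
        rows, cols, vals = [], [], []
        for i in range(4):
            for j in range(4):
                rows.append(tets[:, i])
                cols.append(tets[:, j])
                vals.append(w * np.einsum("ij,ij->i", g[:, i, :], g[:, j, :]))

        self.electrode_areas = np.zeros(self.n_el)
        for li, lab in enumerate(self.labels):
            tris = mesh.electrode_facets[lab]
            p = mesh.nodes[tris] * MM
            areas = 0.5 * np.linalg.norm(
                np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
            )
            self.electrode_areas[li] = areas.sum()
            col = n + li
            # boundary mass on the patch: area/12 * (2 diag, 1 off), over zc
            for i in range(3):
                for j in range(3):
                    rows.append(tris[:, i])
                    cols.append(tris[:, j])
                    vals.append(areas * ((2.0 if i == j else 1.0) / 12.0) / self.zc)
                # node-electrode coupling: -(area/3)/zc
                rows.append(tris[:, i])
                cols.append(np.full(len(tris), col))
                vals.append(-areas / 3.0 / self.zc)
                rows.append(np.full(len(tris), col))
                cols.append(tris[:, i])
                vals.append(-areas / 3.0 / self.zc)
            rows.append([col])
            cols.append([col])
            vals.append([self.electrode_areas[li] / self.zc])
        # zero-mean electrode potential gauge (Lagrange multiplier row/col)
        for li in range(self.n_el):
            rows.extend([[n + li], [size - 1]])
            cols.extend([[size - 1], [n + li]])
            vals.extend([[1.0], [1.0]])
        self.system = sp.coo_matrix(
            (
                np.concatenate([np.asarray(v, dtype=float) for v in vals]),
                (
                    np.concatenate([np.asarray(r, dtype=np.int64) for r in rows]),
                    np.concatenate([np.asarray(c, dtype=np.int64) for c in cols]),
                ),
            ),
            shape=(size, size),
        ).tocsr()
        self.n_nodes = n

    # -- solves --------------------------------------------------------
    def solve_drives(self, drive_currents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Solve for a (n_drives, n_electrodes) current matrix.

        Returns (node potentials (n_drives, n_nodes), electrode potentials
        (n_drives, n_electrodes)).
        """
        drive_currents = np.atleast_2d(drive_currents)
        rhs = np.zeros((self.system.shape[0], len(drive_currents)))
        rhs[self.n_nodes : self.n_nodes + self.n_el, :] = drive_currents.T
        sol = self.lu.solve(rhs)
        return sol[: self.n_nodes].T, sol[self.n_nodes : self.n_nodes + self.n_el].T


def _drive_matrix(protocol: EitProtocol) -> np.ndarray:
    pairs = protocol.injection_pairs()
    drives = np.zeros((len(pairs), protocol.n_electrodes))
    amp = protocol.current_amplitude
    drives[np.arange(len(pairs)), pairs[:, 0]] = amp
    drives[np.arange(len(pairs)), pairs[:, 1]] = -amp
    return drives


def forward_solve(
    mesh: FemMesh,
    sigma: np.ndarray | float,
    protocol: EitProtocol,
    contact_impedance: float = 1e-3,
    system: CemSystem | None = None,
) -> np.ndarray:
    """Simulated measurement vector for all protocol channels (volts)."""
    system = system or CemSystem(mesh, sigma, contact_impedance)
    _, U = system.solve_drives(_drive_matrix(protocol))
    meas = protocol.measurements()
    return U[meas[:, 0], meas[:, 1]] - U[meas[:, 0], meas[:, 2]]


def jacobian(
    mesh: FemMesh,
    sigma0: np.ndarray | float,
    protocol: EitProtocol,
    contact_impedance: float = 1e-3,
    system: CemSystem | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sensitivity matrix J (measurements × elements) and baseline v0.

    Adjoint formula per element e:
    ``J[m, e] = -(1/I) ∫_e ∇u_drive · ∇u_meas dV`` where both fields are
    driven with the protocol amplitude I; measurement fields reuse the
    32 injection-pattern solves since measurement pairs follow the same
    skip pattern.
    """
    system = system or CemSystem(mesh, sigma0, contact_impedance)
    if (system.volumes <= 0).any():
        raise SolverError("zero-volume element in Jacobian assembly")
    u, U = system.solve_drives(_drive_matrix(protocol))
    # per-drive, per-element field gradients: (n_drives, n_elem, 3)
    tets = mesh.tets
    g = system.grads
    grad_u = np.einsum("dnk,nkj->dnj", u[:, tets], g)
    meas = protocol.measurements()
    amp = protocol.current_amplitude
    # measurement pattern j uses the same electrode pair as drive pattern j;
    # find for each measurement row the drive index of its electrode pair
    pairs = protocol.injection_pairs()
    pair_of = {(a, b): d for d, (a, b) in enumerate(pairs)}
    meas_drive = np.array([pair_of[(a, b)] for _, a, b in meas])
    J = -np.einsum(
        "mnj,mnj,n->mn", grad_u[meas[:, 0]], grad_u[meas_drive], system.volumes
    ) / amp
    v0 = U[meas[:, 0], meas[:, 1]] - U[meas[:, 0], meas[:, 2]]
    return J, v0


def reconstruct(
    J: np.ndarray,
    v0: np.ndarray,
    v1: np.ndarray,
    config: ReconConfig | None = None,
    channel_mask: np.ndarray | None = None,
) -> np.ndarray:
    """One-step Gauss-Newton Tikhonov difference image (per-element δσ).

    Data are normalized by the baseline: b = (v1 - v0)/v0 with J
    row-normalized accordingly; δσ = (JnᵀJn + λI)⁻¹ Jnᵀ b, evaluated in
    measurement space via the push-through identity.  Masked channels are
    excluded entirely.
    """
    config = config or ReconConfig()
    J = np.asarray(J, dtype=float)
    v0 = np.asarray(v0, dtype=float).reshape(-1)
    v1 = np.asarray(v1, dtype=float).reshape(-1)
    mask = (
        np.ones(len(v0), dtype=bool) if channel_mask is None
        else np.asarray(channel_mask, dtype=bool)
    )
    if (v0[mask] == 0).any():
        raise SolverError("baseline voltage is zero on an unmasked channel")
    Jn = J[mask] / v0[mask, None]
    b = (v1[mask] - v0[mask]) / v0[mask]
    gram = Jn @ Jn.T
    lam = config.lam * float(np.mean(np.diag(gram)))
    rhs = np.linalg.solve(gram + lam * np.eye(len(b)), b)
    return Jn.T @ rhs


def global_signal(frames: EitFrameSet) -> np.ndarray:
    """Σ|v| over unmasked channels per frame — the breathing waveform."""
    return np.abs(frames.frames[frames.channel_mask]).sum(axis=0)


def detect_breaths(frames: EitFrameSet, min_prominence_frac: float = 0.2):
    """Prominence-based inhale-peak / exhale-trough detection.

    Returns (peak frame indices, trough frame indices).  Raises
    :class:`NoBreathsError` when fewer than two breaths are present.
    """
    sig = global_signal(frames)
    span = float(np.percentile(sig, 98) - np.percentile(sig, 2))
    if span <= 0 or not np.isfinite(span):
        raise NoBreathsError("flat global signal: no breaths detected")
    if len(frames.timestamps) > 1:
        dt = float(np.median(np.diff(frames.timestamps)))
        min_dist = max(1, int(0.5 / dt))  # breaths slower than 2 Hz
    else:
        min_dist = 1
    prom = min_prominence_frac * span
    peaks, _ = find_peaks(sig, prominence=prom, distance=min_dist)
    troughs, _ = find_peaks(-sig, prominence=prom, distance=min_dist)
    if len(peaks) < 2 or len(troughs) < 1:
        raise NoBreathsError(
            f"detected {len(peaks)} inhale peaks / {len(troughs)} troughs; need >=2 breaths"
        )
    return peaks, troughs


def tidal_image(
    frames: EitFrameSet,
    J: np.ndarray,
    v0: np.ndarray | None = None,
    config: ReconConfig | None = None,
) -> np.ndarray:
    """Tidal-breathing difference image: mean end-inhale vs mean end-exhale.

    The baseline for normalization defaults to the exhale mean itself,
    i.e. the image shows conductivity at inhale relative to exhale
    (negative in air-filled lung regions).
    """
    peaks, troughs = detect_breaths(frames)
    v_in = frames.frames[:, peaks].mean(axis=1)
    v_ex = frames.frames[:, troughs].mean(axis=1)
    base = v_ex if v0 is None else np.asarray(v0, dtype=float)
    return reconstruct(J, base, v_in, config, frames.channel_mask)


def filter_channels(
    frames: EitFrameSet,
    rel_variance_threshold: float = 0.25,
    min_fraction: float = 0.5,
) -> np.ndarray:
    """Mask noisy channels by relative temporal variation.

    A channel whose temporal standard deviation exceeds
    ``rel_variance_threshold`` times its mean absolute level is rejected
    (breathing modulates channels by a few percent; anything larger is
    electrode noise).  Raises :class:`TooFewChannelsError` when fewer
    than ``min_fraction`` of channels survive.
    """
    v = frames.frames
    level = np.abs(v).mean(axis=1)
    std = v.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(level > 0, std / level, np.inf)
    mask = rel < rel_variance_threshold
    if mask.sum() < min_fraction * len(mask):
        raise TooFewChannelsError(
            f"only {mask.sum()}/{len(mask)} channels pass the noise filter"
        )
    return mask


def slice_image(
    mesh: FemMesh, delta_sigma: np.ndarray, z: float, n: int = 64
) -> tuple[np.ndarray, tuple]:
    """Nearest-element interpolation of δσ onto the horizontal plane at z.

    Returns (n×n image array with NaN outside the mesh, (x_min, x_max,
    y_min, y_max) extent) for display of the belt-plane slice.
    """
    from scipy.spatial import cKDTree

    cents = mesh.tet_centroids()
    lo = mesh.nodes.min(axis=0)
    hi = mesh.nodes.max(axis=0)
    xs = np.linspace(lo[0], hi[0], n)
    ys = np.linspace(lo[1], hi[1], n)
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    pts = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, z)])
    tree = cKDTree(cents)
    d, idx = tree.query(pts)
    img = delta_sigma[idx]
    img[d > 2.0 * np.median(d)] = np.nan
    return img.reshape(n, n), (lo[0], hi[0], lo[1], hi[1])
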