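"""Smooth low-parameter boundary model r(θ, z) of the belt-level thorax.

The leveled, cropped scan is reduced to a star-shaped radius field:
a Fourier series in azimuth θ whose coefficients vary with height z
through Gaussian radial-basis-function (RBF) interpolation,

    r(θ, z) = Σ_{m=0..2N} Σ_{k=1..M} C[m, k] · ψ_m(θ) · φ_k(z),

with ψ = {1, cos θ, sin θ, …, cos Nθ, sin Nθ} and φ_k Gaussian kernels
centered at M heights spanning the belt band.  At the defaults N=12,
M=7 the surface is described by (2N+1)·M = 175 coefficients.  The model
is fit by ridge-regularized linear least squares on the scan vertices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .errors import ThinBandError
from .scan_io import ColoredSurface


@dataclass
class FitConfig:
    """Knobs of the boundary fit.

    fourier_order : azimuthal harmonics N (2N+1 basis functions)
    n_centers : number M of RBF heights, uniform over the fitted z-range
    rbf_width : Gaussian kernel scale in mm; ``None`` → 1.5× center spacing
    ridge : tiny Tikhonov weight on the coefficients (conditioning only)
    """

    fourier_order: int = 12
    n_centers: int = 7
    rbf_width: float | None = None
    ridge: float = 1e-10


@dataclass
class SurfaceFitModel:
    """Fourier(θ) × RBF(z) radius field; see module docstring."""

    fourier_order: int
    rbf_centers: np.ndarray
    rbf_width: float
    coeffs: np.ndarray
    z_range: tuple[float, float]
    center: np.ndarray = field(default_factory=lambda: np.zeros(2))
    residual_rms: float | None = None

    def __post_init__(self) -> None:
        self.rbf_centers = np.asarray(self.rbf_centers, dtype=float).reshape(-1)
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.center = np.asarray(self.center, dtype=float).reshape(2)
        n_az = 2 * self.fourier_order + 1
        n_height = len(self.rbf_centers) + 1  # constant + Gaussian kernels
        if self.coeffs.shape != (n_az, n_height):
            raise ValueError(
                f"coeffs must be {(n_az, n_height)}, got {self.coeffs.shape}"
            )
        self._tree = None

    @property
    def n_parameters(self) -> int:
        return self.coeffs.size

    # -- basis ---------------------------------------------------------
    def _angular_basis(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        n = self.fourier_order
        cols = [np.ones_like(theta)]
        for m in range(1, n + 1):
            cols.append(np.cos(m * theta))
            cols.append(np.sin(m * theta))
        return np.stack(cols, axis=-1)

    def _height_basis(self, z: np.ndarray) -> np.ndarray:
        # constant + (M-1) Gaussian kernels: the constant term lets flat
        # (z-independent) radii be represented exactly, the usual
        # polynomial augmentation of an RBF basis
        z = self._clamp_z(np.asarray(z, dtype=float))
        d = (z[..., None] - self.rbf_centers) / self.rbf_width
        return np.concatenate(
            [np.ones((*z.shape, 1)), np.exp(-(d**2))], axis=-1
        )

    def _clamp_z(self, z: np.ndarray) -> np.ndarray:
        return np.clip(z, self.z_range[0], self.z_range[1])

    # -- queries -------------------------------------------------------
    def radius(self, theta, z) -> np.ndarray:
        """r(θ, z); z is flat-clamped outside the fitted range."""
        psi = self._angular_basis(theta)
        phi = self._height_basis(z)
        return np.einsum("...m,...k,mk->...", psi, phi, self.coeffs)

    def evaluate(self, theta, z) -> np.ndarray:
        """3D point on the fitted surface at (θ, z)."""
        theta, z = np.broadcast_arrays(
            np.asarray(theta, dtype=float), np.asarray(z, dtype=float)
        )
        r = self.radius(theta, z)
        return np.stack(
            [
                self.center[0] + r * np.cos(theta),
                self.center[1] + r * np.sin(theta),
                z,
            ],
            axis=-1,
        )

    def _cylindrical(self, points: np.ndarray):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        dx = pts[:, 0] - self.center[0]
        dy = pts[:, 1] - self.center[1]
        return np.arctan2(dy, dx), pts[:, 2], np.hypot(dx, dy)

    def project_radial(self, points: np.ndarray) -> np.ndarray:
        """Snap points onto the surface along rays from the center axis."""
        theta, z, _ = self._cylindrical(points)
        return self.evaluate(theta, self._clamp_z(z)).reshape(np.shape(points))

    def signed_distance(self, points: np.ndarray, exact: bool = False) -> np.ndarray:
        """Distance to the lateral surface; negative inside.

        The default is the radial gauge ρ − r(θ, z), exact on the surface
        and cheap enough for remeshing loops.  ``exact=True`` refines the
        magnitude to the true nearest-point distance (sign unchanged).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        theta, z, rho = self._cylindrical(pts)
        radial = rho - self.radius(theta, self._clamp_z(z))
        if not exact:
            return radial if np.asarray(points).ndim > 1 else float(radial[0])
        if self._tree is None:
            th = np.linspace(0, 2 * np.pi, 512, endpoint=False)
            zz = np.linspace(self.z_range[0], self.z_range[1], 128)
            tg, zg = np.meshgrid(th, zz, indexing="ij")
            samples = self.evaluate(tg.ravel(), zg.ravel())
            self._tree = (cKDTree(samples), np.column_stack([tg.ravel(), zg.ravel()]))
        tree, params = self._tree
        d0, idx = tree.query(pts)
        out = np.empty(len(pts))
        for i, p in enumerate(pts):
            t0, z0 = params[idx[i]]

            def sqdist(x):
                return float(np.sum((self.evaluate(x[0], self._clamp_z(x[1])) - p) ** 2))

            res = minimize(sqdist, [t0, z0], method="Nelder-Mead",
                           options={"xatol": 1e-6, "fatol": 1e-12})
            out[i] = np.sqrt(res.fun)
        out *= np.sign(radial) + (radial == 0)
        return out if np.asarray(points).ndim > 1 else float(out[0])

    def sample_mesh(self, n_theta: int, n_z: int) -> ColoredSurface:
        """Triangulated open-ended tube sampled on a (θ, z) grid."""
        th = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
        zz = np.linspace(self.z_range[0], self.z_range[1], n_z)
        tg, zg = np.meshgrid(th, zz, indexing="ij")
        verts = self.evaluate(tg.ravel(), zg.ravel())
        faces = []
        for i in range(n_theta):
            i2 = (i + 1) % n_theta
            for j in range(n_z - 1):
                a = i * n_z + j
                b = i2 * n_z + j
                faces.append([a, b, a + 1])
                faces.append([b, b + 1, a + 1])
        colors = np.full((len(verts), 3), 255, dtype=np.uint8)
        return ColoredSurface(verts, np.array(faces), colors)

    def perimeter(self, z: float, n: int = 4096) -> float:
        """Arc length of the horizontal slice at height z, mm."""
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        pts = self.evaluate(th, np.full(n, float(z)))[:, :2]
        return float(np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1).sum())

    # -- (de)serialization ---------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "fourier_order": self.fourier_order,
                "rbf_centers": self.rbf_centers.tolist(),
                "rbf_width": self.rbf_width,
                "coeffs": self.coeffs.tolist(),
                "z_range": list(self.z_range),
                "center": self.center.tolist(),
                "residual_rms": self.residual_rms,
            }
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "SurfaceFitModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            d["fourier_order"],
            np.array(d["rbf_centers"]),
            d["rbf_width"],
            np.array(d["coeffs"]),
            tuple(d["z_range"]),
            np.array(d["center"]),
            d.get("residual_rms"),
        )


def fit_surface(
    surface: ColoredSurface, config: FitConfig | None = None
) -> SurfaceFitModel:
    """Fit the Fourier×RBF radius field to a leveled scan.

    Vertices are converted to cylindrical (θ, z, r) about the origin (the
    leveled electrode centroid) and the coefficient matrix is solved from
    the ridge-regularized normal equations, accumulated in chunks so
    scans with hundreds of thousands of vertices stay in memory.
    """
    config = config or FitConfig()
    n_param = (2 * config.fourier_order + 1) * config.n_centers
    verts = surface.vertices
    if len(verts) < n_param:
        raise ValueError(
            f"need at least {n_param} vertices to fit {n_param} coefficients, "
            f"got {len(verts)}"
        )
    z = verts[:, 2]
    z_lo, z_hi = float(z.min()), float(z.max())
    # height basis = constant + (n_centers - 1) Gaussians, so the total
    # height dimension stays n_centers
    n_gauss = max(config.n_centers - 1, 1)
    centers = np.linspace(z_lo, z_hi, n_gauss)
    spacing = (z_hi - z_lo) / max(n_gauss - 1, 1)
    width = config.rbf_width if config.rbf_width is not None else 1.5 * spacing
    if (z_hi - z_lo) < 2 * width and config.rbf_width is not None:
        raise ThinBandError(
            f"z-range {z_hi - z_lo:.1f} mm is shorter than two kernel widths "
            f"({2 * width:.1f} mm)"
        )
    if width <= 0:
        raise ThinBandError("degenerate z-range: kernel width is zero")

    model = SurfaceFitModel(
        config.fourier_order, centers, width,
        np.zeros((2 * config.fourier_order + 1, config.n_centers)),
        (z_lo, z_hi),
    )
    theta = np.arctan2(verts[:, 1], verts[:, 0])
    r = np.hypot(verts[:, 0], verts[:, 1])

    # blocked QR accumulation: the wide-Gaussian height basis is highly
    # collinear, so normal equations would square an ~1e8 condition number
    R = np.empty((0, n_param))
    qtb = np.empty(0)
    chunk = 50_000
    col_norm = 0.0
    for s in range(0, len(verts), chunk):
        sl = slice(s, s + chunk)
        psi = model._angular_basis(theta[sl])
        phi = model._height_basis(z[sl])
        a = (psi[:, :, None] * phi[:, None, :]).reshape(len(psi), n_param)
        col_norm += float(np.sum(a**2))
        q, R = np.linalg.qr(np.vstack([R, a]))
        qtb = q.T @ np.concatenate([qtb, r[sl]])
    scale = np.sqrt(config.ridge * col_norm / n_param)
    aug = np.vstack([R, scale * np.eye(n_param)])
    rhs = np.concatenate([qtb, np.zeros(n_param)])
    coeffs = np.linalg.lstsq(aug, rhs, rcond=None)[0]
    model.coeffs = coeffs.reshape(2 * config.fourier_order + 1, config.n_centers)

    sq = 0.0
    for s in range(0, len(verts), chunk):
        sl = slice(s, s + chunk)
        pred = model.radius(theta[sl], z[sl])
        sq += float(np.sum((r[sl] - pred) ** 2))
    model.residual_rms = float(np.sqrt(sq / len(verts)))
    return model
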