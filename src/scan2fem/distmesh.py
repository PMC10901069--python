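"""Force-equilibrium surface remeshing (Persson-Strang style).

Nodes are treated as a truss: every Delaunay edge is a bar pushing its
endpoints apart toward a desired length given by a sizing field h(x),
and after each displacement step the nodes are projected back onto the
geometry.  Two geometry flavors are provided:

* :func:`remesh_tube` — an open-ended star-shaped tube r(θ, z) (the
  belt-band thorax fit); connectivity comes from a periodic 2D Delaunay
  triangulation in an arc-length parameterization.
* :func:`remesh_convex` — a closed convex surface (e.g. a sphere);
  connectivity is the convex hull of the node set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, cKDTree

from .errors import RemeshNoConvergeError


@dataclass
class RemeshReport:
    iterations: int = 0
    converged: bool = False
    max_movement: float = np.nan
    n_nodes: int = 0
    n_triangles: int = 0
    movement_log: list = field(default_factory=list)


def _unique_edges(tris: np.ndarray) -> np.ndarray:
    e = np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    return np.unique(np.sort(e, axis=1), axis=0)


def _spring_step(
    pts: np.ndarray, edges: np.ndarray, h_func, fscale: float, dt: float, movable: np.ndarray
) -> np.ndarray:
    """One distmesh force step in 3D; returns per-node displacement."""
    bars = pts[edges[:, 0]] - pts[edges[:, 1]]
    lengths = np.linalg.norm(bars, axis=1)
    lengths[lengths == 0] = 1e-12
    mids = 0.5 * (pts[edges[:, 0]] + pts[edges[:, 1]])
    hbars = np.asarray(h_func(mids), dtype=float)
    # scale desired lengths so total "material" slightly exceeds current
    scale = fscale * np.sqrt(np.sum(lengths**2) / np.sum(hbars**2))
    l0 = hbars * scale
    force = np.maximum(l0 - lengths, 0.0)
    fvec = (force / lengths)[:, None] * bars
    disp = np.zeros_like(pts)
    np.add.at(disp, edges[:, 0], fvec)
    np.add.at(disp, edges[:, 1], -fvec)
    disp *= dt
    disp[~movable] = 0.0
    return disp


# ----------------------------------------------------------------------
# tube geometry
# ----------------------------------------------------------------------

class _ArcMap:
    """Monotone map between azimuth θ and arc length s of the mid-slice."""

    def __init__(self, model, z_mid: float, n: int = 2048):
        th = np.linspace(0.0, 2 * np.pi, n + 1)
        ring = model.evaluate(th, np.full(n + 1, z_mid))[:, :2]
        seg = np.linalg.norm(np.diff(ring, axis=0), axis=1)
        self.theta = th
        self.cum = np.concatenate([[0.0], np.cumsum(seg)])
        self.total = float(self.cum[-1])

    def s(self, theta: np.ndarray) -> np.ndarray:
        return np.interp(np.mod(theta, 2 * np.pi), self.theta, self.cum)

    def theta_of(self, s: np.ndarray) -> np.ndarray:
        return np.interp(np.mod(s, self.total), self.cum, self.theta)


def _tube_triangulate(pts: np.ndarray, model, arc: _ArcMap, band: float) -> np.ndarray:
    """Periodic Delaunay connectivity in (s, z) parameter space."""
    theta = np.arctan2(pts[:, 1] - model.center[1], pts[:, 0] - model.center[0])
    s = arc.s(theta)
    z = pts[:, 2]
    total = arc.total
    left = np.flatnonzero(s < band)
    right = np.flatnonzero(s > total - band)
    param = np.column_stack([s, z])
    ghosts = np.vstack(
        [
            np.column_stack([s[left] + total, z[left]]),
            np.column_stack([s[right] - total, z[right]]),
        ]
    )
    orig = np.concatenate([np.arange(len(pts)), left, right])
    allpts = np.vstack([param, ghosts])
    tri = Delaunay(allpts)
    cent = allpts[tri.simplices].mean(axis=1)
    keep = (cent[:, 0] >= 0.0) & (cent[:, 0] < total)
    # drop boundary slivers: near-collinear chains along the band ends
    # produce long degenerate triangles hugging the boundary line
    a2d = allpts[tri.simplices]
    e1 = a2d[:, 1] - a2d[:, 0]
    e2 = a2d[:, 2] - a2d[:, 0]
    e3 = a2d[:, 2] - a2d[:, 1]
    area2 = np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
    lmax2 = np.maximum.reduce(
        [np.sum(e1**2, axis=1), np.sum(e2**2, axis=1), np.sum(e3**2, axis=1)]
    )
    keep &= area2 > 0.05 * lmax2
    tris = orig[tri.simplices[keep]]
    # drop duplicated seam triangles and degenerate ones
    tris = tris[np.ptp(tris, axis=1) > 0]
    tris = np.unique(np.sort(tris, axis=1), axis=0)
    return _orient_outward(pts, tris, model)


def _orient_outward(pts: np.ndarray, tris: np.ndarray, model) -> np.ndarray:
    a, b, c = pts[tris[:, 0]], pts[tris[:, 1]], pts[tris[:, 2]]
    normal = np.cross(b - a, c - a)
    cent = (a + b + c) / 3.0
    radial = cent.copy()
    radial[:, 0] -= model.center[0]
    radial[:, 1] -= model.center[1]
    radial[:, 2] = 0.0
    flip = np.einsum("ij,ij->i", normal, radial) < 0
    tris = tris.copy()
    tris[flip] = tris[flip][:, [0, 2, 1]]
    return tris


def _ring_points(model, z: float, h_func, inward: float = 0.0, rng=None) -> np.ndarray:
    """Fixed boundary ring at height z, spaced by the local sizing field.

    ``inward`` (±1) applies a tiny seeded z-jitter into the band: an
    exactly coplanar circle of nodes would later produce degenerate
    (flat) Delaunay tetrahedra in the volume mesher.
    """
    arc = _ArcMap(model, z)
    h_probe = np.asarray(h_func(model.evaluate(np.linspace(0, 2 * np.pi, 64), np.full(64, z))))
    n = max(8, int(np.ceil(arc.total / float(np.min(h_probe)))))
    # equal arc-length spacing, then thin where h is larger
    s = np.linspace(0.0, arc.total, n, endpoint=False)
    pts = model.evaluate(arc.theta_of(s), np.full(n, z))
    keep = [0]
    acc = 0.0
    for i in range(1, n):
        acc += arc.total / n
        if acc >= 0.95 * float(h_func(pts[i][None])[0]):
            keep.append(i)
            acc = 0.0
    pts = pts[keep]
    if inward and rng is not None:
        h_loc = np.asarray(h_func(pts), dtype=float)
        pts[:, 2] += inward * rng.uniform(0.01, 0.04, len(pts)) * h_loc
    return pts


def _seed_tube(model, z_range, h_func, h_min, rng) -> np.ndarray:
    """Initial interior nodes: equilateral grid in (s, z), thinned by 1/h²."""
    arc = _ArcMap(model, 0.5 * (z_range[0] + z_range[1]))
    sx = np.arange(0.0, arc.total, h_min)
    sy = np.arange(z_range[0] + 0.5 * h_min, z_range[1], h_min * np.sqrt(3) / 2)
    sg, zg = np.meshgrid(sx, sy, indexing="ij")
    sg[:, 1::2] += h_min / 2
    pts = model.evaluate(arc.theta_of(sg.ravel()), zg.ravel())
    h = np.asarray(h_func(pts), dtype=float)
    keep = rng.random(len(pts)) < (h_min / h) ** 2
    return pts[keep]


def remesh_tube(
    model,
    z_range: tuple[float, float],
    h_func,
    fixed: np.ndarray | None = None,
    *,
    h_reference: float | None = None,
    fscale: float = 1.2,
    dt: float = 0.2,
    ptol: float = 1e-3,
    max_iter: int = 500,
    seed: int = 0,
    strict: bool = False,
):
    """Remesh the lateral surface of an r(θ, z) tube.

    Returns ``(points, triangles, fixed_mask, report)``.  ``fixed`` points
    (already on the surface) are held in place; boundary rings at both z
    limits are added automatically so the tube ends are clean circles.
    Iteration stops when the largest node displacement drops below
    ``ptol * h_reference`` or after ``max_iter`` sweeps; a NaN collapse
    (or, with ``strict=True``, failure to converge) raises
    :class:`RemeshNoConvergeError`.
    """
    rng = np.random.default_rng(seed)
    z_lo, z_hi = float(z_range[0]), float(z_range[1])
    probe_t = np.linspace(0, 2 * np.pi, 128)
    probe = model.evaluate(
        np.tile(probe_t, 8), np.repeat(np.linspace(z_lo, z_hi, 8), 128)
    )
    h_probe = np.asarray(h_func(probe), dtype=float)
    h_min, h_max = float(h_probe.min()), float(h_probe.max())
    h_ref = h_reference if h_reference is not None else h_max

    rings = [
        _ring_points(model, z_lo, h_func, inward=+1.0, rng=rng),
        _ring_points(model, z_hi, h_func, inward=-1.0, rng=rng),
    ]
    fixed_pts = np.vstack([*rings] + ([np.atleast_2d(fixed)] if fixed is not None and len(fixed) else []))
    pts = _seed_tube(model, (z_lo, z_hi), h_func, h_min, rng)
    # keep free nodes clear of fixed ones
    if len(pts):
        d, _ = cKDTree(fixed_pts).query(pts)
        pts = pts[d > 0.7 * np.asarray(h_func(pts), dtype=float)]
    pts = np.vstack([fixed_pts, pts])
    movable = np.ones(len(pts), dtype=bool)
    movable[: len(fixed_pts)] = False
    # per-node randomized clamp margins: nodes pressed against the band
    # ends must not all land on one exact plane (degenerate volume tets)
    h_at = np.asarray(h_func(pts), dtype=float)
    margin = rng.uniform(0.01, 0.04, len(pts)) * h_at
    z_lo_i = z_lo + margin
    z_hi_i = z_hi - margin

    arc = _ArcMap(model, 0.5 * (z_lo + z_hi))
    band = min(0.45 * arc.total, 8 * h_max)
    report = RemeshReport()
    tris = _tube_triangulate(pts, model, arc, band)
    retriangulate_tol = 0.1
    last_pts = pts.copy()
    for it in range(max_iter):
        edges = _unique_edges(tris)
        disp = _spring_step(pts, edges, h_func, fscale, dt, movable)
        pts = pts + disp
        # project back to the surface, clamping the band
        pts[movable] = model.project_radial(
            np.column_stack(
                [
                    pts[movable, :2],
                    np.clip(pts[movable, 2], z_lo_i[movable], z_hi_i[movable]),
                ]
            )
        )
        if not np.isfinite(pts).all():
            raise RemeshNoConvergeError(
                f"node positions diverged at iteration {it}; log={report.movement_log[-10:]}"
            )
        move = float(np.linalg.norm(disp[movable], axis=1).max()) if movable.any() else 0.0
        report.movement_log.append(move)
        report.iterations = it + 1
        if move < ptol * h_ref:
            report.converged = True
            break
        drift = np.linalg.norm(pts - last_pts, axis=1).max()
        if drift > retriangulate_tol * h_min:
            tris = _tube_triangulate(pts, model, arc, band)
            last_pts = pts.copy()
    report.max_movement = report.movement_log[-1] if report.movement_log else 0.0
    if strict and not report.converged:
        raise RemeshNoConvergeError(
            f"no equilibrium after {max_iter} iterations "
            f"(last movement {report.max_movement:.3g}); log tail={report.movement_log[-10:]}"
        )
    tris = _tube_triangulate(pts, model, arc, band)
    report.n_nodes = len(pts)
    report.n_triangles = len(tris)
    return pts, tris, ~movable, report


# ----------------------------------------------------------------------
# convex closed surfaces
# ----------------------------------------------------------------------

def remesh_convex(
    project,
    h_func,
    seed_points: np.ndarray,
    *,
    fscale: float = 1.2,
    dt: float = 0.2,
    ptol: float = 1e-3,
    max_iter: int = 300,
):
    """Remesh a closed convex surface; connectivity is the convex hull.

    ``project(points)`` must map arbitrary points onto the surface (for a
    sphere: radial normalization).  Returns ``(points, triangles, report)``.
    """
    pts = project(np.asarray(seed_points, dtype=float))
    movable = np.ones(len(pts), dtype=bool)
    h_ref = float(np.max(np.asarray(h_func(pts))))
    report = RemeshReport()
    tris = ConvexHull(pts).simplices
    for it in range(max_iter):
        edges = _unique_edges(tris)
        disp = _spring_step(pts, edges, h_func, fscale, dt, movable)
        pts = project(pts + disp)
        if not np.isfinite(pts).all():
            raise RemeshNoConvergeError(f"diverged at iteration {it}")
        move = float(np.linalg.norm(disp, axis=1).max())
        report.movement_log.append(move)
        report.iterations = it + 1
        if move < ptol * h_ref:
            report.converged = True
            break
        tris = ConvexHull(pts).simplices
    tris = ConvexHull(pts).simplices
    report.max_movement = report.movement_log[-1] if report.movement_log else 0.0
    report.n_nodes = len(pts)
    report.n_triangles = len(tris)
    return pts, tris, report


def fibonacci_sphere(n: int, radius: float = 1.0) -> np.ndarray:
    """Quasi-uniform points on a sphere (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return radius * np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )
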