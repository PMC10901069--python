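"""Shared fixtures: analytic boundary models and a reusable electrode mesh.

The heavier objects (the 32-electrode cylinder FEM mesh and its
sensitivity matrix) are session-scoped so the forward-model, imaging and
acceptance tests share one build.
"""

from __future__ import annotations

import numpy as np
import pytest

from scan2fem import ElectrodeSet, MeshConfig, PhantomSpec, make_scan
from scan2fem.belt_mesh import build_fem_mesh, remesh_surface
from scan2fem.eit_imaging import CemSystem, EitProtocol, jacobian
from scan2fem.surface_fit import SurfaceFitModel


def cylinder_model(radius: float = 100.0, z_range=(-50.0, 50.0)) -> SurfaceFitModel:
    """Analytic circular-cylinder boundary model (exact constant mode)."""
    centers = np.linspace(z_range[0], z_range[1], 6)
    width = 1.5 * (z_range[1] - z_range[0]) / 5
    coeffs = np.zeros((25, 7))
    coeffs[0, 0] = radius
    return SurfaceFitModel(12, centers, width, coeffs, tuple(z_range))


def ring_electrodes(radius: float = 100.0, n: int = 32, z: float = 0.0) -> ElectrodeSet:
    th = (np.arange(n) + 0.5) / n * 2 * np.pi
    pts = np.column_stack([radius * np.cos(th), radius * np.sin(th), np.full(n, z)])
    return ElectrodeSet(pts, np.arange(1, n + 1), frozenset(), n)


def barrel_model(radius: float = 100.0, bulge: float = 3.0) -> SurfaceFitModel:
    """Mildly barreled tube: realistic non-developable belt-band geometry.

    A perfect cylinder is flat along z, which is a degenerate corner case
    for Delaunay-based volume meshing (and unlike any real thorax); the
    barrel adds gentle z-curvature everywhere.
    """
    import numpy as _np

    from scan2fem.scan_io import ColoredSurface
    from scan2fem.surface_fit import fit_surface

    th = _np.linspace(0, 2 * _np.pi, 480, endpoint=False)
    zz = _np.linspace(-50.0, 50.0, 48)
    tg, zg = _np.meshgrid(th, zz, indexing="ij")
    r = radius + bulge * _np.cos(_np.pi * zg / 140.0)
    verts = _np.column_stack(
        [(r * _np.cos(tg)).ravel(), (r * _np.sin(tg)).ravel(), zg.ravel()]
    )
    surf = ColoredSurface(verts, [[0, 1, 2]], _np.full((len(verts), 3), 255, _np.uint8))
    return fit_surface(surf)


@pytest.fixture(scope="session")
def cyl_model():
    return cylinder_model()


@pytest.fixture(scope="session")
def tube_model():
    return barrel_model()


@pytest.fixture(scope="session")
def electrode_mesh(tube_model):
    """Coarse 32-electrode belt-band FEM mesh for CEM tests."""
    cfg = MeshConfig(h_electrode=3.0, h_background=15.0, electrode_radius=5.0, seed=0)
    labeled = remesh_surface(tube_model, ring_electrodes(103.0), cfg, max_iter=60)
    return build_fem_mesh(labeled, cfg)


@pytest.fixture(scope="session")
def protocol():
    return EitProtocol()


@pytest.fixture(scope="session")
def homogeneous_system(electrode_mesh):
    return CemSystem(electrode_mesh, 1.0)


@pytest.fixture(scope="session")
def sensitivity(electrode_mesh, protocol, homogeneous_system):
    """(J, v0) at unit background conductivity."""
    return jacobian(electrode_mesh, 1.0, protocol, system=homogeneous_system)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free mid-size phantom scan plus truth (2 mm resolution)."""
    spec = PhantomSpec(perimeter=1000.0, axis_ratio=1.2, resolution=2.0, seed=11)
    return make_scan(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Scanner-like phantom: 2 mm vertex noise, 10-unit color noise."""
    spec = PhantomSpec(
        perimeter=1000.0, axis_ratio=1.2, resolution=2.0, seed=12,
        vertex_noise_sd=2.0, color_noise_sd=10.0,
    )
    return make_scan(spec)
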