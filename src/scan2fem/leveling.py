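"""Level the scan so the electrode-belt plane is horizontal and centered.

The belt electrodes define a best-fit plane (total least squares); the
scan is rigidly rotated so that plane's normal becomes +z and translated
so the electrode centroid sits at the origin.  The rotation is the
minimal one (no in-plane spin), so the subject's left/right axis is
preserved up to the scan's own orientation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DegeneratePlaneError


@dataclass
class LevelTransform:
    """Rigid map ``x -> rotation @ x + translation`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-6):
            raise ValueError("rotation determinant must be +1")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.rotation.T + self.translation
        return out if np.asarray(points).ndim > 1 else out[0]

    def compose(self, other: "LevelTransform") -> "LevelTransform":
        """Return transform equivalent to applying ``other`` then ``self``."""
        return LevelTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "LevelTransform":
        return LevelTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "rotation": self.rotation.tolist(),
                "translation": self.translation.tolist(),
                "meta": self.meta,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "LevelTransform":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = json.loads(text)
        return cls(np.array(data["rotation"]), np.array(data["translation"]),
                   data.get("meta", {}))

    @classmethod
    def identity(cls) -> "LevelTransform":
        return cls(np.eye(3), np.zeros(3))


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares plane through ``points``.

    Returns (centroid, unit normal); the normal is the smallest right
    singular vector of the centered point matrix, oriented into the +z
    hemisphere of the input frame.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 3:
        raise DegeneratePlaneError(f"plane fit needs >=3 points, got {len(pts)}")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear points: second singular value vanishes relative to the first
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise DegeneratePlaneError("points are collinear; plane is not defined")
    normal = vt[2]
    if normal[2] < 0 or (normal[2] == 0 and (normal[0] < 0 or (normal[0] == 0 and normal[1] < 0))):
        normal = -normal
    return centroid, normal


def _minimal_rotation_to_z(normal: np.ndarray) -> np.ndarray:
    """Rotation matrix taking ``normal`` to +z along the geodesic (no spin)."""
    n = normal / np.linalg.norm(normal)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(n, z)
    c = float(n @ z)
    s = np.linalg.norm(v)
    if s < 1e-15:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def apply_leveling(surface, electrodes):
    """Rigidly level a surface and its electrode set.

    Rotates so the electrodes' best-fit plane normal becomes +z and
    translates their centroid to the origin; the identical map is applied
    to the surface.  Returns ``(surface, electrodes, transform)``.

    The azimuth of electrode 1 after leveling is stored in
    ``transform.meta["electrode1_azimuth_rad"]`` (when present) so a
    reproducible in-plane origin is available without spinning the scan.
    """
    centroid, normal = fit_plane(electrodes.positions)
    rot = _minimal_rotation_to_z(normal)
    transform = LevelTransform(rot, -rot @ centroid)
    new_surface = type(surface)(
        transform.apply(surface.vertices), surface.faces.copy(), surface.colors.copy()
    )
    new_electrodes = electrodes.transformed(transform)
    if 1 in new_electrodes.labels:
        p = new_electrodes.position_of(1)
        transform.meta["electrode1_azimuth_rad"] = float(np.arctan2(p[1], p[0]))
    return new_surface, new_electrodes, transform
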