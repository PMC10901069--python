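"""Read, write and crop colored surface triangulations (PLY scans).

A smartphone depth-sensor scan arrives as a Stanford PLY file holding a
surface triangulation with one RGB color per vertex.  This module loads
such files into :class:`ColoredSurface`, crops them to the belt region,
and writes them back out losslessly enough for downstream geometry
(coordinates to better than 1e-4 mm, colors exactly).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .errors import EmptyCropError, NoColorError, PlyParseError

log = logging.getLogger(__name__)

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class ColoredSurface:
    """Triangulated surface with per-vertex RGB color.

    Attributes
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array of 0-based vertex indices
    colors : (n, 3) uint8 array, RGB in [0, 255]
    """

    vertices: np.ndarray
    faces: np.ndarray
    colors: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        self.colors = np.asarray(self.colors, dtype=np.uint8).reshape(-1, 3)
        if len(self.colors) != len(self.vertices):
            raise ValueError("colors length must equal vertex count")
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index exceeds vertex count")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        a, b, c = (v[self.faces[:, i]] for i in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def remove_degenerate_faces(self, min_area: float = 1e-10) -> "ColoredSurface":
        """Return a copy with zero-area triangles removed."""
        keep = self.face_areas() > min_area
        return ColoredSurface(self.vertices, self.faces[keep], self.colors)

    def to_trimesh(self) -> trimesh.Trimesh:
        rgba = np.column_stack([self.colors, np.full(len(self.colors), 255, np.uint8)])
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, vertex_colors=rgba, process=False
        )


@dataclass
class CropRegion:
    """Region of interest: a polygon in a projected view plus optional z-slab.

    ``polygon`` has at least 3 points (mm) in the plane perpendicular to
    ``view_axis``; ``z_bounds`` optionally restricts height regardless of
    the projection.  Either constraint may be used alone: a polygon that
    encloses everything combined with ``z_bounds`` gives a pure z-slab crop.
    """

    polygon: np.ndarray | None = None
    view_axis: str = "z"
    z_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.view_axis not in _AXES:
            raise ValueError(f"view_axis must be one of {sorted(_AXES)}")
        if self.polygon is not None:
            self.polygon = np.asarray(self.polygon, dtype=float).reshape(-1, 2)
            if len(self.polygon) < 3:
                raise ValueError("polygon needs at least 3 points")
            if not _polygon_is_simple(self.polygon):
                raise ValueError("polygon is self-intersecting")
        if self.z_bounds is not None:
            lo, hi = self.z_bounds
            if not lo < hi:
                raise ValueError("z_bounds lower must be < upper")
        if self.polygon is None and self.z_bounds is None:
            raise ValueError("crop region needs a polygon or z_bounds")


def _polygon_is_simple(poly: np.ndarray) -> bool:
    """O(n^2) check that no two non-adjacent edges intersect."""
    n = len(poly)
    segs = [(poly[i], poly[(i + 1) % n]) for i in range(n)]

    def _ccw(a, b, c):
        return (c[1] - a[1]) * (b[0] - a[0]) - (b[1] - a[1]) * (c[0] - a[0])

    for i in range(n):
        for j in range(i + 1, n):
            if abs(i - j) in (0, 1) or (i == 0 and j == n - 1):
                continue
            a, b = segs[i]
            c, d = segs[j]
            if (_ccw(a, b, c) * _ccw(a, b, d) < 0) and (_ccw(c, d, a) * _ccw(c, d, b) < 0):
                return False
    return True


def _points_in_polygon(pts: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Vectorized even-odd rule point-in-polygon test."""
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    n = len(poly)
    j = n - 1
    for i in range(n):
        xi, yi = poly[i]
        xj, yj = poly[j]
        denom = yj - yi
        crosses = ((yi > y) != (yj > y)) & (
            x < (xj - xi) * (y - yi) / (denom if denom != 0 else 1.0) + xi
        )
        inside ^= crosses
        j = i
    return inside


def _parse_ply_header(path: Path) -> dict:
    """Validate the PLY header without decoding the body.

    Returns format and vertex-property info; raises on dialects the
    pipeline does not support.
    """
    try:
        with open(path, "rb") as fh:
            magic = fh.readline().strip()
            if magic != b"ply":
                raise PlyParseError(f"{path}: not a PLY file (bad magic {magic!r})")
            fmt = None
            props: list[str] = []
            element = None
            for _ in range(1000):
                line = fh.readline()
                if not line:
                    raise PlyParseError(f"{path}: header truncated")
                tokens = line.decode("ascii", "replace").split()
                if not tokens:
                    continue
                if tokens[0] == "format":
                    fmt = tokens[1]
                elif tokens[0] == "element":
                    element = tokens[1]
                elif tokens[0] == "property" and element == "vertex":
                    props.append(tokens[-1])
                elif tokens[0] == "end_header":
                    break
            else:
                raise PlyParseError(f"{path}: header too long")
    except OSError as exc:
        raise PlyParseError(f"{path}: {exc}") from exc
    if fmt == "binary_big_endian":
        raise PlyParseError(
            f"{path}: binary_big_endian PLY is not supported "
            "(scanner output is ascii or binary_little_endian)"
        )
    if fmt not in ("ascii", "binary_little_endian"):
        raise PlyParseError(f"{path}: unknown PLY format {fmt!r}")
    missing = {"red", "green", "blue"} - set(props)
    if missing:
        raise NoColorError(
            f"{path}: vertex color properties missing ({', '.join(sorted(missing))})"
        )
    return {"format": fmt, "properties": props}


def read_scan(path: str | Path) -> ColoredSurface:
    """Load a colored PLY scan, converting meters to mm when needed.

    The scanner app writes mm, but some PLY exporters use meters; a
    bounding-box diagonal under 10 units is taken to mean meters and the
    coordinates are scaled by 1000.
    """
    path = Path(path)
    if not path.exists():
        raise PlyParseError(f"{path}: file not found")
    _parse_ply_header(path)
    try:
        mesh = trimesh.load(path, file_type="ply", process=False)
    except Exception as exc:  # trimesh raises assorted types on truncation
        raise PlyParseError(f"{path}: failed to parse ({exc})") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.vertices) == 0:
        raise PlyParseError(f"{path}: no triangulated vertex data")
    vertices = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=np.int64)
    try:
        colors = np.asarray(mesh.visual.vertex_colors)[:, :3].astype(np.uint8)
    except Exception as exc:
        raise NoColorError(f"{path}: vertex colors unreadable") from exc
    diag = np.linalg.norm(vertices.max(axis=0) - vertices.min(axis=0))
    if diag < 10.0:
        log.info("bounding-box diagonal %.3g < 10: interpreting units as meters", diag)
        vertices = vertices * 1000.0
    surf = ColoredSurface(vertices, faces, colors)
    return surf.remove_degenerate_faces()


def write_scan(surface: ColoredSurface, path: str | Path, ascii: bool = False) -> Path:
    """Write a colored surface as PLY (binary little-endian by default)."""
    path = Path(path)
    mesh = surface.to_trimesh()
    encoding = "ascii" if ascii else "binary"
    try:
        mesh.export(path, file_type="ply", encoding=encoding)
    except OSError as exc:
        raise PlyParseError(f"{path}: cannot write ({exc})") from exc
    return path


def _largest_component(n_vertices: int, faces: np.ndarray) -> np.ndarray:
    """Boolean mask of vertices in the largest face-connected component."""
    if len(faces) == 0:
        return np.zeros(n_vertices, dtype=bool)
    i = np.concatenate([faces[:, 0], faces[:, 1], faces[:, 2]])
    j = np.concatenate([faces[:, 1], faces[:, 2], faces[:, 0]])
    adj = coo_matrix((np.ones(len(i)), (i, j)), shape=(n_vertices, n_vertices))
    n_comp, labels = connected_components(adj, directed=False)
    used = np.zeros(n_vertices, dtype=bool)
    used[faces.ravel()] = True
    counts = np.bincount(labels[used], minlength=n_comp)
    return used & (labels == np.argmax(counts))


def crop(surface: ColoredSurface, region: CropRegion) -> ColoredSurface:
    """Crop to the belt region of interest.

    Keeps vertices whose projection falls inside the polygon (if given)
    and whose z lies within ``z_bounds`` (if given), drops faces touching
    removed vertices, then keeps only the largest connected component and
    reindexes.
    """
    keep = np.ones(surface.n_vertices, dtype=bool)
    if region.polygon is not None:
        ax = _AXES[region.view_axis]
        plane = [a for a in range(3) if a != ax]
        proj = surface.vertices[:, plane]
        keep &= _points_in_polygon(proj, region.polygon)
    if region.z_bounds is not None:
        lo, hi = region.z_bounds
        z = surface.vertices[:, 2]
        keep &= (z >= lo) & (z <= hi)
    if not keep.any():
        raise EmptyCropError("crop region retained no vertices")
    face_keep = keep[surface.faces].all(axis=1)
    faces = surface.faces[face_keep]
    if len(faces) == 0:
        raise EmptyCropError("crop region retained no faces")
    comp = _largest_component(surface.n_vertices, faces)
    faces = faces[comp[faces].all(axis=1)]
    new_index = -np.ones(surface.n_vertices, dtype=np.int64)
    new_index[comp] = np.arange(comp.sum())
    return ColoredSurface(
        surface.vertices[comp], new_index[faces], surface.colors[comp]
    ).remove_degenerate_faces()
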