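"""Exact nearest point-to-triangulation queries.

Candidate triangles are pre-selected with a k-d tree over triangle
centroids, then the exact closest point on each candidate triangle is
computed (region classification on the barycentric plane, the standard
closest-point-on-triangle construction).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def closest_point_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest points to ``p`` (3,) on each triangle in ``tri`` (k, 3, 3)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(a)
    done = np.zeros(len(tri), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)  # vertex a
    out[m] = a[m]
    done |= m

    m = ~done & (d3 >= 0) & (d4 <= d3)  # vertex b
    out[m] = b[m]
    done |= m

    m = ~done & (d6 >= 0) & (d5 <= d6)  # vertex c
    out[m] = c[m]
    done |= m

    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge ab
    t = np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 != 0, d1 - d3, 1.0), 0.0)
    out[m] = a[m] + t[m, None] * ab[m]
    done |= m

    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge ac
    t = np.where(d2 - d6 != 0, d2 / np.where(d2 - d6 != 0, d2 - d6, 1.0), 0.0)
    out[m] = a[m] + t[m, None] * ac[m]
    done |= m

    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge bc
    denom = (d4 - d3) + (d5 - d6)
    t = np.where(denom != 0, (d4 - d3) / np.where(denom != 0, denom, 1.0), 0.0)
    out[m] = b[m] + t[m, None] * (c[m] - b[m])
    done |= m

    m = ~done  # interior
    denom = np.where(va + vb + vc != 0, va + vb + vc, 1.0)
    v = vb / denom
    w = vc / denom
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


class TriangleNearest:
    """Repeated nearest-surface queries against one triangulation."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray, k: int = 48):
        self.tri = np.asarray(vertices, dtype=float)[np.asarray(faces, dtype=np.int64)]
        self.k = min(k, len(self.tri))
        self.tree = cKDTree(self.tri.mean(axis=1))
        # largest circumscribing extent, to widen candidate search safely
        self.max_half_diam = 0.5 * float(
            np.max(np.linalg.norm(self.tri - self.tri.mean(axis=1, keepdims=True), axis=2))
        ) * 2.0

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Returns (closest surface points, distances)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d_cent, idx = self.tree.query(pts, k=self.k)
        idx = np.atleast_2d(idx)
        closest = np.empty_like(pts)
        dist = np.empty(len(pts))
        for i, p in enumerate(pts):
            cand = self.tri[idx[i]]
            cp = closest_point_on_triangles(p, cand)
            dd = np.linalg.norm(cp - p, axis=1)
            j = int(np.argmin(dd))
            closest[i] = cp[j]
            dist[i] = dd[j]
        return closest, dist


def nearest_on_surface(vertices, faces, points):
    """One-shot convenience wrapper around :class:`TriangleNearest`."""
    return TriangleNearest(vertices, faces).query(points)
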