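"""Detect colored belt fiducials and number electrodes 1-32.

The 32-electrode belt carries a sticker opposite every electrode; six
stickers have known colors (cyan, orange, red, yellow, green, pink) at
electrodes 7, 12, 17, 22, 27 and 32, the rest are white.  Detecting the
colored anchors fixes the belt's winding direction and lets the white
stickers be numbered by angular interpolation, including inference of
electrodes hidden by the belt buckle.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .errors import AnchorOrderError, MissingAnchorWarning, OverfullSegmentError
from .scan_io import ColoredSurface

#: Belt color scheme: anchor sticker color -> electrode number.
ANCHOR_NUMBERS = {"cyan": 7, "orange": 12, "red": 17, "yellow": 22, "green": 27, "pink": 32}

#: Nominal sticker RGB values.
ANCHOR_RGB = {
    "cyan": (0, 255, 255),
    "orange": (255, 128, 0),
    "red": (255, 0, 0),
    "yellow": (255, 255, 0),
    "green": (0, 200, 0),
    "pink": (255, 105, 180),
    "white": (255, 255, 255),
}


@dataclass
class ColorPalette:
    """Reference sticker colors and the anchor numbering they encode."""

    anchor_map: dict = field(default_factory=lambda: dict(ANCHOR_NUMBERS))
    reference_rgb: dict = field(default_factory=lambda: dict(ANCHOR_RGB))
    tolerance: float = 60.0

    def __post_init__(self) -> None:
        if self.anchor_map != ANCHOR_NUMBERS:
            raise ValueError("anchor_map must be the standard belt scheme "
                             f"{ANCHOR_NUMBERS}")
        missing = set(self.anchor_map) - set(self.reference_rgb)
        if missing:
            raise ValueError(f"reference RGB missing for {sorted(missing)}")


@dataclass
class ElectrodeSet:
    """Labeled 3D electrode centers with occlusion bookkeeping.

    ``positions[i]`` belongs to electrode number ``labels[i]``;
    ``occluded`` holds the numbers that could not be located, so
    ``len(positions) + len(occluded) == 32``.
    """

    positions: np.ndarray
    labels: np.ndarray
    occluded: frozenset = frozenset()
    n_total: int = 32

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.labels = np.asarray(self.labels, dtype=int).reshape(-1)
        self.occluded = frozenset(int(x) for x in self.occluded)
        if len(self.labels) != len(self.positions):
            raise ValueError("labels and positions length mismatch")
        if len(set(self.labels.tolist())) != len(self.labels):
            raise ValueError("electrode labels must be unique")
        if len(self.positions) + len(self.occluded) != self.n_total:
            raise ValueError(
                f"|positions| + |occluded| must equal {self.n_total} "
                f"(got {len(self.positions)} + {len(self.occluded)})"
            )
        order = np.argsort(self.labels)
        self.labels = self.labels[order]
        self.positions = self.positions[order]

    def position_of(self, label: int) -> np.ndarray:
        idx = np.flatnonzero(self.labels == label)
        if len(idx) == 0:
            raise KeyError(f"electrode {label} not present")
        return self.positions[idx[0]]

    def transformed(self, transform) -> "ElectrodeSet":
        return ElectrodeSet(
            transform.apply(self.positions), self.labels.copy(), self.occluded, self.n_total
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["label", "x", "y", "z"])
            for lab, pos in zip(self.labels, self.positions):
                writer.writerow([int(lab), *(f"{c:.6f}" for c in pos)])
        return path

    @classmethod
    def from_csv(cls, path: str | Path, n_total: int = 32) -> "ElectrodeSet":
        labels, positions = [], []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                labels.append(int(row["label"]))
                positions.append([float(row["x"]), float(row["y"]), float(row["z"])])
        occluded = frozenset(range(1, n_total + 1)) - frozenset(labels)
        return cls(np.array(positions), np.array(labels), occluded, n_total)


def _color_clusters(
    surface: ColoredSurface, mask: np.ndarray, min_cluster: int
) -> list[tuple[np.ndarray, int]]:
    """Connected clusters (over mesh edges) of masked vertices -> centroids."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    sub = -np.ones(surface.n_vertices, dtype=np.int64)
    sub[idx] = np.arange(len(idx))
    fmask = mask[surface.faces].sum(axis=1) >= 2
    edges = []
    for a, b in ((0, 1), (1, 2), (2, 0)):
        fa, fb = surface.faces[fmask, a], surface.faces[fmask, b]
        ok = mask[fa] & mask[fb]
        edges.append(np.column_stack([sub[fa[ok]], sub[fb[ok]]]))
    edges = np.vstack(edges) if edges else np.empty((0, 2), dtype=np.int64)
    adj = coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(len(idx), len(idx))
    )
    _, labels = connected_components(adj, directed=False)
    out = []
    for comp in np.unique(labels):
        members = idx[labels == comp]
        if len(members) >= min_cluster:
            out.append((surface.vertices[members].mean(axis=0), len(members)))
    out.sort(key=lambda t: -t[1])
    return out


def _project_to_surface(points: np.ndarray, surface: ColoredSurface) -> np.ndarray:
    from ._nearest import nearest_on_surface

    closest, _ = nearest_on_surface(surface.vertices, surface.faces, points)
    return closest


def detect_fiducials(
    surface: ColoredSurface,
    palette: ColorPalette | None = None,
    min_cluster: int = 5,
    project: bool = True,
) -> dict[str, list[np.ndarray]]:
    """Find sticker candidates per color class (6 anchors + white).

    Vertices within the palette's RGB tolerance of a reference color are
    clustered over mesh connectivity; clusters below ``min_cluster``
    vertices are discarded and each surviving cluster is reduced to its
    centroid projected back onto the surface.  Candidates are returned
    largest-cluster first.  A missing anchor color raises a
    ``MissingAnchorWarning`` (not fatal: manual points may be supplied).
    """
    palette = palette or ColorPalette()
    rgb = surface.colors.astype(float)
    result: dict[str, list[np.ndarray]] = {}
    # nearest-reference-color assignment, gated by tolerance, so a vertex
    # near two references (e.g. yellow vs white) goes to the closer one
    names = list(palette.reference_rgb)
    refs = np.array([palette.reference_rgb[n] for n in names], dtype=float)
    dists = np.linalg.norm(rgb[:, None, :] - refs[None, :, :], axis=2)
    nearest = np.argmin(dists, axis=1)
    within = dists[np.arange(len(rgb)), nearest] <= palette.tolerance
    for k, name in enumerate(names):
        mask = within & (nearest == k)
        clusters = _color_clusters(surface, mask, min_cluster)
        pts = [c for c, _ in clusters]
        if pts and project:
            pts = list(_project_to_surface(np.array(pts), surface))
        result[name] = pts
        if name in palette.anchor_map and not pts:
            warnings.warn(
                f"missing-anchor: no cluster found for color '{name}'",
                MissingAnchorWarning,
                stacklevel=2,
            )
    return result


def _cyclic_direction(anchor_numbers: list[int]) -> int:
    """+1 if the sequence is a rotation of the increasing anchor cycle,
    -1 if of the decreasing one, else 0."""
    def descents(seq):
        return sum(1 for a, b in zip(seq, seq[1:] + seq[:1]) if b < a)

    if descents(anchor_numbers) == 1:
        return 1
    if descents(anchor_numbers[::-1]) == 1:
        return -1
    return 0


def _fill_segment(
    n_lo: int, n_hi: int, gap_angles: np.ndarray, seg_span: float
) -> list[int]:
    """Choose labels for whites between anchors ``n_lo`` and ``n_hi``.

    ``gap_angles`` are the whites' angular offsets from the low anchor
    (increasing, within ``seg_span``).  Among all order-preserving
    assignments of the whites to the open slots, picks the one minimizing
    the variance of per-label-step angular spacing — i.e. missing
    electrodes are placed where the angular gaps are widest.
    """
    slots = (n_hi - n_lo - 1) % 32
    w = len(gap_angles)
    if w > slots:
        raise OverfullSegmentError(
            f"{w} points between anchors {n_lo} and {n_hi} but only {slots} slots"
        )
    if w == 0:
        return []
    best, best_cost = None, np.inf
    for combo in combinations(range(1, slots + 1), w):
        knots_lab = [0, *combo, slots + 1]
        knots_ang = [0.0, *gap_angles, seg_span]
        spac = [
            (knots_ang[t + 1] - knots_ang[t]) / (knots_lab[t + 1] - knots_lab[t])
            for t in range(len(combo) + 1)
        ]
        cost = float(np.var(spac))
        if cost < best_cost - 1e-15:
            best_cost, best = cost, combo
    return [(n_lo + c - 1) % 32 + 1 for c in best]


def label_electrodes(
    anchors: dict[str, np.ndarray] | dict[int, np.ndarray],
    whites: list[np.ndarray] | np.ndarray,
    level_normal: np.ndarray = (0.0, 0.0, 1.0),
    n_total: int = 32,
) -> ElectrodeSet:
    """Assign electrode numbers 1-32 from anchor colors and white stickers.

    Points are sorted by azimuth about their centroid in the plane normal
    to ``level_normal``; the rotation direction is the one along which the
    anchor numbers increase cyclically (7→12→17→22→27→32).  Whites between
    consecutive anchors get the interpolated numbers; when a segment is
    short (occluded stickers) the missing numbers are inferred by the
    widest-angular-gap rule.  Labels 1-6 live between anchors 32 and 7.
    """
    anchor_pts = {}
    for key, pt in anchors.items():
        num = ANCHOR_NUMBERS[key] if isinstance(key, str) else int(key)
        if num not in ANCHOR_NUMBERS.values():
            raise ValueError(f"{num} is not an anchor electrode number")
        anchor_pts[num] = np.asarray(pt, dtype=float)
    if len(anchor_pts) < 2:
        raise AnchorOrderError("need at least 2 anchor electrodes to fix direction")
    whites = [np.asarray(p, dtype=float) for p in np.atleast_2d(np.asarray(whites))] \
        if len(np.atleast_1d(whites)) else []
    if len(anchor_pts) + len(whites) > n_total:
        raise OverfullSegmentError("more candidate points than electrode slots")

    pts = np.array([*anchor_pts.values(), *whites])
    nums = [*anchor_pts.keys()] + [None] * len(whites)
    center = pts.mean(axis=0)
    n = np.asarray(level_normal, dtype=float)
    n = n / np.linalg.norm(n)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ n) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    rel = pts - center
    theta = np.arctan2(rel @ e2, rel @ e1)

    order = np.argsort(theta)
    seq_nums = [nums[i] for i in order]
    anchor_seq = [x for x in seq_nums if x is not None]
    direction = _cyclic_direction(anchor_seq)
    if direction == 0:
        raise AnchorOrderError(
            f"anchor angular order {anchor_seq} fits no belt winding direction"
        )
    if direction == -1:
        order = order[::-1]
        theta = -theta
        seq_nums = [nums[i] for i in order]

    sorted_theta = theta[order]
    anchor_pos = [k for k, x in enumerate(seq_nums) if x is not None]

    labels = {}
    for a_idx in range(len(anchor_pos)):
        i = anchor_pos[a_idx]
        j = anchor_pos[(a_idx + 1) % len(anchor_pos)]
        n_lo, n_hi = seq_nums[i], seq_nums[j]
        labels[n_lo] = pts[order[i]]
        between = (
            list(range(i + 1, j)) if j > i
            else list(range(i + 1, len(seq_nums))) + list(range(0, j))
        )
        seg_span = (sorted_theta[j] - sorted_theta[i]) % (2 * np.pi)
        if seg_span == 0:
            seg_span = 2 * np.pi
        gaps = np.array([(sorted_theta[k] - sorted_theta[i]) % (2 * np.pi) for k in between])
        for k, lab in zip(between, _fill_segment(n_lo, n_hi, gaps, seg_span)):
            labels[lab] = pts[order[k]]

    all_labels = sorted(labels)
    occluded = frozenset(range(1, n_total + 1)) - frozenset(all_labels)
    return ElectrodeSet(
        np.array([labels[k] for k in all_labels]), np.array(all_labels), occluded, n_total
    )


def identify_electrodes(
    surface: ColoredSurface,
    palette: ColorPalette | None = None,
    level_normal: np.ndarray = (0.0, 0.0, 1.0),
    min_cluster: int = 5,
    manual_points: str | Path | None = None,
) -> ElectrodeSet:
    """Full fiducial pipeline: detect colors, pick anchors, number electrodes.

    ``manual_points`` (CSV ``label,x,y,z``, blank label for white) overrides
    automatic detection, mirroring an operator clicking the stickers.
    """
    if manual_points is not None:
        anchors, whites = read_manual_points(manual_points)
        return label_electrodes(anchors, whites, level_normal)
    palette = palette or ColorPalette()
    candidates = detect_fiducials(surface, palette, min_cluster)
    anchors = {
        name: pts[0] for name, pts in candidates.items()
        if name in palette.anchor_map and pts
    }
    whites = candidates.get("white", [])
    return label_electrodes(anchors, whites, level_normal)


def read_manual_points(path: str | Path):
    """Read operator-picked fiducials: CSV ``label,x,y,z`` (blank = white)."""
    anchors, whites = {}, []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            p = np.array([float(row["x"]), float(row["y"]), float(row["z"])])
            lab = (row.get("label") or "").strip()
            if lab:
                anchors[int(lab)] = p
            else:
                whites.append(p)
    return anchors, whites
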