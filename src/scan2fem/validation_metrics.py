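"""Precision/accuracy metrics for scans and tracked ground truth.

Precision is scan-to-scan reproducibility of the labeled electrode
positions; accuracy is agreement with an independently tracked reference
(infrared pointer).  Both are RMS (and max) over the electrode labels
common to the two sets, after an optional label-correspondence rigid
alignment (Kabsch/orthogonal Procrustes without scaling) since the scans
live in arbitrary frames.  Surface accuracy uses unsigned nearest-point
distances from traced contours to the scan triangulation or the fit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np

from .electrode_id import ElectrodeSet
from .errors import InsufficientCorrespondenceError, Scan2FemError
from .leveling import LevelTransform
from .scan_io import ColoredSurface
from .surface_fit import SurfaceFitModel


@dataclass
class ComparisonReport:
    """Per-electrode distances between two labeled sets (mm)."""

    rms: float
    max: float
    per_electrode: dict
    n_pairs: int
    transform_used: LevelTransform

    def __post_init__(self) -> None:
        d2 = np.array([v**2 for v in self.per_electrode.values()])
        assert self.n_pairs == len(self.per_electrode)
        assert np.isclose(self.rms, np.sqrt(d2.mean()))


def rigid_align(source: ElectrodeSet, target: ElectrodeSet) -> LevelTransform:
    """Least-squares rigid map (no scaling) of source onto target.

    Closed-form orthogonal Procrustes over the common labels, with the
    reflection excluded (determinant forced to +1).
    """
    common = sorted(set(source.labels) & set(target.labels))
    if len(common) < 3:
        raise InsufficientCorrespondenceError(
            f"rigid alignment needs >=3 common labels, got {len(common)}"
        )
    A = np.array([source.position_of(l) for l in common])
    B = np.array([target.position_of(l) for l in common])
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (A - ca).T @ (B - cb)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return LevelTransform(R, cb - R @ ca)


def electrode_error(
    a: ElectrodeSet, b: ElectrodeSet, align: bool = True
) -> ComparisonReport:
    """RMS/max electrode position differences over common labels.

    Occluded electrodes are excluded pairwise (intersection of labels).
    """
    common = sorted(set(a.labels) & set(b.labels))
    if not common:
        raise Scan2FemError("no common electrode labels to compare")
    transform = rigid_align(a, b) if align else LevelTransform.identity()
    dists = {
        l: float(np.linalg.norm(transform.apply(a.position_of(l)) - b.position_of(l)))
        for l in common
    }
    vals = np.array(list(dists.values()))
    return ComparisonReport(
        rms=float(np.sqrt(np.mean(vals**2))),
        max=float(vals.max()),
        per_electrode=dists,
        n_pairs=len(common),
        transform_used=transform,
    )


def contour_to_surface(
    points: np.ndarray, surface: ColoredSurface | SurfaceFitModel
) -> dict:
    """Unsigned nearest distances from contour samples to a surface.

    For a triangulation, exact point-triangle distances; for a fitted
    boundary model, |signed distance| with nearest-point refinement.
    Returns distances plus mean/SD/RMS/max summary (mm).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) == 0:
        raise Scan2FemError("empty contour")
    if isinstance(surface, SurfaceFitModel):
        d = np.abs(surface.signed_distance(pts, exact=True))
    else:
        from ._nearest import nearest_on_surface

        _, d = nearest_on_surface(surface.vertices, surface.faces, pts)
    d = np.asarray(d, dtype=float)
    return {
        "distances": d,
        "mean": float(d.mean()),
        "sd": float(d.std(ddof=1)) if len(d) > 1 else 0.0,
        "rms": float(np.sqrt(np.mean(d**2))),
        "max": float(d.max()),
        "n": len(d),
    }


def precision_report(scans: list[ElectrodeSet], align: bool = True) -> dict:
    """All-pairs electrode comparisons across repeated scans.

    k scans give C(k, 2) comparisons (three successive scans → exactly 3);
    returns the pairwise reports and the average ± SD of their RMS and
    max values.
    """
    if len(scans) < 2:
        raise Scan2FemError("precision needs at least 2 scans")
    pairs = list(combinations(range(len(scans)), 2))
    reports = {(i, j): electrode_error(scans[i], scans[j], align) for i, j in pairs}
    rms = np.array([r.rms for r in reports.values()])
    mx = np.array([r.max for r in reports.values()])
    return {
        "pairs": reports,
        "n_comparisons": len(pairs),
        "rms_mean": float(rms.mean()),
        "rms_sd": float(rms.std(ddof=1)) if len(rms) > 1 else 0.0,
        "max_mean": float(mx.mean()),
        "max_sd": float(mx.std(ddof=1)) if len(mx) > 1 else 0.0,
    }


def read_contour_csv(path: str | Path) -> np.ndarray:
    """Ordered contour samples from CSV ``x,y,z``."""
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rows.append([float(row["x"]), float(row["y"]), float(row["z"])])
    return np.array(rows)


def write_contour_csv(points: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y", "z"])
        for p in np.atleast_2d(points):
            writer.writerow([f"{c:.6f}" for c in p])
    return path
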