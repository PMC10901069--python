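"""Fiducial color detection and electrode numbering, incl. occlusion."""

import itertools
import warnings

import numpy as np
import pytest

from scan2fem import ColoredSurface, detect_fiducials, label_electrodes
from scan2fem.electrode_id import ANCHOR_NUMBERS, ColorPalette, ElectrodeSet
from scan2fem.errors import AnchorOrderError, MissingAnchorWarning, OverfullSegmentError

ANCHORS = sorted(ANCHOR_NUMBERS.values())


def circle_points(n=32, radius=100.0, z=0.0):
    th = np.arange(n) / n * 2 * np.pi
    return np.column_stack([radius * np.cos(th), radius * np.sin(th), np.full(n, z)])


def split_anchor_white(pts, missing=()):
    anchors = {num: pts[num - 1] for num in ANCHORS}
    whites = [
        pts[i] for i in range(len(pts))
        if (i + 1) not in ANCHORS and (i + 1) not in missing
    ]
    return anchors, whites


def oracle_assignment(anchors, whites, n_total=32):
    """Independent brute force: enumerate every cyclically consistent
    labeling and pick the one with minimal global variance of per-label
    angular spacing."""
    pts = np.array([*anchors.values(), *whites])
    nums = [*anchors.keys()] + [None] * len(whites)
    center = pts.mean(axis=0)
    theta = np.arctan2(pts[:, 1] - center[1], pts[:, 0] - center[0])
    order = np.argsort(theta)
    seq = [(theta[i], nums[i], i) for i in order]
    anchor_pos = [k for k, (_, n, _) in enumerate(seq) if n is not None]

    segments = []
    for a in range(len(anchor_pos)):
        i, j = anchor_pos[a], anchor_pos[(a + 1) % len(anchor_pos)]
        n_lo, n_hi = seq[i][1], seq[j][1]
        between = (
            list(range(i + 1, j)) if j > i
            else list(range(i + 1, len(seq))) + list(range(j))
        )
        slots = (n_hi - n_lo - 1) % n_total
        segments.append((i, j, n_lo, slots, between))

    per_seg_choices = []
    for _, _, n_lo, slots, between in segments:
        opts = list(itertools.combinations(range(1, slots + 1), len(between)))
        per_seg_choices.append(opts)

    best, best_cost = None, np.inf
    for combo in itertools.product(*per_seg_choices):
        labels = {}
        spacings = []
        for (i, j, n_lo, slots, between), offsets in zip(segments, combo):
            th_i = seq[i][0]
            th_j = seq[j][0]
            span = (th_j - th_i) % (2 * np.pi) or 2 * np.pi
            knots_lab = [0, *offsets, slots + 1]
            knots_th = [0.0, *[(seq[k][0] - th_i) % (2 * np.pi) for k in between], span]
            for t in range(len(offsets) + 1):
                spacings.append(
                    (knots_th[t + 1] - knots_th[t]) / (knots_lab[t + 1] - knots_lab[t])
                )
            labels[n_lo] = seq[i][2]
            for k, off in zip(between, offsets):
                labels[(n_lo + off - 1) % n_total + 1] = seq[k][2]
        cost = float(np.var(spacings))
        if cost < best_cost - 1e-15:
            best_cost, best = cost, labels
    return {lab: pts[idx] for lab, idx in best.items()}


def test_symmetric_circle_labels_in_order():
    pts = circle_points()
    anchors, whites = split_anchor_white(pts)
    es = label_electrodes(anchors, whites)
    assert sorted(es.occluded) == []
    for lab in range(1, 33):
        assert np.allclose(es.position_of(lab), pts[lab - 1])


def test_occlusion_between_last_anchors():
    """Five consecutive whites removed between anchors 32 and 7."""
    pts = circle_points()
    anchors, whites = split_anchor_white(pts, missing={2, 3, 4, 5, 6})
    es = label_electrodes(anchors, whites)
    assert sorted(es.occluded) == [2, 3, 4, 5, 6]
    assert np.allclose(es.position_of(1), pts[0])


@pytest.mark.parametrize("seed", range(100))
def test_random_deletions_match_bruteforce_oracle(seed):
    """0-5 random white stickers deleted: spacing-variance assignment
    agrees with the independent global brute-force oracle."""
    rng = np.random.default_rng(seed)
    pts = circle_points()
    # jitter angles slightly so spacings are not exactly degenerate
    th = np.arange(32) / 32 * 2 * np.pi + rng.normal(0, 0.004, 32)
    pts = np.column_stack([100 * np.cos(th), 100 * np.sin(th), np.zeros(32)])
    white_labels = [l for l in range(1, 33) if l not in ANCHORS]
    k = rng.integers(0, 6)
    missing = set(rng.choice(white_labels, size=k, replace=False).tolist())
    anchors = {num: pts[num - 1] for num in ANCHORS}
    whites = [pts[l - 1] for l in white_labels if l not in missing]
    es = label_electrodes(anchors, whites)
    expected = oracle_assignment(anchors, whites)
    assert set(es.labels) == set(expected)
    for lab in es.labels:
        assert np.allclose(es.position_of(lab), expected[lab])


def test_rigid_transform_invariance():
    """Labels are unchanged under an arbitrary rigid transform."""
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(7)
    pts = circle_points()
    anchors, whites = split_anchor_white(pts, missing={9, 20})
    es0 = label_electrodes(anchors, whites)
    R = Rotation.random(random_state=3).as_matrix()
    t = rng.normal(0, 50, 3)
    anchors_r = {k: R @ v + t for k, v in anchors.items()}
    whites_r = [R @ w + t for w in whites]
    es1 = label_electrodes(anchors_r, whites_r, level_normal=R @ [0.0, 0.0, 1.0])
    assert np.array_equal(es0.labels, es1.labels)
    assert es0.occluded == es1.occluded


def test_reversed_winding_still_labels():
    pts = circle_points()
    pts_r = pts * [1.0, -1.0, 1.0]  # mirror flips the winding direction
    anchors, whites = split_anchor_white(pts)
    anchors_r = {k: v * [1.0, -1.0, 1.0] for k, v in anchors.items()}
    whites_r = [w * [1.0, -1.0, 1.0] for w in whites]
    es = label_electrodes(anchors_r, whites_r)
    for lab in range(1, 33):
        assert np.allclose(es.position_of(lab), pts_r[lab - 1])


def test_permuted_anchors_raise():
    pts = circle_points()
    anchors, whites = split_anchor_white(pts)
    # swap two anchor assignments -> no consistent winding
    anchors[7], anchors[22] = anchors[22], anchors[7]
    with pytest.raises(AnchorOrderError):
        label_electrodes(anchors, whites)


def test_overfull_segment_raises():
    pts = circle_points(n=32)
    anchors, whites = split_anchor_white(pts)
    # cram an extra point between anchors 27 and 32 (only 4 slots)
    extra = pts[28:32].mean(axis=0)
    with pytest.raises(OverfullSegmentError):
        label_electrodes(anchors, whites + [extra])


def test_detection_on_clean_phantom(clean_phantom):
    surf, truth = clean_phantom
    cands = detect_fiducials(surf)
    for name, num in ANCHOR_NUMBERS.items():
        assert len(cands[name]) == 1, f"anchor {name} not uniquely detected"
        d = np.linalg.norm(cands[name][0] - truth.electrode_centers[num - 1])
        assert d < 1.0, f"anchor {name} centroid {d:.2f} mm from truth"
    assert len(cands["white"]) == 26


def test_detection_with_color_noise():
    """RGB noise σ=10 alone leaves anchor centroids within 2 mm of truth."""
    from scan2fem import PhantomSpec, make_scan

    spec = PhantomSpec(
        perimeter=900.0, axis_ratio=1.2, resolution=2.0, seed=21, color_noise_sd=10.0
    )
    surf, truth = make_scan(spec)
    cands = detect_fiducials(surf)
    for name, num in ANCHOR_NUMBERS.items():
        assert len(cands[name]) >= 1
        d = np.linalg.norm(cands[name][0] - truth.electrode_centers[num - 1])
        assert d < 2.0


def test_all_white_surface_warns_six_times():
    verts = circle_points(n=200, radius=50.0)
    faces = [[i, (i + 1) % 200, (i + 2) % 200] for i in range(0, 196, 2)]
    surf = ColoredSurface(verts, faces, np.full((200, 3), 255, dtype=np.uint8))
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cands = detect_fiducials(surf, min_cluster=3)
    anchor_warnings = [w for w in caught if issubclass(w.category, MissingAnchorWarning)]
    assert len(anchor_warnings) == 6
    assert all(len(cands[name]) == 0 for name in ANCHOR_NUMBERS)


def test_electrode_set_invariants():
    with pytest.raises(ValueError):  # duplicate labels
        ElectrodeSet(np.zeros((2, 3)), [1, 1], frozenset(range(3, 33)))
    with pytest.raises(ValueError):  # count mismatch with occlusion
        ElectrodeSet(np.zeros((2, 3)), [1, 2], frozenset())
    with pytest.raises(ValueError):
        ColorPalette(anchor_map={"cyan": 1})


def test_electrode_set_csv_roundtrip(tmp_path):
    pts = circle_points()
    es = ElectrodeSet(pts[:30], np.arange(1, 31), frozenset({31, 32}))
    es.to_csv(tmp_path / "e.csv")
    back = ElectrodeSet.from_csv(tmp_path / "e.csv")
    assert np.array_equal(back.labels, es.labels)
    assert back.occluded == es.occluded
    assert np.abs(back.positions - es.positions).max() < 1e-5
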