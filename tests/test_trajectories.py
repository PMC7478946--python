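"""Conflict-metric geometry: worked examples, oracle agreement, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from choicetrace import (ScreenGeometry, Trajectory, TrajectoryError,
                         compute_auc, compute_xflips, preprocess,
                         signed_area_auc)
from choicetrace.simulate import make_path


def brute_force_auc(points, target):
    """Independent per-step angle loop (the oracle for the vectorized metric)."""
    angles = []
    for i in range(len(points) - 1):
        d = (points[i + 1][0] - points[i][0], points[i + 1][1] - points[i][1])
        t = (target[0] - points[i][0], target[1] - points[i][1])
        nd = (d[0] ** 2 + d[1] ** 2) ** 0.5
        nt = (t[0] ** 2 + t[1] ** 2) ** 0.5
        if nd == 0 or nt == 0:
            continue
        c = (d[0] * t[0] + d[1] * t[1]) / (nd * nt)
        angles.append(np.arccos(min(1.0, max(-1.0, c))))
    return float(np.mean(angles))


def brute_force_xflips(xs):
    signs = [np.sign(b - a) for a, b in zip(xs[:-1], xs[1:]) if b != a]
    return sum(1 for a, b in zip(signs[:-1], signs[1:]) if a != b)


@pytest.mark.parametrize("points,target,expected", [
    # straight at the target: zero deviation
    ([(0, 0), (1, 1), (2, 2)], (2, 2), 0.0),
    # first step orthogonal-ish: 45 deg then 0 -> pi/8
    ([(0, 0), (1, 0), (2, 2)], (2, 2), np.pi / 8),
    # first step points directly away -> (pi + 0)/2
    ([(0, 0), (0, -1), (0, 1)], (0, 1), np.pi / 2),
])
def test_auc_worked_examples(points, target, expected):
    traj = Trajectory(points=points, target=target)
    assert compute_auc(traj) == pytest.approx(expected, abs=1e-7)


def test_auc_degenerate_inputs():
    with pytest.raises(TrajectoryError):
        Trajectory(points=[(0, 0)], target=(1, 1))
    # every step zero-length -> metric undefined
    traj = Trajectory(points=[(1, 1), (1, 1), (1, 1)], target=(2, 2))
    with pytest.raises(TrajectoryError):
        compute_auc(traj)


@pytest.mark.parametrize("xs,expected", [
    ([0, 1, 2, 3], 0),        # monotone
    ([0, 2, 1, 3], 2),        # +,-,+
    ([0, 1, 1, 2], 0),        # zero increment carries the previous sign
    ([0, 1, 1, 0], 1),
    ([5], 0),
])
def test_xflips_examples(xs, expected):
    pts = [(x, 0.0) for x in xs] if len(xs) > 1 else [(xs[0], 0.0), (xs[0], 1.0)]
    traj = Trajectory(points=pts, target=(10.0, 0.0))
    assert compute_xflips(traj) == expected


def test_oracle_agreement_on_random_paths():
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        m = rng.integers(2, 30)
        pts = rng.normal(0, 100, (m, 2))
        target = rng.normal(0, 100, 2)
        traj = Trajectory(points=pts, target=target)
        assert compute_auc(traj) == pytest.approx(
            brute_force_auc(pts.tolist(), target.tolist()), abs=1e-12)
        assert compute_xflips(traj) == brute_force_xflips(pts[:, 0].tolist())


@settings(max_examples=60, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1), st.floats(0.1, 10.0),
       st.floats(-np.pi, np.pi), st.booleans())
def test_auc_rigid_transform_invariance(seed, scale, angle, reflect):
    """The angle metric depends only on angles: invariant under rotation,
    uniform scaling and reflection applied jointly to path and target."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(0, 10, (rng.integers(2, 12), 2))
    target = rng.normal(0, 10, 2)
    base = compute_auc(Trajectory(points=pts, target=target))
    R = np.array([[np.cos(angle), -np.sin(angle)],
                  [np.sin(angle), np.cos(angle)]])
    if reflect:
        R = R @ np.diag([1.0, -1.0])
    A = scale * R
    t2 = Trajectory(points=pts @ A.T, target=A @ target)
    assert compute_auc(t2) == pytest.approx(base, abs=1e-9)


@settings(max_examples=60, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_xflips_ignores_y(seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(0, 10, (rng.integers(2, 15), 2))
    traj = Trajectory(points=pts, target=(0.0, 0.0))
    pts2 = pts.copy()
    pts2[:, 1] = rng.normal(0, 100, len(pts))
    assert compute_xflips(Trajectory(points=pts2, target=(5.0, 5.0))) \
        == compute_xflips(traj)


def test_auc_zero_iff_steps_point_at_target():
    # along-the-ray path: each step a positive multiple of its to-target vector
    traj = Trajectory(points=[(0, 0), (1, 2), (2, 4), (3, 6)], target=(3, 6))
    assert compute_auc(traj) == pytest.approx(0.0, abs=1e-6)
    # any deviating step makes it strictly positive
    traj2 = Trajectory(points=[(0, 0), (1, 2.5), (3, 6)], target=(3, 6))
    assert compute_auc(traj2) > 1e-4


def test_signed_area_zero_for_straight_chord():
    traj = Trajectory(points=[(0, 0), (1, 1), (3, 3)], target=(3, 3))
    assert signed_area_auc(traj) == pytest.approx(0.0, abs=1e-12)


# -- preprocessing ---------------------------------------------------------

def test_preprocess_threshold_and_canonical_frame():
    geom = ScreenGeometry()
    # rise from the start box through the threshold to the right corner
    t = np.arange(0, 1000, 10.0)
    y = np.linspace(geom.start[1], geom.right_target[1], t.size)
    x = np.linspace(geom.start[0], geom.right_target[0], t.size)
    traj, timeout = preprocess(t, x, y, chose_left=False, geometry=geom)
    assert not timeout
    assert traj.points[0] == pytest.approx([0.0, 0.0])
    assert np.all(np.diff(traj.points[:, 1]) > 0)  # y-up canonical frame
    assert compute_auc(traj) == pytest.approx(0.0, abs=1e-6)
    # samples below the threshold were discarded
    assert traj.points.shape[0] < t.size


def test_preprocess_no_crossing_is_malformed():
    geom = ScreenGeometry()
    t = np.arange(0, 200, 10.0)
    y = np.full(t.size, geom.start[1])  # never leaves the start box
    x = np.linspace(geom.start[0], geom.start[0] + 50, t.size)
    with pytest.raises(TrajectoryError):
        preprocess(t, x, y, chose_left=False, geometry=geom)


def test_preprocess_timeout_flag():
    geom = ScreenGeometry()
    t = np.linspace(0, 5200, 200)
    y = np.linspace(geom.start[1], geom.right_target[1], t.size)
    x = np.linspace(geom.start[0], geom.right_target[0], t.size)
    _, timeout = preprocess(t, x, y, chose_left=False, geometry=geom)
    assert timeout


def test_mirrored_choice_has_identical_metrics():
    """A left-corner choice is the mirror image of the right-corner one;
    both metrics are reflection-invariant, so they must agree exactly."""
    geom = ScreenGeometry()
    t, x, y = make_path(amplitude=0.4, oscillation=2.0, chose_left=False,
                        geometry=geom)
    xm = geom.width - x  # exact horizontal mirror
    tr_r, _ = preprocess(t, x, y, chose_left=False, geometry=geom)
    tr_l, _ = preprocess(t, xm, y, chose_left=True, geometry=geom)
    assert compute_auc(tr_l) == pytest.approx(compute_auc(tr_r), abs=1e-9)
    assert compute_xflips(tr_l) == compute_xflips(tr_r)
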