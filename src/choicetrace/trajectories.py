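"""Mouse-trajectory conflict metrics.

Two process-tracing measures of decision conflict are computed from the
cursor path recorded during a binary choice trial:

* the angle-based AUC — the mean angle (radians) between each movement
  step and the direction from that step's origin to the chosen target.
  A perfectly direct path scores 0; a path that initially moves away
  from the eventually-chosen option scores higher.  Despite the
  conventional name this is an average angle, not a geometric area; a
  signed-area diagnostic is provided separately as
  :func:`signed_area_auc` and is never substituted for the angle metric.
* x-flips — the number of reversals in the sign of horizontal movement.

Both metrics are purely geometric: invariant to rotation, uniform
scaling and reflection of the path-plus-target (angle-AUC), to arbitrary
y-perturbation (x-flips), and to timestamp rescaling (both).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "ConflictMetrics",
    "ScreenGeometry",
    "TrajectoryError",
    "compute_auc",
    "compute_xflips",
    "signed_area_auc",
    "preprocess",
    "metrics_from_samples",
]


class TrajectoryError(ValueError):
    """Raised for malformed or degenerate trajectories."""


@dataclass
class Trajectory:
    """One trial's cursor path in a screen-independent frame.

    Parameters
    ----------
    points : (n, 2) array
        Ordered (x, y) samples.
    target : (2,) array
        Location of the chosen option.  May coincide with the final
        point.
    timestamps : (n,) array, optional
        Sample times in ms, strictly increasing.  The metrics do not
        depend on them; they are kept for provenance.
    """

    points: np.ndarray
    target: np.ndarray
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise TrajectoryError("points must be an (n, 2) array")
        if self.points.shape[0] < 2:
            raise TrajectoryError("a trajectory needs at least 2 points")
        if self.target.shape != (2,):
            raise TrajectoryError("target must be a length-2 coordinate")
        if self.timestamps is not None:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if self.timestamps.shape != (self.points.shape[0],):
                raise TrajectoryError("timestamps must match points")
            if np.any(np.diff(self.timestamps) <= 0):
                raise TrajectoryError("timestamps must be strictly increasing")


@dataclass(frozen=True)
class ConflictMetrics:
    """Conflict metrics of one trial: mean angular deviation and x-flips."""

    auc: float
    xflips: int


def compute_auc(traj: Trajectory) -> float:
    """Mean angular deviation (radians) of each step from the target direction.

    For step vectors ``d_i = p[i+1] - p[i]`` and point-to-target vectors
    ``t_i = target - p[i]`` the metric is ``mean(acos(d_i . t_i / (|d_i||t_i|)))``
    over the steps for which both vectors are nonzero (zero-length steps, and
    the degenerate step whose origin already sits on the target, carry no
    direction and are excluded from the mean).  The cosine is clamped to
    [-1, 1] before acos for floating-point safety.

    Raises
    ------
    TrajectoryError
        If no step has both a nonzero step vector and a nonzero
        point-to-target vector.
    """
    p = traj.points
    d = np.diff(p, axis=0)                      # step vectors
    t = traj.target[None, :] - p[:-1]           # anchored at each step's origin
    nd = np.hypot(d[:, 0], d[:, 1])
    nt = np.hypot(t[:, 0], t[:, 1])
    keep = (nd > 0) & (nt > 0)
    if not np.any(keep):
        raise TrajectoryError("all steps are degenerate; angle undefined")
    cosang = np.einsum("ij,ij->i", d[keep], t[keep]) / (nd[keep] * nt[keep])
    return float(np.mean(np.arccos(np.clip(cosang, -1.0, 1.0))))


def compute_xflips(traj: Trajectory, min_movement: float = 0.0) -> int:
    """Count reversals in the sign of horizontal movement.

    Increments with ``|dx| <= min_movement`` (default 0: exact zeros) are
    skipped, carrying the previous direction, so a pause does not create
    a flip.  Monotone and single-step paths return 0.
    """
    dx = np.diff(traj.points[:, 0])
    signs = np.sign(dx[np.abs(dx) > min_movement])
    if signs.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(signs)))


def signed_area_auc(traj: Trajectory) -> float:
    """Signed area between the path and the straight start-to-end chord.

    A conventional geometric area-under-curve diagnostic (positive when
    the path bows to the left of the chord).  Provided for comparison
    only — the conflict analyses use :func:`compute_auc`.
    """
    p = traj.points
    chord = p[-1] - p[0]
    norm = np.hypot(*chord)
    if norm == 0:
        return 0.0
    # cross product of chord with each point's offset, trapezoid-summed
    rel = p - p[0]
    cross = rel[:, 0] * chord[1] - rel[:, 1] * chord[0]
    dev = -cross / norm  # perpendicular offset, +ve left of chord
    along = (rel @ chord) / norm
    return float(np.trapezoid(dev, along))


@dataclass(frozen=True)
class ScreenGeometry:
    """Task screen layout, in raw pixel coordinates with y increasing downward.

    The start box sits bottom-center; the two response options sit in the
    upper corners.  Food pictures appear once the cursor has risen 10% of
    the vertical resolution above the start box (``onset_fraction``).
    """

    width: float = 1920.0
    height: float = 1080.0
    start: tuple[float, float] = field(default=None)  # type: ignore[assignment]
    left_target: tuple[float, float] = field(default=None)  # type: ignore[assignment]
    right_target: tuple[float, float] = field(default=None)  # type: ignore[assignment]
    onset_fraction: float = 0.10
    max_trial_ms: float = 4000.0

    def __post_init__(self) -> None:
        if self.start is None:
            object.__setattr__(self, "start", (self.width / 2, self.height * 0.95))
        if self.left_target is None:
            object.__setattr__(self, "left_target", (self.width * 0.08, self.height * 0.10))
        if self.right_target is None:
            object.__setattr__(self, "right_target", (self.width * 0.92, self.height * 0.10))

    @property
    def onset_y(self) -> float:
        """Raw-pixel y below which (screenwise: above which) pictures are on."""
        return self.start[1] - self.onset_fraction * self.height


def preprocess(
    t_ms: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    chose_left: bool,
    geometry: ScreenGeometry | None = None,
) -> tuple[Trajectory, bool]:
    """Convert raw screen samples of one trial to a canonical :class:`Trajectory`.

    Samples before the onset threshold crossing (cursor risen
    ``onset_fraction`` of the screen height above the start box) are
    discarded; the retained path is re-expressed with its first point at
    the origin and y increasing toward the response row, and left-corner
    choices are mirrored horizontally so every trajectory heads for the
    canonical right-side target.

    Returns
    -------
    (trajectory, timeout)
        ``timeout`` is True when more than ``max_trial_ms`` elapsed
        between picture onset and the last sample; such trials are kept
        but flagged for exclusion from the analyses.

    Raises
    ------
    TrajectoryError
        If the cursor never crosses the onset threshold.
    """
    geom = geometry or ScreenGeometry()
    t_ms = np.asarray(t_ms, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    above = y <= geom.onset_y  # y-down pixels: smaller y = higher on screen
    if not np.any(above):
        raise TrajectoryError("cursor never crossed the picture-onset threshold")
    i0 = int(np.argmax(above))
    t_ms, x, y = t_ms[i0:], x[i0:], y[i0:]
    if x.size < 2:
        raise TrajectoryError("fewer than 2 samples after picture onset")
    timeout = bool(t_ms[-1] - t_ms[0] > geom.max_trial_ms)

    target = np.array(geom.left_target if chose_left else geom.right_target, float)
    # canonical frame: origin at first retained point, y flipped upward
    cx = x - x[0]
    cy = y[0] - y
    tx = target[0] - x[0]
    ty = y[0] - target[1]
    if chose_left:  # mirror so the chosen corner is on the right
        cx, tx = -cx, -tx
    pts = np.column_stack([cx, cy])
    traj = Trajectory(points=pts, target=np.array([tx, ty]), timestamps=t_ms)
    return traj, timeout


def metrics_from_samples(
    samples: pd.DataFrame,
    chosen_side: pd.Series | dict,
    geometry: ScreenGeometry | None = None,
    keys: tuple[str, ...] = ("participant_id", "trial_index"),
) -> pd.DataFrame:
    """Compute per-trial conflict metrics from a long table of raw samples.

    Parameters
    ----------
    samples : DataFrame
        Columns ``keys`` + ``t_ms, x, y`` (raw screen pixels, y-down).
    chosen_side : mapping
        Trial key tuple -> "left"/"right".

    Returns
    -------
    DataFrame with one row per trial: keys, ``auc``, ``xflips``, ``timeout``.
    """
    rows = []
    for key, grp in samples.groupby(list(keys), sort=True):
        grp = grp.sort_values("t_ms")
        side = chosen_side[key] if not isinstance(chosen_side, pd.Series) else chosen_side.loc[key]
        traj, timeout = preprocess(
            grp["t_ms"].to_numpy(), grp["x"].to_numpy(), grp["y"].to_numpy(),
            chose_left=(side == "left"), geometry=geometry,
        )
        rows.append(dict(zip(keys, key)) | {
            "auc": compute_auc(traj),
            "xflips": compute_xflips(traj),
            "timeout": timeout,
        })
    return pd.DataFrame(rows)
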