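"""Cube-rotation quantification and face orientation labels.

The instantaneous angular variation is measured per grid step as the angle
traversed in the world frame by each of the three unit body axes orthogonal
to the faces. For two consecutive world directions v_t, v_{t-1} of an axis
the angle is atan2(||v_t x v_{t-1}||, v_t . v_{t-1}) * 180 / pi, which equals
the printed arctan-of-quotient form on (0, 90) degrees and stays well
defined at and beyond 90 degrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from ._geometry import (
    ParticipantFrame,
    absolute_face_labels,
    quat_to_rotation,
    relative_face_labels,
)
from .errors import ValidationError
from .preprocess import TrialGrid

logger = logging.getLogger(__name__)

MOTION_THRESHOLD_DPS = 1.0


@dataclass(frozen=True)
class OrientationLabels:
    """Bijective face -> label maps at one grid sample."""

    relative: dict[int, str]
    absolute: dict[int, str]


def _axis_angles(v_now: np.ndarray, v_prev: np.ndarray) -> np.ndarray:
    cross = np.cross(v_prev, v_now)
    dot = np.sum(v_prev * v_now, axis=-1)
    return np.degrees(np.arctan2(np.linalg.norm(cross, axis=-1), dot))


def axis_delta(q_t: np.ndarray, q_prev: np.ndarray) -> np.ndarray:
    """Per-axis traversal angles (degrees) between two orientations.

    For each body axis (X, Y, Z) the axis is rotated into the world frame by
    both quaternions and the angle between the two world directions is
    returned; all values lie in [0, 180]. Invariant under q -> -q on either
    argument (both encode the same rotation).
    """
    for q in (q_t, q_prev):
        if abs(np.linalg.norm(q) - 1.0) > 1e-6:
            raise ValidationError("axis_delta requires unit quaternions")
    m_t = quat_to_rotation(q_t).as_matrix()
    m_p = quat_to_rotation(q_prev).as_matrix()
    # columns of the matrices are the body axes expressed in world coordinates
    return _axis_angles(m_t.T, m_p.T)


def axis_traversal(grid: TrialGrid) -> np.ndarray:
    """(T-1, 3) per-step traversal angles of the three body axes, degrees."""
    mats = grid.rotations().as_matrix()  # (T, 3, 3)
    axes = np.swapaxes(mats, 1, 2)  # (T, 3 axes, 3 coords)
    return _axis_angles(axes[1:], axes[:-1])


def amount_of_rotation(grid: TrialGrid) -> float:
    """Maximum over the three axes of the cumulative traversal, degrees."""
    return float(axis_traversal(grid).sum(axis=0).max())


def rotation_speed(grid: TrialGrid, motion_threshold_dps: float = MOTION_THRESHOLD_DPS) -> float:
    """Mean rotation speed (deg/s) over the in-motion instants.

    Per-axis speeds are the per-step traversals divided by the grid step; an
    instant is in motion when the mean speed across the three axes exceeds
    the threshold (1 deg/s by default). The returned value averages the
    per-axis speeds over the three axes and all in-motion instants, so static
    holding phases do not dilute the estimate. Returns 0 when no instant
    qualifies.
    """
    speeds = axis_traversal(grid) / grid.dt  # (T-1, 3)
    in_motion = speeds.mean(axis=1) > motion_threshold_dps
    if not in_motion.any():
        logger.info("no instant above %.2f deg/s; rotation speed reported as 0", motion_threshold_dps)
        return 0.0
    return float(speeds[in_motion].mean())


def relative_labels_per_sample(
    grid: TrialGrid, participant_frame: ParticipantFrame | None = None
) -> np.ndarray:
    """(T, 6) array of relative-label indices (into RELATIVE_LABELS) per face.

    Vectorized: per sample the reference axis with the largest |component|
    per body axis almost always forms a permutation directly; the rare
    conflicting samples (near 45-degree ties) fall back to the greedy
    assignment used by :func:`orientation_labels`.
    """
    from ._geometry import RELATIVE_LABELS

    frame = participant_frame or ParticipantFrame()
    basis = frame.basis()
    index = {name: i for i, name in enumerate(RELATIVE_LABELS)}
    rots = grid.rotations()
    mats = rots.as_matrix()  # (T, 3, 3), columns = body axes in world coords
    comp = np.einsum("ri,tij->trj", basis.T, mats)  # comp[t, r, j] = <ref_r, body_j>
    assign = np.abs(comp).argmax(axis=1)  # (T, 3): ref axis per body axis
    ok = np.sort(assign, axis=1) == np.arange(3)
    ok = ok.all(axis=1)
    sign_pos = np.take_along_axis(comp, assign[:, None, :], axis=1)[:, 0, :] >= 0  # (T, 3)
    out = np.empty((len(grid), 6), dtype=np.int8)
    # +axis face 2j+1 -> label 2*assign (positive) or 2*assign+1; -axis face opposite
    out[:, 0::2] = 2 * assign + np.where(sign_pos, 0, 1)
    out[:, 1::2] = 2 * assign + np.where(sign_pos, 1, 0)
    for t in np.flatnonzero(~ok):  # degenerate ties: exact greedy
        labels = relative_face_labels(rots[int(t)], frame)
        for face, name in labels.items():
            out[t, face - 1] = index[name]
    return out


def orientation_labels(
    q: np.ndarray | Rotation, participant_frame: ParticipantFrame | None = None
) -> OrientationLabels:
    """Absolute (cardinal) and relative (egocentric) labels of all six faces."""
    rot = q if isinstance(q, Rotation) else quat_to_rotation(np.asarray(q))
    return OrientationLabels(
        relative=relative_face_labels(rot, participant_frame),
        absolute=absolute_face_labels(rot),
    )
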