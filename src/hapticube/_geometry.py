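"""Fixed body-frame and label conventions for the sensorized cube.

Faces are numbered 1..6 with outward normals +X, -X, +Y, -Y, +Z, -Z in the
cube's body frame; cells 0..15 are in row-major 4x4 order per face.
Quaternions are scalar-first (w, x, y, z) and encode the active rotation
taking body-frame vectors to world-frame vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

N_FACES = 6
N_CELLS = 16

#: outward unit normal of face i+1 in the body frame (row i)
FACE_NORMALS = np.array(
    [
        [1.0, 0.0, 0.0],
        [-1.0, 0.0, 0.0],
        [0.0, 1.0, 0.0],
        [0.0, -1.0, 0.0],
        [0.0, 0.0, 1.0],
        [0.0, 0.0, -1.0],
    ]
)

#: body axes orthogonal to the faces (X, Y, Z); the three axes whose world
#: trajectories are integrated for the amount-of-rotation measure
BODY_AXES = np.eye(3)

#: egocentric (participant-perspective) labels in the fixed tie-break order
RELATIVE_LABELS = ("up", "down", "front", "rear", "left", "right")

#: cardinal labels for absolute face orientation
ABSOLUTE_LABELS = ("Up", "Down", "North", "South", "East", "West")


@dataclass(frozen=True)
class ParticipantFrame:
    """World-frame directions of the participant's up / front / left.

    Default: world +Z is up, +X is front; the frame is right-handed so
    +Y is the participant's left.
    """

    up: tuple[float, float, float] = (0.0, 0.0, 1.0)
    front: tuple[float, float, float] = (1.0, 0.0, 0.0)
    left: tuple[float, float, float] = (0.0, 1.0, 0.0)

    def basis(self) -> np.ndarray:
        """Columns (up, front, left), checked orthonormal."""
        b = np.column_stack([self.up, self.front, self.left]).astype(float)
        if not np.allclose(b.T @ b, np.eye(3), atol=1e-9):
            raise ValueError("participant frame must be orthonormal")
        return b


#: per participant axis (up, front, left) the labels for +/- alignment
_RELATIVE_SIGNED = (("up", "down"), ("front", "rear"), ("left", "right"))

#: cardinal basis: columns (Up, North, East) in world coordinates (ENU world:
#: +X East, +Y North, +Z up)
_CARDINAL_BASIS = np.column_stack([(0.0, 0.0, 1.0), (0.0, 1.0, 0.0), (1.0, 0.0, 0.0)])
_ABSOLUTE_SIGNED = (("Up", "Down"), ("North", "South"), ("East", "West"))


def quat_to_rotation(q: np.ndarray) -> Rotation:
    """Scalar-first quaternion array (…, 4) -> scipy Rotation."""
    return Rotation.from_quat(np.asarray(q, dtype=float), scalar_first=True)


def rotation_to_quat(r: Rotation) -> np.ndarray:
    q = r.as_quat(scalar_first=True)
    # canonicalize sign for reproducible on-disk output
    q = np.atleast_2d(q)
    flip = q[:, 0] < 0
    q[flip] *= -1.0
    return q.squeeze()


def _greedy_axis_assignment(m_abs: np.ndarray, axis_priority: tuple[int, ...]) -> np.ndarray:
    """Assign each body axis (column) a distinct reference axis (row).

    Greedy on the largest |component|; ties resolved by ``axis_priority``
    (reference-axis order) then by body-axis order, which realizes the fixed
    label tie-break order. Returns assignment[j] = reference-axis index for
    body axis j.
    """
    m = m_abs.copy()
    assign = np.full(3, -1, dtype=int)
    for _ in range(3):
        best = None
        for i in axis_priority:
            if np.all(np.isneginf(m[i])):
                continue
            for j in range(3):
                if np.isneginf(m[i, j]):
                    continue
                if best is None or m[i, j] > m[best[0], best[1]] + 1e-12:
                    best = (i, j)
        i, j = best
        assign[j] = i
        m[i, :] = -np.inf
        m[:, j] = -np.inf
    return assign


def face_labels(
    rotation: Rotation,
    reference_basis: np.ndarray,
    signed_labels: tuple[tuple[str, str], ...],
    axis_priority: tuple[int, ...] = (0, 1, 2),
) -> dict[int, str]:
    """Bijective face -> label map for one orientation.

    ``reference_basis`` holds the reference directions as columns; each body
    axis is matched to the reference axis with the largest |dot|, greedily so
    that the six faces always receive six distinct labels (a plain per-face
    argmax breaks down at 45-degree ties).
    """
    mat = rotation.as_matrix()  # columns = body axes in world coordinates
    comp = reference_basis.T @ mat  # comp[i, j] = <ref_i, body_j>
    assign = _greedy_axis_assignment(np.abs(comp), axis_priority)
    labels: dict[int, str] = {}
    for body_axis in range(3):
        ref_axis = assign[body_axis]
        pos, neg = signed_labels[ref_axis]
        positive = comp[ref_axis, body_axis] >= 0
        face_pos = 2 * body_axis + 1  # +axis face id
        face_neg = 2 * body_axis + 2
        labels[face_pos] = pos if positive else neg
        labels[face_neg] = neg if positive else pos
    return labels


def relative_face_labels(rotation: Rotation, frame: ParticipantFrame | None = None) -> dict[int, str]:
    frame = frame or ParticipantFrame()
    return face_labels(rotation, frame.basis(), _RELATIVE_SIGNED)


def absolute_face_labels(rotation: Rotation) -> dict[int, str]:
    return face_labels(rotation, _CARDINAL_BASIS, _ABSOLUTE_SIGNED)
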