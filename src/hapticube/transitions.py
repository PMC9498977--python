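"""Exploration sequences, transition matrices and the derived scores.

A trial's classified frames are reduced to a temporal sequence of
exploration episodes (maximal runs of one explored physical face); each
episode carries the relative-orientation label under which the face was
explored. Transitions between consecutive episodes are tallied into a 6x6
percentage matrix over the relative labels (up, down, front, rear, left,
right). Diagonal cells arise when successive (different) faces are explored
under the same relative orientation — the participant rotates the cube to
bring each new face into a preferred position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geometry import RELATIVE_LABELS
from .touch import ExplorationFrames

N_LABELS = len(RELATIVE_LABELS)


@dataclass(frozen=True)
class ExplorationEpisode:
    """A maximal run of one explored face, with its modal relative label."""

    face: int
    orientation_label: str
    start_index: int
    end_index: int
    gap_before: bool = False


@dataclass(frozen=True)
class TransitionMatrix:
    """6x6 percentages of episode-to-episode transitions between labels."""

    values: np.ndarray  # (6, 6), rows = from-label, cols = to-label
    n_transitions: int

    @property
    def labels(self) -> tuple[str, ...]:
        return RELATIVE_LABELS


def build_episodes(
    frames: ExplorationFrames, labels_per_sample: np.ndarray
) -> list[ExplorationEpisode]:
    """Segment the per-frame explored faces into episodes.

    ``labels_per_sample`` is the (T, 6) relative-label index array for the
    same trimmed grid. Frames with no explored face break runs; when the same
    face resumes after such a gap it starts a new episode (a return). Ties
    between explored faces are resolved to the lowest face id before run
    building. Each episode's label is the modal relative label of its
    samples, ties resolved to the label at episode start.
    """
    face_seq = np.asarray(frames.explored_face_lowest())  # (T-1,), 0 = none
    # maximal runs of a constant non-zero face
    boundaries = np.flatnonzero(np.diff(face_seq) != 0) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(face_seq)]]) - 1
    episodes: list[ExplorationEpisode] = []
    for start, end in zip(starts, ends):
        face = int(face_seq[start])
        if face == 0:
            continue
        # frame i classifies grid sample i + 1; labels are per grid sample
        labels = [int(labels_per_sample[t + 1, face - 1]) for t in range(start, end + 1)]
        counts = np.bincount(labels, minlength=N_LABELS)
        label_idx = labels[0] if counts[labels[0]] == counts.max() else int(np.argmax(counts))
        gap_before = bool(episodes) and start > 0 and face_seq[start - 1] == 0
        episodes.append(
            ExplorationEpisode(
                face=face,
                orientation_label=RELATIVE_LABELS[label_idx],
                start_index=int(start) + 1,
                end_index=int(end) + 1,
                gap_before=gap_before,
            )
        )
    return episodes


def transition_matrix(episodes: list[ExplorationEpisode]) -> TransitionMatrix:
    """Percentage matrix of transitions between consecutive episodes' labels.

    Consecutive episodes of the same physical face (possible only across an
    untouched gap) contribute a return but no transition. With fewer than one
    countable transition the matrix is all-zero.
    """
    label_index = {name: i for i, name in enumerate(RELATIVE_LABELS)}
    counts = np.zeros((N_LABELS, N_LABELS), dtype=float)
    n = 0
    for prev, nxt in zip(episodes, episodes[1:]):
        if prev.face == nxt.face:
            continue
        counts[label_index[prev.orientation_label], label_index[nxt.orientation_label]] += 1
        n += 1
    if n == 0:
        return TransitionMatrix(values=counts, n_transitions=0)
    return TransitionMatrix(values=counts / n * 100.0, n_transitions=n)


def max_diagonal_score(matrix: TransitionMatrix) -> float:
    """Highest percentage among the six diagonal (self-transition) cells."""
    return float(np.diag(matrix.values).max())


def n_different_transitions(matrix: TransitionMatrix) -> int:
    """Number of distinct transitions used (strictly positive cells of 36)."""
    return int((matrix.values > 0).sum())


def n_returns(episodes: list[ExplorationEpisode]) -> int:
    """Episodes revisiting an already-explored physical face.

    Equals (number of episodes) - (number of distinct faces explored);
    independent of the orientation labels.
    """
    if not episodes:
        return 0
    faces = [e.face for e in episodes]
    return len(faces) - len(set(faces))
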