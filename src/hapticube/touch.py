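"""SMC similarity, explorative-touch classification and touch metrics.

The spatiotemporal filter separates explorative touches (probing a face, so
its map varies between consecutive 0.2 s samples) from holding touches
(stable support grips). At each grid sample the simple matching coefficient
(SMC) of every face against the previous sample is computed; the face(s)
attaining the minimum SMC are the explored faces, unless the SMC is 1 for
all six faces (an untouched or perfectly still cube), in which case no face
is explored at that instant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geometry import N_CELLS
from .errors import MetricUndefinedError, ValidationError
from .preprocess import TrialGrid


@dataclass(frozen=True)
class SmcValue:
    """SMC between two 16-cell binary maps, with the match/mismatch counts."""

    m00: int
    m01: int
    m10: int
    m11: int

    @property
    def value(self) -> float:
        return (self.m00 + self.m11) / N_CELLS


def smc(map_a: np.ndarray, map_b: np.ndarray) -> SmcValue:
    """Simple matching coefficient (m00 + m11) / 16 of two binary maps.

    1 indicates identical maps, 0 complementary maps; symmetric in its
    arguments.
    """
    a = np.asarray(map_a)
    b = np.asarray(map_b)
    if a.shape != (N_CELLS,) or b.shape != (N_CELLS,):
        raise ValidationError(f"maps must have {N_CELLS} cells")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValidationError("maps must be binary")
    m11 = int(np.sum((a == 1) & (b == 1)))
    m00 = int(np.sum((a == 0) & (b == 0)))
    m01 = int(np.sum((a == 0) & (b == 1)))
    m10 = int(np.sum((a == 1) & (b == 0)))
    return SmcValue(m00=m00, m01=m01, m10=m10, m11=m11)


@dataclass(frozen=True)
class ExplorationFrame:
    """Classification of one grid sample (t >= 1; sample 0 has no predecessor)."""

    grid_index: int
    explored_faces: frozenset[int]
    smc_per_face: tuple[float, ...]
    active_cells_explored: int

    @property
    def min_smc(self) -> float:
        return min(self.smc_per_face)


class ExplorationFrames:
    """Array-backed sequence of per-sample classifications for one trial.

    Indexing yields :class:`ExplorationFrame` views; the metric functions
    consume the underlying arrays directly. Frame ``i`` describes grid sample
    ``i + 1`` of the trimmed grid.
    """

    def __init__(self, grid: TrialGrid):
        if len(grid) < 2:
            raise ValidationError("classification needs a trimmed grid with T >= 2")
        self.grid = grid
        touch = grid.touch.astype(np.int8)
        same = touch[1:] == touch[:-1]  # (T-1, 6, 16)
        self.smc_per_face = same.sum(axis=2) / N_CELLS  # (T-1, 6)
        min_smc = self.smc_per_face.min(axis=1)
        self.explored_mask = (self.smc_per_face == min_smc[:, None]) & (min_smc[:, None] < 1.0)
        self.min_smc = min_smc
        self.active_cells_explored = (touch[1:] * self.explored_mask[:, :, None]).sum(axis=(1, 2))

    def __len__(self) -> int:
        return self.explored_mask.shape[0]

    def __getitem__(self, i: int) -> ExplorationFrame:
        faces = frozenset(int(f) + 1 for f in np.flatnonzero(self.explored_mask[i]))
        return ExplorationFrame(
            grid_index=i + 1,
            explored_faces=faces,
            smc_per_face=tuple(float(x) for x in self.smc_per_face[i]),
            active_cells_explored=int(self.active_cells_explored[i]),
        )

    @property
    def any_explored(self) -> np.ndarray:
        return self.explored_mask.any(axis=1)

    def explored_face_lowest(self) -> np.ndarray:
        """Per frame, the lowest explored face id (1..6), or 0 when none.

        Ties between faces sharing the minimum SMC are resolved to the lowest
        face id for sequence building; the tied faces all still contribute to
        the touch metrics.
        """
        first = self.explored_mask.argmax(axis=1) + 1
        return np.where(self.any_explored, first, 0)


def classify_explorative(grid: TrialGrid) -> ExplorationFrames:
    """Classify every grid sample (from the second on) of a trimmed trial."""
    return ExplorationFrames(grid)


def exploration_duration(grid: TrialGrid) -> float:
    """Seconds between the first and last grid sample with any active cell."""
    active = np.flatnonzero(grid.active_cells >= 1)
    if active.size == 0:
        raise MetricUndefinedError("no active samples in trial")
    return float((active[-1] - active[0]) * grid.dt)


def count_touches(frames: ExplorationFrames) -> int:
    """Touch events: 0 -> 1 transitions of single cells on explored faces."""
    touch = frames.grid.touch
    onsets = (touch[1:] == 1) & (touch[:-1] == 0)  # (T-1, 6, 16)
    return int((onsets * frames.explored_mask[:, :, None]).sum())


def touch_frequency(frames: ExplorationFrames, duration: float) -> float:
    """Touches per second over the exploration duration."""
    if duration <= 0:
        raise MetricUndefinedError("touch frequency undefined for zero duration")
    return count_touches(frames) / duration


def per_face_duration_stats(frames: ExplorationFrames) -> tuple[float, float]:
    """(mean, sample SD) across the six faces of per-face exploration time.

    A face's exploration time is the number of frames in which it is an
    explored face times the grid step; faces never explored contribute zero,
    which makes the SD sensitive to focused exploration.
    """
    seconds = frames.explored_mask.sum(axis=0) * frames.grid.dt  # (6,)
    return float(seconds.mean()), float(seconds.std(ddof=1))


def mean_active_cells(frames: ExplorationFrames) -> float:
    """Mean active cells per sample on the explored faces.

    Samples with no explored face, and explored samples with zero active
    cells, are excluded.
    """
    mask = frames.any_explored & (frames.active_cells_explored > 0)
    if not mask.any():
        raise MetricUndefinedError("no explored samples with active cells")
    return float(frames.active_cells_explored[mask].mean())


def mean_smc(frames: ExplorationFrames) -> float:
    """Mean (minimum) SMC of the explored faces over explored samples."""
    mask = frames.any_explored
    if not mask.any():
        raise MetricUndefinedError("no explored samples")
    return float(frames.min_smc[mask].mean())
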