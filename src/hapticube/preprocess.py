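"""Resampling of raw sessions onto the constant 0.2 s analysis grid.

Binary tactile maps are resampled by zero-order hold (the latest raw map at
or before each grid time), which keeps values binary and never invents a map
that was not in the raw stream. Orientations are resampled by spherical
linear interpolation (SLERP) along the shortest arc. Trials are then trimmed
to the actively touched interval: leading and trailing grid samples with
fewer than two active cells (whole-cube count) are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

from ._geometry import quat_to_rotation, rotation_to_quat
from .errors import EmptyTrialError, TrialTooShortError, ValidationError
from .io import RawSample

logger = logging.getLogger(__name__)

GRID_DT = 0.2
TRIM_MIN_ACTIVE_CELLS = 2
GAP_WARNING_S = 2.0


@dataclass
class TrialGrid:
    """A trial resampled to a constant grid (touch maps + orientations).

    ``touch`` is (T, 6, 16) with values in {0, 1}; ``q`` is (T, 4)
    scalar-first unit quaternions; ``t0`` is the absolute time of the first
    grid sample; consecutive grid samples are exactly ``dt`` apart.
    """

    dt: float
    t0: float
    touch: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        self.touch = np.asarray(self.touch, dtype=np.uint8)
        self.q = np.asarray(self.q, dtype=float)
        if self.touch.ndim != 3 or self.q.shape != (self.touch.shape[0], 4):
            raise ValidationError("touch must be (T, 6, 16) and q (T, 4)")
        norms = np.linalg.norm(self.q, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValidationError("grid quaternions must be unit-norm within 1e-6")

    def __len__(self) -> int:
        return self.touch.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self))

    def rotations(self) -> Rotation:
        return quat_to_rotation(self.q)

    @property
    def active_cells(self) -> np.ndarray:
        """Total active cells per grid sample (whole cube)."""
        return self.touch.sum(axis=(1, 2)).astype(int)


def _grid_times(times: np.ndarray, dt: float) -> np.ndarray:
    span = times[-1] - times[0]
    if len(times) < 2 or span <= dt:
        raise TrialTooShortError(f"trial spans {span:.3f} s, need more than {dt} s")
    n = int(np.floor(span / dt + 1e-9)) + 1
    return times[0] + dt * np.arange(n)


def interpolate_touch(samples: Sequence[RawSample], dt: float = GRID_DT) -> np.ndarray:
    """Zero-order hold of the binary maps onto the dt grid."""
    times = np.array([s.t for s in samples])
    grid = _grid_times(times, dt)
    idx = np.searchsorted(times, grid + 1e-9, side="right") - 1
    gaps = np.diff(times)
    if gaps.size and gaps.max() > GAP_WARNING_S:
        logger.warning("raw stream has a %.2f s gap; holding last sample across it", gaps.max())
    touch = np.stack([samples[i].touch for i in idx])
    return touch


def interpolate_orientation(samples: Sequence[RawSample], dt: float = GRID_DT) -> np.ndarray:
    """SLERP of the raw orientations onto the dt grid (shortest arc)."""
    times = np.array([s.t for s in samples])
    grid = _grid_times(times, dt)
    rots = quat_to_rotation(np.stack([s.q for s in samples]))
    slerp = Slerp(times, rots)
    grid = np.clip(grid, times[0], times[-1])  # guard fp rounding at the last sample
    out = slerp(grid)
    return np.atleast_2d(rotation_to_quat(out))


def resample_trial(samples: Sequence[RawSample], dt: float = GRID_DT) -> TrialGrid:
    """Build the untrimmed constant-rate grid for one trial."""
    touch = interpolate_touch(samples, dt)
    q = interpolate_orientation(samples, dt)
    return TrialGrid(dt=dt, t0=samples[0].t, touch=touch, q=q)


def trim_trial(
    grid: TrialGrid, min_active_cells: int = TRIM_MIN_ACTIVE_CELLS
) -> tuple[TrialGrid, tuple[int, int]]:
    """Drop leading/trailing grid samples with < ``min_active_cells`` active.

    Returns the trimmed grid and the (first, last) kept indices of the input
    grid. Interior low-activity samples are untouched; the operation is
    idempotent. Raises :class:`EmptyTrialError` when no sample qualifies.
    """
    active = grid.active_cells
    qualifying = np.flatnonzero(active >= min_active_cells)
    if qualifying.size == 0:
        raise EmptyTrialError(f"no grid sample has at least {min_active_cells} active cells")
    first, last = int(qualifying[0]), int(qualifying[-1])
    if last == first:
        raise EmptyTrialError("touched interval shorter than two grid samples")
    trimmed = TrialGrid(
        dt=grid.dt,
        t0=grid.t0 + grid.dt * first,
        touch=grid.touch[first : last + 1],
        q=grid.q[first : last + 1],
    )
    return trimmed, (first, last)
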