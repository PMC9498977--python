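"""End-to-end per-trial metric extraction.

One row per trial phase with the haptic dependent variables analyzed at the
group level: exploration duration, number/frequency of touches, amount and
speed of rotation, the three transition scores, per-face duration mean and
variability, mean active cells and mean SMC. Recognition accuracy is a
per-participant variable computed from the recall annotations.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from ._geometry import ParticipantFrame
from .errors import EmptyTrialError, MetricUndefinedError, TrialTooShortError
from .io import RawSample, TrialAnnotation
from .preprocess import GRID_DT, resample_trial, trim_trial
from .rotation import amount_of_rotation, relative_labels_per_sample, rotation_speed
from .touch import (
    classify_explorative,
    count_touches,
    exploration_duration,
    mean_active_cells,
    mean_smc,
    per_face_duration_stats,
)
from .transitions import (
    build_episodes,
    max_diagonal_score,
    n_different_transitions,
    n_returns,
    transition_matrix,
)

#: the haptic per-trial dependent variables, in reporting order
METRIC_COLUMNS = (
    "exploration_duration",
    "n_touches",
    "touch_frequency",
    "amount_of_rotation",
    "rotation_speed",
    "max_diagonal_score",
    "n_different_transitions",
    "duration_per_face_mean",
    "duration_per_face_sd",
    "n_returns",
    "mean_active_cells",
    "mean_smc",
)


def compute_trial_metrics(
    samples: Sequence[RawSample],
    dt: float = GRID_DT,
    participant_frame: ParticipantFrame | None = None,
    return_transition_matrix: bool = False,
):
    """All per-trial metrics for the raw samples of one trial phase.

    Resamples to the constant grid, trims to the touched interval, classifies
    explorative touches and derives the 12 haptic metrics. Returns a dict
    (plus the 6x6 transition matrix when requested).
    """
    grid = resample_trial(samples, dt)
    grid, _ = trim_trial(grid)
    frames = classify_explorative(grid)
    duration = exploration_duration(grid)
    touches = count_touches(frames)
    face_mean, face_sd = per_face_duration_stats(frames)
    labels = relative_labels_per_sample(grid, participant_frame)
    episodes = build_episodes(frames, labels)
    tm = transition_matrix(episodes)
    metrics = {
        "exploration_duration": duration,
        "n_touches": touches,
        "touch_frequency": touches / duration if duration > 0 else np.nan,
        "amount_of_rotation": amount_of_rotation(grid),
        "rotation_speed": rotation_speed(grid),
        "max_diagonal_score": max_diagonal_score(tm),
        "n_different_transitions": n_different_transitions(tm),
        "duration_per_face_mean": face_mean,
        "duration_per_face_sd": face_sd,
        "n_returns": n_returns(episodes),
        "mean_active_cells": mean_active_cells(frames),
        "mean_smc": mean_smc(frames),
    }
    if return_transition_matrix:
        return metrics, tm
    return metrics


def trial_metrics_table(
    samples: Sequence[RawSample],
    annotations: Sequence[TrialAnnotation],
    dt: float = GRID_DT,
    participant_frame: ParticipantFrame | None = None,
) -> pd.DataFrame:
    """One MetricsRow per annotated trial phase of a session.

    Trials whose window yields no valid exploration (too short or never
    touched) are skipped. Columns: participant_id, group, trial_index, phase
    plus the 12 haptic metrics.
    """
    times = np.array([s.t for s in samples])
    rows = []
    for ann in annotations:
        lo = int(np.searchsorted(times, ann.t_start, side="left"))
        hi = int(np.searchsorted(times, ann.t_end, side="right"))
        window = samples[lo:hi]
        try:
            metrics = compute_trial_metrics(window, dt=dt, participant_frame=participant_frame)
        except (TrialTooShortError, EmptyTrialError, MetricUndefinedError):
            continue
        rows.append(
            {
                "participant_id": ann.participant_id,
                "group": ann.group,
                "trial_index": ann.trial_index,
                "phase": ann.phase,
                **metrics,
            }
        )
    return pd.DataFrame(rows, columns=["participant_id", "group", "trial_index", "phase", *METRIC_COLUMNS])


def accuracy_table(annotations: Sequence[TrialAnnotation]) -> pd.DataFrame:
    """Per-participant recognition accuracy over recall trials.

    Accuracy is the fraction of recall phases whose same/different response
    matches the ground truth.
    """
    rows: dict[str, dict] = {}
    for ann in annotations:
        if ann.phase != "recall":
            continue
        entry = rows.setdefault(ann.participant_id, {"group": ann.group, "n": 0, "correct": 0})
        entry["n"] += 1
        entry["correct"] += int(ann.response == ann.truth)
    return pd.DataFrame(
        [
            {
                "participant_id": pid,
                "group": e["group"],
                "n_trials": e["n"],
                "accuracy": e["correct"] / e["n"],
            }
            for pid, e in sorted(rows.items())
        ]
    )


def write_metrics_csv(table: pd.DataFrame, path) -> None:
    """Deterministic CSV output (fixed float formatting) for metrics tables."""
    table.to_csv(path, index=False, float_format="%.6f")
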