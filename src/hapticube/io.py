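"""Reading and writing raw cube sessions and trial annotations.

A session is stored as JSON-lines, one record per raw sample::

    {"t": 1.234567, "touch": [[16 ints] x 6 faces], "q": [w, x, y, z]}

Trial annotations live in a sibling CSV with columns
``participant_id, group, trial_index, phase, t_start, t_end, response, truth``.
This module is the only place where the on-disk dialect is defined.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._geometry import N_CELLS, N_FACES
from .errors import ParseError, ValidationError

GROUPS = ("CB", "LB", "SI")
PHASES = ("memorization", "recall")
RESPONSES = ("same", "different", "none")


@dataclass
class RawSample:
    """One irregular-rate observation: time, 6x16 touch map, orientation.

    ``t`` is seconds since session start; ``touch`` is a (6, 16) array of
    0/1 (faces x cells); ``q`` is a scalar-first unit quaternion (w, x, y, z)
    encoding the active body-to-world rotation.
    """

    t: float
    touch: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        raw = np.asarray(self.touch)
        if raw.dtype == np.uint8:
            self.touch = raw
            if self.touch.shape == (N_FACES, N_CELLS) and self.touch.max(initial=0) > 1:
                raise ValidationError("touch values must be 0 or 1")
        else:
            if not np.isin(raw, (0, 1)).all():
                raise ValidationError("touch values must be 0 or 1")
            self.touch = raw.astype(np.uint8)
        self.q = np.asarray(self.q, dtype=float)
        if self.touch.shape != (N_FACES, N_CELLS):
            raise ValidationError(f"touch map must be {N_FACES}x{N_CELLS}, got {self.touch.shape}")
        if self.q.shape != (4,):
            raise ValidationError("quaternion must have 4 components (w, x, y, z)")
        norm = float(np.linalg.norm(self.q))
        if abs(norm - 1.0) > 1e-3:
            raise ValidationError(f"quaternion norm {norm:.6f} deviates from 1 by more than 1e-3")
        if abs(norm - 1.0) > 1e-12:  # renormalize, but keep already-unit input bit-stable
            self.q = self.q / norm

    @classmethod
    def _trusted(cls, t: float, touch: np.ndarray, q: np.ndarray) -> "RawSample":
        """Validation-free constructor for generators that guarantee validity."""
        obj = cls.__new__(cls)
        obj.t = t
        obj.touch = touch
        obj.q = q
        return obj

    def __eq__(self, other: object) -> bool:  # bit-for-bit sample equality
        if not isinstance(other, RawSample):
            return NotImplemented
        return (
            self.t == other.t
            and np.array_equal(self.touch, other.touch)
            and np.array_equal(self.q, other.q)
        )


@dataclass(frozen=True)
class TrialAnnotation:
    """Metadata for one trial phase (a time window of the session)."""

    participant_id: str
    group: str
    trial_index: int
    phase: str
    t_start: float
    t_end: float
    response: str = "none"
    truth: str = "none"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.phase not in PHASES:
            raise ValidationError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if self.response not in RESPONSES or self.truth not in RESPONSES:
            raise ValidationError("response/truth must be 'same', 'different' or 'none'")
        if self.phase == "memorization" and (self.response != "none" or self.truth != "none"):
            raise ValidationError("memorization phases carry no response/truth")
        if self.t_end <= self.t_start:
            raise ValidationError("t_end must exceed t_start")


def _validate_annotations(annotations: Sequence[TrialAnnotation]) -> None:
    by_participant: dict[str, dict[int, set[str]]] = {}
    for ann in annotations:
        phases = by_participant.setdefault(ann.participant_id, {}).setdefault(ann.trial_index, set())
        if ann.phase in phases:
            raise ValidationError(
                f"duplicate {ann.phase} phase for participant {ann.participant_id} "
                f"trial {ann.trial_index}"
            )
        phases.add(ann.phase)
    for pid, trials in by_participant.items():
        for idx, phases in trials.items():
            if phases != {"memorization", "recall"}:
                raise ValidationError(
                    f"participant {pid} trial {idx} must have exactly one "
                    f"memorization+recall pair, got {sorted(phases)}"
                )


def annotations_path_for(session_path: str | Path) -> Path:
    p = Path(session_path)
    return p.with_suffix(".annotations.csv")


def read_session(path: str | Path) -> tuple[list[RawSample], list[TrialAnnotation]]:
    """Read a JSON-lines session plus its sibling annotations CSV (if present).

    Samples are returned sorted by time. Quaternions deviating from unit norm
    by at most 1e-3 are renormalized; larger deviations raise
    :class:`ValidationError`, as do non-monotonic timestamps.
    """
    path = Path(path)
    samples: list[RawSample] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                rec = json.loads(line)
                sample = RawSample(t=float(rec["t"]), touch=rec["touch"], q=rec["q"])
            except ValidationError as exc:
                if "norm" in str(exc):  # quaternion past the repairable band
                    raise ValidationError(f"{path}:{lineno}: {exc}") from exc
                raise ParseError(f"{path}:{lineno}: malformed sample record: {exc}") from exc
            except Exception as exc:  # malformed JSON / missing keys
                raise ParseError(f"{path}:{lineno}: malformed sample record: {exc}") from exc
            samples.append(sample)
    times = np.array([s.t for s in samples])
    if len(times) > 1 and not (np.diff(times) > 0).all():
        bad = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 2
        raise ValidationError(f"{path}: timestamps not strictly increasing at line {bad}")

    annotations: list[TrialAnnotation] = []
    ann_path = annotations_path_for(path)
    if ann_path.exists():
        annotations = read_annotations(ann_path)
    return samples, annotations


def read_annotations(path: str | Path) -> list[TrialAnnotation]:
    path = Path(path)
    annotations: list[TrialAnnotation] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            try:
                annotations.append(
                    TrialAnnotation(
                        participant_id=row["participant_id"],
                        group=row["group"],
                        trial_index=int(row["trial_index"]),
                        phase=row["phase"],
                        t_start=float(row["t_start"]),
                        t_end=float(row["t_end"]),
                        response=row.get("response") or "none",
                        truth=row.get("truth") or "none",
                    )
                )
            except ValidationError:
                raise
            except Exception as exc:
                raise ParseError(f"{path}:{lineno}: malformed annotation row: {exc}") from exc
    _validate_annotations(annotations)
    return annotations


def write_session(
    samples: Iterable[RawSample],
    annotations: Sequence[TrialAnnotation],
    path: str | Path,
) -> Path:
    """Write a session (and annotations when non-empty); exact round-trip.

    Timestamps are written with 9 decimal digits and quaternion components in
    ``repr`` precision so that :func:`read_session` reproduces the inputs
    bit-for-bit (after the reader's renormalization no-op on already-unit
    quaternions).
    """
    path = Path(path)
    samples = list(samples)
    times = [s.t for s in samples]
    if len(times) > 1 and not (np.diff(times) > 0).all():
        raise ValidationError("timestamps must be strictly increasing")
    _validate_annotations(annotations)
    with path.open("w") as fh:
        fh.write("# hapticube session v1: one JSON record per raw sample\n")
        for s in samples:
            rec = {
                "t": round(float(s.t), 9),
                "touch": s.touch.astype(int).tolist(),
                "q": [float(x) for x in s.q],
            }
            fh.write(json.dumps(rec, separators=(",", ":")) + "\n")
    if annotations:
        write_annotations(annotations, annotations_path_for(path))
    return path


def write_annotations(annotations: Sequence[TrialAnnotation], path: str | Path) -> Path:
    path = Path(path)
    _validate_annotations(annotations)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["participant_id", "group", "trial_index", "phase", "t_start", "t_end", "response", "truth"]
        )
        for a in annotations:
            writer.writerow(
                [a.participant_id, a.group, a.trial_index, a.phase,
                 f"{a.t_start:.6f}", f"{a.t_end:.6f}", a.response, a.truth]
            )
    return path
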