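"""Synthetic exploration-trace generator.

Emulates the statistical structure the analysis pipeline assumes: episodic
face-by-face exploration with reorientations between episodes, a stable
two-cell holding pattern on a support face, spatiotemporally variable maps
on the explored face with controlled active-cell count and step-to-step
SMC, irregular ~5 Hz sampling (intervals 203 +/- 113 ms, truncated at
50 ms), and low-activity lead-in/tail phases that exercise trimming.

Group presets carry the published group-level targets (mean active cells,
mean SMC, total rotation) so that a synthetic cohort reproduces the
between-group structure of the study without any recorded data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation, Slerp
from scipy.stats import poisson, truncnorm

from ._geometry import (
    FACE_NORMALS,
    N_CELLS,
    N_FACES,
    ParticipantFrame,
    relative_face_labels,
    rotation_to_quat,
)
from .errors import GenerationError
from .io import RawSample, TrialAnnotation

# raw sampling cadence (seconds)
SAMPLE_MEAN = 0.203
SAMPLE_SD = 0.113
SAMPLE_MIN = 0.05

LEAD_S = 1.0  # low-activity lead-in / tail per trial
GAP_S = 2.0  # untouched gap between trial phases
HOLDING_FACE = 6  # support face, never explored
HOLDING_CELLS = (0, 5)  # constant two-cell holding pattern

_MAX_SMC = 15.0 / 16.0  # the explored face must change at least one cell/step

#: participant-frame world directions of the six relative labels
_LABEL_DIRS = {
    "up": np.array([0.0, 0.0, 1.0]),
    "down": np.array([0.0, 0.0, -1.0]),
    "front": np.array([1.0, 0.0, 0.0]),
    "rear": np.array([-1.0, 0.0, 0.0]),
    "left": np.array([0.0, 1.0, 0.0]),
    "right": np.array([0.0, -1.0, 0.0]),
}


@dataclass(frozen=True)
class GroupPreset:
    """Generative targets for one participant group."""

    target_active_cells: float  # mean cells/sample on the explored face
    target_smc: float  # mean step-to-step SMC of the explored face
    total_rotation: float  # degrees/trial (max-axis cumulative target)
    rotation_speed: float = 25.0  # deg/s whenever the cube moves
    episode_policy: float = 4.0  # weight of the preferred relative orientation
    n_episodes: int = 12
    trial_duration: float = 60.0  # seconds per trial phase
    accuracy: float = 0.75  # P(recall response matches truth)

    def validate(self) -> None:
        if not (1.0 < self.target_active_cells < N_CELLS):
            raise GenerationError(
                f"target_active_cells must lie in (1, {N_CELLS}), got {self.target_active_cells}"
            )
        if not (0.0 <= self.target_smc < 1.0):
            raise GenerationError("target_smc must lie in [0, 1)")
        if self.target_smc > _MAX_SMC:
            raise GenerationError(
                "target_smc incompatible with the explorative filter: the explored "
                f"face must change at least one cell per step (SMC <= {_MAX_SMC:.4f})"
            )
        # two consecutive maps with ~a active cells differ in at most ~2a cells
        if N_CELLS * (1.0 - self.target_smc) > 2.0 * self.target_active_cells:
            raise GenerationError(
                "target_smc incompatible with target_active_cells bounds: "
                f"{N_CELLS * (1.0 - self.target_smc):.2f} mismatching cells per step "
                f"requested, but maps with ~{self.target_active_cells:.2f} active cells "
                f"can sustain at most ~{2 * self.target_active_cells:.2f}"
            )
        if self.rotation_speed <= 0:
            raise GenerationError("rotation_speed must be positive")
        if self.n_episodes < 1 or self.trial_duration <= 2 * LEAD_S:
            raise GenerationError("need at least one episode and a usable trial duration")


def published_presets() -> dict[str, GroupPreset]:
    """Published group-level targets for the CB / LB / SI cohorts."""
    return {
        "CB": GroupPreset(target_active_cells=5.24, target_smc=0.77, total_rotation=560.0, accuracy=0.72),
        "LB": GroupPreset(target_active_cells=4.32, target_smc=0.81, total_rotation=517.0, accuracy=0.77),
        "SI": GroupPreset(target_active_cells=4.14, target_smc=0.80, total_rotation=710.0, accuracy=0.69),
    }


# ---------------------------------------------------------------------------
# calibrated active-cell distribution


def _truncated_poisson_pmf(rate: float) -> np.ndarray:
    k = np.arange(1, N_CELLS + 1)
    pmf = poisson.pmf(k, rate)
    return pmf / pmf.sum()


def calibrated_cell_pmf(target_mean: float) -> np.ndarray:
    """Poisson pmf truncated to [1, 16] whose mean equals the target.

    Plain truncation shifts the mean above the rate (appreciably for small
    targets), which would bias parameter recovery; the rate is root-solved so
    the truncated mean hits the target exactly.
    """
    k = np.arange(1, N_CELLS + 1)

    def mean_err(rate: float) -> float:
        pmf = _truncated_poisson_pmf(rate)
        return float((pmf * k).sum()) - target_mean

    rate = brentq(mean_err, 1e-6, 60.0, xtol=1e-10)
    return _truncated_poisson_pmf(rate)


# ---------------------------------------------------------------------------
# per-trial ground-truth script


@dataclass
class EpisodePlan:
    face: int
    target_label: str | None  # None: rotation budget exhausted, explore in place
    label: str = ""  # actual relative label during the episode
    reorientation_deg: float = 0.0
    spin_deg: float = 0.0
    dwell_s: float = 0.0


@dataclass
class TrialScript:
    trial_index: int
    phase: str
    t_start: float = 0.0
    t_end: float = 0.0
    episodes: list[EpisodePlan] = field(default_factory=list)
    axis_cumulative: np.ndarray = field(default_factory=lambda: np.zeros(3))
    onset_count: int = 0

    @property
    def faces(self) -> list[int]:
        return [e.face for e in self.episodes]

    @property
    def max_axis_cumulative(self) -> float:
        return float(self.axis_cumulative.max())


@dataclass
class SimulationScript:
    seed: int
    participant_id: str
    group: str
    preset: GroupPreset
    trials: list[TrialScript] = field(default_factory=list)


# ---------------------------------------------------------------------------
# planning helpers


def _face_axis(face: int) -> int:
    return (face - 1) // 2


def _shortest_arc(v_from: np.ndarray, v_to: np.ndarray) -> Rotation:
    cross = np.cross(v_from, v_to)
    dot = float(np.dot(v_from, v_to))
    angle = math.atan2(float(np.linalg.norm(cross)), dot)
    if angle < 1e-12:
        return Rotation.identity()
    if np.linalg.norm(cross) < 1e-12:  # antipodal: any orthogonal axis works
        helper = np.array([0.0, 1.0, 0.0]) if abs(v_from[0]) > 0.9 else np.array([1.0, 0.0, 0.0])
        cross = np.cross(v_from, helper)
    axis = cross / np.linalg.norm(cross)
    return Rotation.from_rotvec(axis * angle)


def _segment_axis_traversal(rot: Rotation, delta: Rotation) -> np.ndarray:
    """Exact per-body-axis traversal (deg) of a fixed-axis world rotation.

    A body axis at angle phi from the (world) rotation axis sweeps
    angle * sin(phi); the angle to the axis is invariant during the segment.
    """
    rotvec = delta.as_rotvec()
    angle = float(np.linalg.norm(rotvec))
    if angle < 1e-12:
        return np.zeros(3)
    axis = rotvec / angle
    world_axes = rot.as_matrix().T  # rows: body axes in world coordinates
    sin_phi = np.linalg.norm(np.cross(world_axes, axis), axis=1)
    return np.degrees(angle) * sin_phi


def _plan_trial(
    preset: GroupPreset,
    rng: np.random.Generator,
    rot0: Rotation,
    preferred_label: str,
) -> list[EpisodePlan]:
    """Draft the episode sequence: faces, target labels, dwells, spins.

    Reorientation angles and axis traversals are estimated here to budget the
    rotation target and the dwell times; the executor recomputes the exact
    geometry (spins shift subsequent normals) and records the actual
    cumulative traversal in the script.
    """
    labels = list(_LABEL_DIRS)
    weights = np.array([preset.episode_policy if l == preferred_label else 1.0 for l in labels])
    weights = weights / weights.sum()
    explorable = [f for f in range(1, N_FACES + 1) if f != HOLDING_FACE]

    faces: list[int] = []
    for _ in range(preset.n_episodes):
        options = [f for f in explorable if not faces or f != faces[-1]]
        faces.append(int(rng.choice(options)))

    rot = rot0
    cum = np.zeros(3)
    plans: list[EpisodePlan] = []
    min_dwell = 0.4
    reorient_time = 0.0
    budget = preset.trial_duration - 2 * LEAD_S
    for face in faces:
        if cum.max() < preset.total_rotation:
            target = str(rng.choice(labels, p=weights))
            normal_world = rot.apply(FACE_NORMALS[face - 1])
            delta = _shortest_arc(normal_world, _LABEL_DIRS[target])
        else:
            target = None
            delta = Rotation.identity()
        angle = math.degrees(float(np.linalg.norm(delta.as_rotvec())))
        # keep the trial inside its time budget: stop adding episodes rather
        # than overrunning (short trials simply get fewer episodes)
        needed = reorient_time + angle / preset.rotation_speed + min_dwell * (len(plans) + 1)
        if plans and needed > budget:
            break
        cum += _segment_axis_traversal(rot, delta)
        rot = delta * rot
        reorient_time += angle / preset.rotation_speed
        plans.append(EpisodePlan(face=face, target_label=target, reorientation_deg=angle))

    explore_time = budget - reorient_time
    if explore_time < min_dwell * len(plans):
        raise GenerationError(
            "trial_duration too short for even one episode at this rotation_speed"
        )
    shares = rng.dirichlet(np.full(len(plans), 8.0))
    dwells = min_dwell + shares * (explore_time - min_dwell * len(plans))
    for p, d in zip(plans, dwells):
        p.dwell_s = float(d)

    # make up any rotation deficit with in-place spins about the explored
    # face's normal (these preserve that face's relative label); a spin adds
    # its angle to the two body axes orthogonal to the spin axis
    for _ in range(4):
        deficit = preset.total_rotation - cum.max()
        if deficit <= 1e-9:
            break
        j_max = int(np.argmax(cum))
        for p in plans:
            deficit = preset.total_rotation - cum.max()
            if deficit <= 1e-9:
                break
            axis = _face_axis(p.face)
            if axis == j_max:
                continue
            budget = 0.8 * p.dwell_s * preset.rotation_speed - p.spin_deg
            alpha = float(min(deficit, budget, 90.0))
            if alpha <= 0:
                continue
            p.spin_deg += alpha
            cum[[a for a in range(3) if a != axis]] += alpha

    return plans


def _append_keyframes(
    keyframes: list[tuple[float, Rotation]],
    t0: float,
    duration: float,
    rot_from: Rotation,
    delta: Rotation,
) -> Rotation:
    """Add sub-90-degree keyframes for a fixed-axis rotation segment."""
    rotvec = delta.as_rotvec()
    angle = float(np.degrees(np.linalg.norm(rotvec)))
    if angle < 1e-9 or duration <= 0:
        return rot_from
    n_chunks = max(1, int(math.ceil(angle / 90.0)))
    for c in range(1, n_chunks + 1):
        frac = c / n_chunks
        keyframes.append((t0 + duration * frac, Rotation.from_rotvec(rotvec * frac) * rot_from))
    return delta * rot_from


# ---------------------------------------------------------------------------
# touch-map evolution on the explored face


class _ExploredFace:
    """Redraws one face's 16-cell map with controlled per-step SMC.

    The active-cell count follows a Metropolis +/-1 random walk whose
    stationary law is the calibrated truncated Poisson, so the mean count
    recovers the target exactly while consecutive counts stay close. Per
    redraw, k cells are flipped with k tracking 16 * (1 - target SMC) through
    an error accumulator (a flip count must match the count change in parity
    and respect the 16-cell budget, so individual steps round; the carry
    keeps the long-run mean exact). k >= 1 keeps the face the minimum-SMC
    face at every redraw.
    """

    REFRESH_PERIOD = 3  # redraws between new active-count targets

    def __init__(
        self, cell_pmf: np.ndarray, target_smc: float, target_cells: float, rng: np.random.Generator
    ):
        self.cell_pmf = cell_pmf
        self.k_target = N_CELLS * (1.0 - target_smc)
        self.mean_target = target_cells
        self.carry = 0.0
        self.count_err = 0.0
        self.rng = rng
        self.map = np.zeros(N_CELLS, dtype=np.uint8)
        self.count_target = 0
        self.steps_since_refresh = 0

    def _draw_count(self, minimum: int = 1) -> int:
        pmf = self.cell_pmf
        if minimum > 1:
            pmf = pmf.copy()
            pmf[: minimum - 1] = 0.0
            pmf = pmf / pmf.sum()
        return int(self.rng.choice(N_CELLS, p=pmf)) + 1

    def activate(self) -> None:
        # at least two cells, so the activation outranks the one-cell holding
        # transition at the trial's first explored sample
        a = self._draw_count(minimum=2)
        self.map[:] = 0
        self.map[self.rng.choice(N_CELLS, size=a, replace=False)] = 1
        self.count_target = a
        self.steps_since_refresh = 0
        self.count_err = float(np.clip(self.count_err + a - self.mean_target, -30, 30))

    def _count_step(self, a_cur: int) -> int:
        """Always-moving +/-1 count dynamics with exact long-run mean.

        The count ramps toward a truncated-Poisson target refreshed every few
        redraws (giving the count its spread and fast mixing); on target it
        oscillates +/-1, with an error accumulator steering the excursions so
        the time-averaged count equals the preset target exactly. Moving
        every step keeps the flip count odd and >= 1, so every redraw is an
        explorative event and the flip budget is never forced to skip frames
        selectively.
        """
        self.steps_since_refresh += 1
        if self.steps_since_refresh >= self.REFRESH_PERIOD:
            self.count_target = self._draw_count()
            self.steps_since_refresh = 0
        if a_cur < self.count_target:
            d = 1
        elif a_cur > self.count_target:
            d = -1
        else:
            d = -1 if self.count_err > 0 else 1
            if not 1 <= a_cur + d <= N_CELLS:
                d = -d
        self.count_err = float(np.clip(self.count_err + (a_cur + d) - self.mean_target, -30, 30))
        return d

    def redraw(self) -> None:
        a_cur = int(self.map.sum())
        d = self._count_step(a_cur)
        k_des = self.k_target + self.carry
        k = int(round(k_des))
        if (k - d) % 2 != 0:  # flip count and count change must share parity
            k += 1 if k < k_des else -1
        k = max(k, abs(d), 1)
        if (k - d) % 2 != 0:
            k += 1
        extra = (k - abs(d)) // 2
        extra = max(min(extra, a_cur - max(0, -d), (N_CELLS - a_cur) - max(0, d)), 0)
        off = max(0, -d) + extra
        on = max(0, d) + extra
        self.carry = float(np.clip(self.carry + self.k_target - (off + on), -4.0, 4.0))
        active = np.flatnonzero(self.map == 1)
        inactive = np.flatnonzero(self.map == 0)
        if off:
            self.map[self.rng.choice(active, size=off, replace=False)] = 0
        if on:
            self.map[self.rng.choice(inactive, size=on, replace=False)] = 1

    def clear(self) -> None:
        self.map[:] = 0


# ---------------------------------------------------------------------------
# session generation


def generate_session(
    preset: GroupPreset,
    n_trials: int = 3,
    seed: int = 0,
    participant_id: str = "P00",
    group: str = "SI",
    participant_frame: ParticipantFrame | None = None,
    regular_sampling: bool = False,
) -> tuple[list[RawSample], list[TrialAnnotation], SimulationScript]:
    """One synthetic session: ``n_trials`` memorization+recall pairs.

    Deterministic in ``seed``. Each trial phase has a 1 s one-cell lead-in
    and tail (exercising the trim rule), episodic exploration of the five
    non-support faces with reorientations executed at the preset rotation
    speed (plus in-place spins when the rotation target needs them), and a
    support face holding a constant two-cell pattern.
    """
    preset.validate()
    frame = participant_frame or ParticipantFrame()
    rng = np.random.default_rng(seed)
    cell_pmf = calibrated_cell_pmf(preset.target_active_cells)
    preferred_label = str(rng.choice(list(_LABEL_DIRS)))

    script = SimulationScript(seed=seed, participant_id=participant_id, group=group, preset=preset)
    annotations: list[TrialAnnotation] = []

    keyframes: list[tuple[float, Rotation]] = [(0.0, Rotation.identity())]
    rot = Rotation.identity()
    # contiguous schedule intervals: (t0, kind, payload)
    intervals: list[tuple[float, str, EpisodePlan | None]] = []
    t = 0.0
    for trial_index in range(1, n_trials + 1):
        for phase in ("memorization", "recall"):
            plans = _plan_trial(preset, rng, rot, preferred_label)
            t_start = t
            cum = np.zeros(3)
            intervals.append((t, "lead", None))
            t += LEAD_S
            for plan in plans:
                if plan.target_label is not None:
                    normal_world = rot.apply(FACE_NORMALS[plan.face - 1])
                    delta = _shortest_arc(normal_world, _LABEL_DIRS[plan.target_label])
                else:
                    delta = Rotation.identity()
                angle = math.degrees(float(np.linalg.norm(delta.as_rotvec())))
                plan.reorientation_deg = angle
                cum += _segment_axis_traversal(rot, delta)
                reorient_s = angle / preset.rotation_speed
                if reorient_s > 1e-9:
                    intervals.append((t, "reorient", None))
                    rot = _append_keyframes(keyframes, t, reorient_s, rot, delta)
                    t += reorient_s
                intervals.append((t, "episode", plan))
                if plan.spin_deg > 0:
                    spin_s = plan.spin_deg / preset.rotation_speed
                    world_axis = rot.apply(np.eye(3)[_face_axis(plan.face)])
                    spin = Rotation.from_rotvec(world_axis * math.radians(plan.spin_deg))
                    cum += _segment_axis_traversal(rot, spin)
                    rot = _append_keyframes(keyframes, t, spin_s, rot, spin)
                plan.label = relative_face_labels(rot, frame)[plan.face]
                t += plan.dwell_s
            intervals.append((t, "tail", None))
            t += LEAD_S
            keyframes.append((t, rot))
            t_end = t
            if phase == "recall":
                truth = str(rng.choice(("same", "different")))
                correct = bool(rng.random() < preset.accuracy)
                response = truth if correct else ("different" if truth == "same" else "same")
            else:
                truth = response = "none"
            annotations.append(
                TrialAnnotation(
                    participant_id=participant_id,
                    group=group,
                    trial_index=trial_index,
                    phase=phase,
                    t_start=round(t_start - 1e-6, 6),  # 6 dp: exact CSV round-trip
                    t_end=round(t_end + 1e-6, 6),
                    response=response,
                    truth=truth,
                )
            )
            script.trials.append(
                TrialScript(
                    trial_index=trial_index,
                    phase=phase,
                    t_start=t_start,
                    t_end=t_end,
                    episodes=plans,
                    axis_cumulative=cum,
                )
            )
            intervals.append((t, "gap", None))
            t += GAP_S
    session_end = t
    keyframes.append((session_end + 1.0, rot))

    # ---- raw timestamps ----------------------------------------------------
    if regular_sampling:  # noise-free: raw stream already on the analysis grid
        times = np.round(np.arange(0.0, session_end, 0.2), 9)
    else:
        a = (SAMPLE_MIN - SAMPLE_MEAN) / SAMPLE_SD
        n_est = int(session_end / SAMPLE_MIN) + 8
        steps = truncnorm.rvs(a, np.inf, loc=SAMPLE_MEAN, scale=SAMPLE_SD, size=n_est, random_state=rng)
        times = np.concatenate([[0.0], np.cumsum(steps)])
        times = np.round(times[times <= session_end], 9)

    # ---- orientations (vectorized slerp over the keyframe timeline) --------
    kf_times = np.array([k[0] for k in keyframes])
    kf_times = np.maximum.accumulate(kf_times + 1e-9 * np.arange(len(kf_times)))
    kf_rots = Rotation.concatenate([k[1] for k in keyframes])
    quats = np.atleast_2d(
        rotation_to_quat(Slerp(kf_times, kf_rots)(np.clip(times, kf_times[0], kf_times[-1])))
    )

    # ---- touch maps ---------------------------------------------------------
    starts = np.array([iv[0] for iv in intervals])
    idx = np.clip(np.searchsorted(starts, times + 1e-12, side="right") - 1, 0, len(intervals) - 1)
    explored = _ExploredFace(cell_pmf, preset.target_smc, preset.target_active_cells, rng)
    samples: list[RawSample] = []
    current_plan: EpisodePlan | None = None
    last_window = -1  # the map advances at most once per 0.2 s analysis window,
    # so consecutive distinct grid maps always differ by exactly one redraw
    grid_dt = 0.2
    for i, tt in enumerate(times):
        _, kind, plan = intervals[idx[i]]
        window = int(math.floor(tt / grid_dt + 1e-9))
        touch = np.zeros((N_FACES, N_CELLS), dtype=np.uint8)
        if kind in ("lead", "tail"):
            touch[HOLDING_FACE - 1, HOLDING_CELLS[0]] = 1
        elif kind in ("reorient", "episode"):
            touch[HOLDING_FACE - 1, list(HOLDING_CELLS)] = 1
        if kind == "episode":
            if plan is not current_plan:
                explored.activate()
                current_plan = plan
            elif window > last_window:
                explored.redraw()
            touch[plan.face - 1] = explored.map
        elif current_plan is not None:
            explored.clear()
            current_plan = None
        last_window = window
        samples.append(RawSample._trusted(float(tt), touch, quats[i]))

    # ground-truth onset tally: 0->1 events on non-support faces in the raw maps
    sample_times = np.array([s.t for s in samples])
    for trial in script.trials:
        lo = int(np.searchsorted(sample_times, trial.t_start - 1e-9, side="left"))
        hi = int(np.searchsorted(sample_times, trial.t_end + 1e-9, side="right"))
        onsets = 0
        for prev, cur in zip(samples[lo : hi - 1], samples[lo + 1 : hi]):
            d = (cur.touch == 1) & (prev.touch == 0)
            d[HOLDING_FACE - 1] = False
            onsets += int(d.sum())
        trial.onset_count = onsets

    return samples, annotations, script


# ---------------------------------------------------------------------------
# cohorts


def generate_cohort(
    n_per_group: dict[str, int] | None = None,
    seed: int = 0,
    presets: dict[str, GroupPreset] | None = None,
    n_trials: int = 3,
    jitter_sd: float = 0.05,
    duration_cell_coupling: float = 0.0,
) -> list[tuple[list[RawSample], list[TrialAnnotation], SimulationScript]]:
    """Synthetic cohort with per-participant jitter around the group presets.

    Defaults to the study's post-exclusion cohort sizes (CB 6, LB 10, SI 16).
    Each participant's targets are jittered by a relative Gaussian of SD
    ``jitter_sd``. With ``duration_cell_coupling`` = c > 0, a participant
    whose jittered active-cell target is higher explores for a shorter time
    (duration scaled by (group target / jittered target)^c) — the planted
    effect behind the directed duration correlations.
    """
    n_per_group = n_per_group or {"CB": 6, "LB": 10, "SI": 16}
    presets = presets or published_presets()
    master = np.random.SeedSequence(seed)
    sessions = []
    for group in sorted(n_per_group):
        base = presets[group]
        n = n_per_group[group]
        grng = np.random.default_rng(master.spawn(1)[0])
        # centered deviates: each cohort realizes the group-level targets
        # exactly while keeping the between-participant spread
        dev = grng.normal(0.0, jitter_sd, size=(n, 3))
        dev -= dev.mean(axis=0)
        session_seeds = grng.integers(2**31, size=n)
        for i in range(n):
            cells = float(np.clip(base.target_active_cells * (1 + dev[i, 0]), 1.2, 14.0))
            smc = float(np.clip(base.target_smc * (1 + dev[i, 1]), 0.3, _MAX_SMC - 1e-3))
            rot_total = float(max(base.total_rotation * (1 + dev[i, 2]), 60.0))
            duration = base.trial_duration
            if duration_cell_coupling:
                duration *= (base.target_active_cells / cells) ** duration_cell_coupling
            preset = replace(
                base,
                target_active_cells=cells,
                target_smc=smc,
                total_rotation=rot_total,
                trial_duration=float(np.clip(duration, 12.0, 240.0)),
            )
            sessions.append(
                generate_session(
                    preset,
                    n_trials=n_trials,
                    seed=int(session_seeds[i]),
                    participant_id=f"{group}{i + 1:02d}",
                    group=group,
                )
            )
    return sessions
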