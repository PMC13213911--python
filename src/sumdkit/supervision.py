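"""The SuMD controller.

Supervised molecular dynamics accelerates binding-event sampling without
biasing forces: short unbiased MD steps (default 300 ps) are run, the
ligand–receptor centre-of-mass distance is recorded at every saved frame,
a line is fitted to distance vs time, and the step is retained only if the
slope is negative (the ligand is approaching).  Rejected steps are re-run
from the same coordinates with freshly resampled velocities.  A productive
step's final coordinates seed the next step.

This implementation adds the two-phase protocol for binders with both a
disordered, charged segment and a structured core: phase 1 supervises the
disordered segment's approach to the receptor; once that segment is
stably in contact (a configurable fraction of a productive step's frames
below a switch distance), supervision switches to the structured core.

Determinism: each attempt's velocity-resampling and dynamics seeds are
derived from ``(master_seed, productive-step counter, attempt counter)``
via ``numpy.random.SeedSequence([master_seed, step, attempt])`` — never
from the wall clock — so any run replays exactly from its configuration.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .engine import DynamicsEngine, EngineError, EngineState
from .topology import (
    Frame,
    MolecularSystem,
    Selection,
    Trajectory,
    com_distance,
)


class Decision(str, enum.Enum):
    PRODUCTIVE = "productive"
    REJECTED = "rejected"


class Status(str, enum.Enum):
    REACHED_TARGET = "reached_target"
    EXHAUSTED_RETRIES = "exhausted_retries"
    EXHAUSTED_STEPS = "exhausted_steps"


@dataclass
class SupervisionPhase:
    """One stage of the supervision protocol.

    ``switch_distance``/``switch_fraction`` define the phase-exit rule: the
    phase ends after a productive step in which at least ``switch_fraction``
    of the saved frames have supervised distance below ``switch_distance``.
    The final phase instead carries ``target_distance``, the protocol
    termination criterion (reached when a productive step's final frame is
    below it).
    """

    name: str
    ligand_sel: Selection
    receptor_sel: Selection
    step_length: float = 300.0  # ps
    slope_threshold: float = 0.0  # Å/ps; productive iff slope < threshold
    switch_distance: float | None = None  # Å
    switch_fraction: float = 1.0
    target_distance: float | None = None  # Å, final phase only

    def __post_init__(self) -> None:
        if self.step_length <= 0:
            raise ValueError("step_length must be > 0")
        if not (0 < self.switch_fraction <= 1):
            raise ValueError("switch_fraction must be in (0, 1]")


@dataclass
class SuMDProtocol:
    phases: list[SupervisionPhase]
    max_retries_per_step: int = 20
    max_productive_steps: int = 100
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("protocol needs at least one phase")
        if self.max_retries_per_step <= 0 or self.max_productive_steps <= 0:
            raise ValueError("retry/step budgets must be positive")
        for ph in self.phases[:-1]:
            if ph.switch_distance is None:
                raise ValueError(
                    f"non-final phase {ph.name!r} must define switch_distance"
                )
        last = self.phases[-1]
        if last.switch_distance is None and last.target_distance is None:
            # permitted: run to max_productive_steps
            pass


@dataclass
class StepRecord:
    """Audit record of one attempted SuMD step (productive or not)."""

    phase_name: str
    step_index: int  # productive-step counter at the time of the attempt
    attempt_index: int
    seed: int
    distance_series: list[tuple[float, float]]  # (time ps, distance Å)
    slope: float  # Å/ps
    decision: Decision
    frames_kept: int
    snapshot_interval: float | None = None  # provenance: frame spacing, ps

    def to_json_dict(self) -> dict:
        return {
            "phase_name": self.phase_name,
            "step_index": self.step_index,
            "attempt_index": self.attempt_index,
            "seed": self.seed,
            "distance_series": [[t, d] for t, d in self.distance_series],
            "slope": self.slope,
            "decision": self.decision.value,
            "frames_kept": self.frames_kept,
            "snapshot_interval": self.snapshot_interval,
        }


@dataclass
class SuMDResult:
    trajectory: Trajectory
    step_log: list[StepRecord]
    status: Status
    phase_boundaries: list[int] = field(default_factory=list)  # start frame per phase

    @property
    def productive_records(self) -> list[StepRecord]:
        return [r for r in self.step_log if r.decision is Decision.PRODUCTIVE]


def fit_slope(distance_series: Sequence[tuple[float, float]]) -> float:
    """Ordinary least-squares slope of distance vs time, Å/ps."""
    if len(distance_series) < 2:
        raise ValueError("need at least 2 points to fit a slope")
    t = np.array([p[0] for p in distance_series], dtype=float)
    d = np.array([p[1] for p in distance_series], dtype=float)
    tc = t - t.mean()
    denom = float(tc @ tc)
    if denom == 0.0:
        raise ValueError("all times equal; slope undefined")
    return float(tc @ (d - d.mean()) / denom)


def evaluate_step(
    segment: Trajectory,
    system: MolecularSystem,
    phase: SupervisionPhase,
    step_index: int = 0,
    attempt_index: int = 0,
    seed: int = 0,
) -> StepRecord:
    """Supervise one step segment: distance per frame, OLS slope, decision.

    Productive iff slope < ``phase.slope_threshold`` (strict: a perfectly
    flat series under the default threshold 0 is rejected — no progress
    means resample).
    """
    if len(segment) == 0:
        raise ValueError("empty step segment")
    series = [
        (f.time, com_distance(f, system, phase.ligand_sel, phase.receptor_sel))
        for f in segment
    ]
    # a single saved frame defines no trend: slope 0 (rejected at threshold 0)
    slope = fit_slope(series) if len(series) > 1 else 0.0
    decision = Decision.PRODUCTIVE if slope < phase.slope_threshold else Decision.REJECTED
    return StepRecord(
        phase_name=phase.name,
        step_index=step_index,
        attempt_index=attempt_index,
        seed=seed,
        distance_series=series,
        slope=slope,
        decision=decision,
        frames_kept=len(segment) if decision is Decision.PRODUCTIVE else 0,
    )


def check_phase_switch(record: StepRecord, phase: SupervisionPhase) -> bool:
    """Has the supervised group stabilised below the phase switch distance?

    True iff ``switch_distance`` is set and at least ``switch_fraction`` of
    the record's distances lie strictly below it.  Evaluated on every
    attempted step, productive or rejected: a group that has settled at
    its contact floor produces flat (hence rejected) slopes, and exactly
    that stabilisation is the phase-exit signal.
    """
    if phase.switch_distance is None:
        return False
    dists = np.array([d for _, d in record.distance_series])
    frac = float(np.mean(dists < phase.switch_distance))
    return frac >= phase.switch_fraction


def derive_seeds(master_seed: int, step: int, attempt: int) -> tuple[int, int]:
    """(velocity seed, dynamics seed) for one attempt, each < 2^31.

    Deterministic split via SeedSequence([master_seed, step, attempt]).
    """
    ss = np.random.SeedSequence([master_seed, step, attempt])
    a, b = ss.generate_state(2)
    return int(a & 0x7FFFFFFF), int(b & 0x7FFFFFFF)


def stitch(
    records: Sequence[StepRecord],
    segments: Sequence[Trajectory],
    system: MolecularSystem | None = None,
) -> Trajectory:
    """Merge productive segments into one trajectory with a global clock.

    Times are re-offset so each segment continues from the previous end,
    preserving the segment's internal frame spacing.  Zero segments give a
    valid empty trajectory (a topology must then be supplied).
    """
    if len(records) != len(segments):
        raise ValueError("records and segments must align")
    if not segments:
        if system is None:
            raise ValueError("empty stitch needs an explicit topology")
        return Trajectory(system=system, frames=[])
    frames: list[Frame] = []
    t_end = 0.0
    for rec, seg in zip(records, segments):
        if rec.decision is not Decision.PRODUCTIVE:
            raise ValueError("stitch accepts productive segments only")
        times = seg.times
        if len(seg) > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("segment times are not strictly increasing")
        # spacing inferred from the segment itself (uniform by engine contract)
        if len(seg) > 1:
            spacing = float(times[1] - times[0])
        else:
            spacing = float(times[0]) if times[0] > 0 else 1.0
        for k, f in enumerate(seg):
            frames.append(
                Frame(
                    coordinates=f.coordinates,
                    velocities=f.velocities,
                    time=t_end + (k + 1) * spacing,
                )
            )
        t_end = frames[-1].time
    return Trajectory(system=segments[0].system, frames=frames)


def run_sumd(
    engine: DynamicsEngine,
    start: EngineState,
    protocol: SuMDProtocol,
    on_record=None,
) -> SuMDResult:
    """Run the full supervised protocol.

    Loop per attempt: derive child seeds from (master_seed, step, attempt);
    resample velocities; advance one step length; supervise.  Productive →
    keep the frames, continue from the segment's final state (velocities
    are resampled again at the next attempt regardless), check the phase
    switch and the termination target.  Rejected → restore the pre-step
    coordinates and retry with the next attempt seed, up to the retry
    budget.  Every attempt is logged.  An engine blow-up aborts but
    preserves the partial log.
    """
    system = engine.system
    state = start
    phase_idx = 0
    step = 0  # productive-step counter
    log: list[StepRecord] = []
    kept_records: list[StepRecord] = []
    kept_segments: list[Trajectory] = []
    boundaries: list[int] = [0]
    frames_so_far = 0
    status: Status | None = None

    try:
        while status is None:
            phase = protocol.phases[phase_idx]
            final_phase = phase_idx == len(protocol.phases) - 1
            productive = None
            switched_on_rejection = False
            for attempt in range(protocol.max_retries_per_step):
                vel_seed, dyn_seed = derive_seeds(protocol.master_seed, step, attempt)
                trial = engine.resample_velocities(state, seed=vel_seed)
                segment, end_state = engine.advance(trial, phase.step_length, dyn_seed)
                record = evaluate_step(
                    segment, system, phase, step_index=step, attempt_index=attempt,
                    seed=dyn_seed,
                )
                if len(segment) > 1:
                    record.snapshot_interval = float(segment.times[1] - segment.times[0])
                log.append(record)
                if on_record is not None:
                    on_record(record)
                if record.decision is Decision.PRODUCTIVE:
                    productive = (record, segment, end_state)
                    break
                # rejected: a group already settled at its contact floor
                # yields flat slopes forever — stabilisation still ends the
                # phase (frames are not retained; the pre-step coordinates
                # are already in stable contact)
                if not final_phase and check_phase_switch(record, phase):
                    switched_on_rejection = True
                    break
                if final_phase and phase.target_distance is not None:
                    dists = np.array([d for _, d in record.distance_series])
                    if np.mean(dists < phase.target_distance) >= 0.5:
                        status = Status.REACHED_TARGET
                        break
            if status is Status.REACHED_TARGET:
                break
            if switched_on_rejection:
                phase_idx += 1
                boundaries.append(frames_so_far)
                continue
            if productive is None:
                status = Status.EXHAUSTED_RETRIES
                break
            record, segment, state = productive
            kept_records.append(record)
            kept_segments.append(segment)
            frames_so_far += record.frames_kept
            step += 1

            if not final_phase and check_phase_switch(record, phase):
                phase_idx += 1
                boundaries.append(frames_so_far)
            elif final_phase and phase.target_distance is not None:
                if record.distance_series[-1][1] < phase.target_distance:
                    status = Status.REACHED_TARGET
            if status is None and step >= protocol.max_productive_steps:
                status = Status.EXHAUSTED_STEPS
    except EngineError:
        # abort, but keep what we have; callers inspect the partial log
        status = Status.EXHAUSTED_STEPS if status is None else status
        raise

    traj = stitch(kept_records, kept_segments, system=system)
    return SuMDResult(
        trajectory=traj, step_log=log, status=status, phase_boundaries=boundaries
    )


def run_unsupervised(
    engine: DynamicsEngine,
    start: EngineState,
    phase: SupervisionPhase,
    max_steps: int,
    master_seed: int,
) -> tuple[float | None, int]:
    """Plain dynamics with identical step bookkeeping but no acceptance test.

    Runs chunks of ``phase.step_length`` with velocities resampled before
    each chunk (every chunk is "accepted"), and returns (time at which the
    supervised distance first fell below ``phase.target_distance``, chunks
    run).  The time is None if the target was never reached — the natural
    baseline for supervised-vs-unsupervised efficacy comparisons.
    """
    if phase.target_distance is None:
        raise ValueError("baseline needs a target_distance")
    state = start
    for step in range(max_steps):
        vel_seed, dyn_seed = derive_seeds(master_seed, step, 0)
        trial = engine.resample_velocities(state, seed=vel_seed)
        segment, state = engine.advance(trial, phase.step_length, dyn_seed)
        for f in segment:
            d = com_distance(f, engine.system, phase.ligand_sel, phase.receptor_sel)
            if d < phase.target_distance:
                return float(f.time - start.time), step + 1
    return None, max_steps
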