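"""Interleaved dual adaptive staircases for per-participant calibration.

Two staircases run simultaneously on one stimulus continuum, starting at
opposite endpoints, with strictly alternating trials.  A response is
"correct" when it matches the label of the staircase's own starting end.
Two consecutive correct identifications advance the staircase toward the
far end; any incorrect identification is a *reversal* and moves it back
toward its own end.  Material continua (10 steps) always move one step;
colour continua (50 steps) use accelerated schedules — progressions of
5, 4, 2 then 1 steps and regressions of 4, 3, 2 then 1 steps, keyed to
the number of incorrect identifications so far.  After five reversals
the participant must correctly label the current stimulus once more,
which terminates the staircase.

From a terminated staircase we extract:

* the **low-discriminability** stimulus — the stimulus of the final
  correct identification, which sits near the participant's category
  boundary; and
* the **high-discriminability** stimulus — the latest stimulus that was
  correctly identified before any reversal at a step index <= 2 (i.e.
  still close to the staircase's own prototypical end).

A participant's calibration for an attribute succeeds only if all four
stimuli (high/low for both categories) were identified.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "AttributeCalibration",
    "CalibrationResult",
    "MATERIAL_STAIRCASE",
    "COLOUR_STAIRCASE",
    "update_staircase",
    "extract_low_disc",
    "extract_high_disc",
    "run_dual_staircase",
    "write_session_log",
    "write_calibration_manifest",
]


@dataclass(frozen=True)
class StaircaseConfig:
    """Step rules for one attribute's staircases.

    ``progression_schedule`` and ``regression_schedule`` give jump sizes
    indexed by the number of prior incorrect identifications (the last
    entry repeats indefinitely).
    """

    n_steps: int
    kind: str  # "material" | "colour"
    consecutive_correct_required: int = 2
    progression_schedule: tuple[int, ...] = (1,)
    regression_schedule: tuple[int, ...] = (1,)
    reversals_to_terminate: int = 5
    high_disc_max_step: int = 2

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        for sched in (self.progression_schedule, self.regression_schedule):
            if not sched or any(j < 1 for j in sched):
                raise ValueError("schedules must be non-empty with jumps >= 1")
            if any(a < b for a, b in zip(sched, sched[1:])):
                raise ValueError("schedules must be non-increasing")

    def progression_jump(self, n_incorrect: int) -> int:
        """Jump size given the number of incorrect identifications so far."""
        i = min(n_incorrect, len(self.progression_schedule) - 1)
        return self.progression_schedule[i]

    def regression_jump(self, n_incorrect: int) -> int:
        """Jump size for the ``n_incorrect``-th incorrect identification (1-based)."""
        i = min(n_incorrect - 1, len(self.regression_schedule) - 1)
        return self.regression_schedule[i]


#: 10-step material staircase: one-step moves in both directions.
MATERIAL_STAIRCASE = StaircaseConfig(n_steps=10, kind="material")

#: 50-step colour staircase: accelerated 5/4/2/1 progressions, 4/3/2/1 regressions.
COLOUR_STAIRCASE = StaircaseConfig(
    n_steps=50,
    kind="colour",
    progression_schedule=(5, 4, 2, 1),
    regression_schedule=(4, 3, 2, 1),
)


@dataclass(frozen=True)
class TrialRecord:
    """One staircase trial: the position presented, the label chosen, and correctness."""

    position: int
    response_label: str
    correct: bool
    reversals_so_far: int


@dataclass(frozen=True)
class StaircaseState:
    """Evolving state of one staircase, in its own coordinates (1 = own start end)."""

    config: StaircaseConfig
    own_label: str
    other_label: str
    position: int = 1
    n_incorrect: int = 0
    n_reversals: int = 0
    consecutive_correct: int = 0
    terminated: bool = False
    awaiting_confirmation: bool = False
    history: tuple[TrialRecord, ...] = ()


def update_staircase(state: StaircaseState, correct: bool) -> StaircaseState:
    """Apply one response to a staircase and return the new state.

    Correct responses accumulate toward the two-in-a-row criterion; on
    meeting it the position advances by the progression schedule and the
    counter resets.  An incorrect response is a reversal: it resets the
    counter and regresses the position by the regression schedule.  All
    moves clamp to [1, n_steps].  Once the reversal quota is met the
    staircase awaits one further correct identification, which
    terminates it without moving.
    """
    if state.terminated:
        raise RuntimeError("cannot update a terminated staircase")
    cfg = state.config
    record = TrialRecord(
        position=state.position,
        response_label=state.own_label if correct else state.other_label,
        correct=correct,
        reversals_so_far=state.n_reversals,
    )
    history = state.history + (record,)

    if correct:
        if state.awaiting_confirmation:
            # confirmation response: terminate in place
            return replace(state, terminated=True, consecutive_correct=0, history=history)
        streak = state.consecutive_correct + 1
        if streak >= cfg.consecutive_correct_required:
            jump = cfg.progression_jump(state.n_incorrect)
            pos = min(cfg.n_steps, state.position + jump)
            return replace(state, position=pos, consecutive_correct=0, history=history)
        return replace(state, consecutive_correct=streak, history=history)

    n_incorrect = state.n_incorrect + 1
    n_reversals = min(state.n_reversals + 1, cfg.reversals_to_terminate)
    jump = cfg.regression_jump(n_incorrect)
    pos = max(1, state.position - jump)
    awaiting = n_reversals >= cfg.reversals_to_terminate
    return replace(
        state,
        position=pos,
        n_incorrect=n_incorrect,
        n_reversals=n_reversals,
        consecutive_correct=0,
        awaiting_confirmation=awaiting,
        history=history,
    )


def extract_low_disc(state: StaircaseState) -> int:
    """The stimulus of the final correct identification (own coordinates)."""
    if not state.terminated:
        raise RuntimeError("low-discriminability extraction requires a terminated staircase")
    for rec in reversed(state.history):
        if rec.correct:
            return rec.position
    raise ValueError("calibration failure: no correct identification in staircase history")


def extract_high_disc(state: StaircaseState) -> Optional[int]:
    """Latest correctly identified stimulus before any reversal at step <= 2.

    Returns ``None`` when no trial satisfies all three criteria (no
    reversals yet, correct identification, step index within the
    high-discriminability bound); callers treat that as a calibration
    failure for the attribute.
    """
    best: Optional[int] = None
    for rec in state.history:
        if (
            rec.reversals_so_far == 0
            and rec.correct
            and rec.position <= state.config.high_disc_max_step
        ):
            best = rec.position
    return best


@dataclass(frozen=True)
class AttributeCalibration:
    """The four extracted stimuli for one attribute, in absolute continuum indices."""

    label_A: str
    label_B: str
    high_disc_A: Optional[int]
    high_disc_B: Optional[int]
    low_disc_A: Optional[int]
    low_disc_B: Optional[int]
    success: bool
    n_trials: int = 0

    def high_disc(self, label: str) -> int:
        return {self.label_A: self.high_disc_A, self.label_B: self.high_disc_B}[label]

    def low_disc(self, label: str) -> int:
        return {self.label_A: self.low_disc_A, self.label_B: self.low_disc_B}[label]


@dataclass(frozen=True)
class CalibrationResult:
    """Per-attribute calibrations for one participant."""

    attributes: dict

    @property
    def success(self) -> bool:
        return all(c.success for c in self.attributes.values())

    def __getitem__(self, attribute: str) -> AttributeCalibration:
        return self.attributes[attribute]


def _absolute(position: int, n_steps: int, is_far_staircase: bool) -> int:
    """Map a staircase-local position to an absolute continuum index."""
    return n_steps - position + 1 if is_far_staircase else position


def run_dual_staircase(
    responder: Callable[[int, str, str], str],
    config: StaircaseConfig,
    rng: np.random.Generator,
    label_A: str = "A",
    label_B: str = "B",
    trial_cap: int = 500,
    log: Optional[list] = None,
) -> AttributeCalibration:
    """Run the two interleaved staircases for one attribute.

    ``responder(absolute_position, label_A, label_B) -> chosen label``
    models the participant.  Staircase A starts at absolute index 1
    (endpoint A), staircase B at absolute index ``n_steps`` (endpoint B,
    local position 1 maps to absolute ``n_steps - p + 1``).  Trials
    strictly alternate; once one staircase terminates, all remaining
    trials go to the other.  Hitting the trial cap marks the calibration
    as failed.

    ``rng`` is accepted for interface symmetry with stochastic responders
    (the schedule itself is deterministic).
    """
    del rng  # determinism lives in the responder
    states = {
        "A": StaircaseState(config=config, own_label=label_A, other_label=label_B),
        "B": StaircaseState(config=config, own_label=label_B, other_label=label_A),
    }
    order = ("A", "B")
    n_trials = 0
    turn = 0
    while not all(s.terminated for s in states.values()) and n_trials < trial_cap:
        key = order[turn % 2]
        if states[key].terminated:
            key = order[(turn + 1) % 2]
        state = states[key]
        absolute = _absolute(state.position, config.n_steps, is_far_staircase=(key == "B"))
        chosen = responder(absolute, label_A, label_B)
        correct = chosen == state.own_label
        states[key] = update_staircase(state, correct)
        if log is not None:
            log.append({
                "trial": n_trials + 1,
                "staircase": key,
                "kind": config.kind,
                "absolute_position": absolute,
                "stimulus_id": f"{config.kind}:{absolute}",
                "response_label": chosen,
                "correct": correct,
                "reversals_so_far": states[key].n_reversals,
            })
        n_trials += 1
        turn += 1

    completed = all(s.terminated for s in states.values())

    def extract(key: str):
        s = states[key]
        far = key == "B"
        low = extract_low_disc(s) if s.terminated and any(r.correct for r in s.history) else None
        high = extract_high_disc(s)
        to_abs = lambda p: None if p is None else _absolute(p, config.n_steps, far)
        return to_abs(high), to_abs(low)

    high_A, low_A = extract("A")
    high_B, low_B = extract("B")
    success = completed and None not in (high_A, high_B, low_A, low_B)
    return AttributeCalibration(
        label_A=label_A,
        label_B=label_B,
        high_disc_A=high_A,
        high_disc_B=high_B,
        low_disc_A=low_A,
        low_disc_B=low_B,
        success=success,
        n_trials=n_trials,
    )


def write_session_log(path: str | Path, rows: Sequence[dict]) -> None:
    """Write the staircase trial log as CSV."""
    fields = ["trial", "staircase", "kind", "absolute_position", "stimulus_id",
              "response_label", "correct", "reversals_so_far"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        writer.writerows(rows)


def write_calibration_manifest(path: str | Path, result: CalibrationResult) -> None:
    """Write the per-attribute calibration outcome as JSON."""
    payload = {
        attr: {
            "label_A": c.label_A,
            "label_B": c.label_B,
            "high_disc_A": c.high_disc_A,
            "high_disc_B": c.high_disc_B,
            "low_disc_A": c.low_disc_A,
            "low_disc_B": c.low_disc_B,
            "success": c.success,
            "n_trials": c.n_trials,
        }
        for attr, c in result.attributes.items()
    }
    payload["success"] = result.success
    Path(path).write_text(json.dumps(payload, indent=2))
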