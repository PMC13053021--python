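"""Trial construction and referring-expression scoring for the director tasks.

Experiment one ("bat factory"): each trial shows three bats, each with a
colour (visual) and a material impact sound (auditory).  One attribute is
*sufficient* — its value uniquely demarcates the target — and the other
is *redundant* — shared by all three items.  Display types cross the
perceptual discriminability of the two attributes: Baseline (both high),
S-High/R-Low (sufficient high, redundant low) and S-Low/R-High
(sufficient low, redundant high).  Low-discriminability stimuli are the
participant-calibrated boundary stimuli and are always placed on the
target, so speakers must label the boundary stimulus when naming it.

Experiment two: visual arrays of shapes (circle, square, pentagon,
hexagon) varying in one redundant attribute — orientation of stripes, or
colour under high- or low-frequency colour terms.  The target's shape is
always unique on critical trials, so the noun alone suffices; display
density (set size) and contextual distinctiveness (number of items
sharing the target's attribute value) vary within participants.

Expression scoring: an expression denotes the set of display items
matching every mentioned term; it is *identifiable* when that set is
exactly the target.  Among identifiable expressions, one is
*overinformative* when some proper subset of its modifiers (the noun,
when present, is the head and always kept) still identifies the target,
and *minimal* otherwise.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .staircase import AttributeCalibration, CalibrationResult

__all__ = [
    "DisplayType",
    "Feedback",
    "Expression",
    "BatItem",
    "BatTrial",
    "ShapeTrial",
    "MislabelError",
    "build_exp1_display",
    "build_exp1_filler",
    "generate_exp1_session",
    "generate_exp2_session",
    "classify_expression",
    "feedback",
    "write_trial_table",
    "write_expression_records",
    "EXP2_GRID",
    "EXP2_VALUE_PAIRS",
    "SHAPES",
]

# display timing constants (ms): fall, impact sound, post-impact dwell
FALL_MS = 800
SOUND_MS = 1000
DWELL_MS = 1700

SHAPES = ("circle", "square", "pentagon", "hexagon")

#: experiment-two attribute value pairs per between-subject condition
EXP2_VALUE_PAIRS = {
    "orientation": ("horizontal", "vertical"),
    "colour-HF": ("green", "blue"),
    "colour-LF": ("teal", "jade"),
}

#: (set size -> admissible N-distractor levels); each combination occurs twice
EXP2_GRID = {3: (0, 1), 6: (0, 1, 2, 3, 4), 9: (0, 1, 2, 3, 4), 16: (0, 1, 2, 3, 4)}


class DisplayType(str, Enum):
    BASELINE = "baseline"
    S_HIGH_R_LOW = "s-high/r-low"
    S_LOW_R_HIGH = "s-low/r-high"
    FILLER = "filler"


class Feedback(str, Enum):
    THUMBS_UP = "thumbs_up"
    THUMBS_DOWN = "thumbs_down"
    SHRUG = "shrug"


class MislabelError(ValueError):
    """An expression term is outside the trial's vocabulary."""


@dataclass(frozen=True)
class Expression:
    """A structured referring expression: at most one term per attribute slot."""

    colour_term: Optional[str] = None
    material_term: Optional[str] = None
    orientation_term: Optional[str] = None
    noun: Optional[str] = None

    @property
    def modifiers(self) -> dict:
        mods = {}
        if self.colour_term is not None:
            mods["colour"] = self.colour_term
        if self.material_term is not None:
            mods["material"] = self.material_term
        if self.orientation_term is not None:
            mods["orientation"] = self.orientation_term
        return mods

    @property
    def empty(self) -> bool:
        return not self.modifiers and self.noun is None

    def drop(self, attribute: str) -> "Expression":
        kw = {"colour": "colour_term", "material": "material_term",
              "orientation": "orientation_term"}[attribute]
        return Expression(**{**self.__dict__, kw: None})


@dataclass(frozen=True)
class BatItem:
    colour_index: int
    colour_label: str
    material_index: int
    material_label: str
    screen_position: str  # left | middle | right


@dataclass(frozen=True)
class BatTrial:
    """One bat-factory referential scene."""

    items: tuple[BatItem, ...]
    target_index: int
    display_type: DisplayType
    sufficient_attribute: Optional[str]  # "colour" | "material"; None for fillers
    redundant_attribute: Optional[str]
    timing_ms: tuple[int, int, int] = (FALL_MS, SOUND_MS, DWELL_MS)

    @property
    def is_filler(self) -> bool:
        return self.display_type is DisplayType.FILLER

    # --- generic scoring interface ---
    @property
    def n_items(self) -> int:
        return len(self.items)

    def item_label(self, i: int, attribute: str) -> str:
        item = self.items[i]
        return {"colour": item.colour_label, "material": item.material_label}[attribute]

    def item_noun(self, i: int) -> str:
        return "bat"

    def vocabulary(self, attribute: str) -> frozenset:
        return frozenset(self.item_label(i, attribute) for i in range(self.n_items))

    @property
    def attributes(self) -> tuple[str, ...]:
        return ("colour", "material")

    noun_required = False


@dataclass(frozen=True)
class ShapeItem:
    shape: str
    value: str


@dataclass(frozen=True)
class ShapeTrial:
    """One shape-array referential scene (experiment two)."""

    items: tuple[ShapeItem, ...]
    target_index: int
    set_size: int
    n_distractors: int
    condition: str  # orientation | colour-HF | colour-LF
    is_filler: bool = False

    @property
    def attribute(self) -> str:
        return "orientation" if self.condition == "orientation" else "colour"

    @property
    def n_items(self) -> int:
        return len(self.items)

    def item_label(self, i: int, attribute: str) -> str:
        if attribute != self.attribute:
            raise KeyError(attribute)
        return self.items[i].value

    def item_noun(self, i: int) -> str:
        return self.items[i].shape

    def vocabulary(self, attribute: str) -> frozenset:
        return frozenset(EXP2_VALUE_PAIRS[self.condition])

    @property
    def attributes(self) -> tuple[str, ...]:
        return (self.attribute,)

    noun_required = True


# --- experiment one displays -----------------------------------------------

_POSITIONS = ("left", "middle", "right")


def _attribute_assignment(
    cal: AttributeCalibration,
    level: str,
    target_cat: str,
    other_cat: str,
) -> tuple[int, str, int, str]:
    """(target index+label, distractor index+label) for a *sufficient* attribute.

    High-discriminability contrasts oppose the two high-disc stimuli; a
    low-discriminability contrast puts the boundary (low-disc) stimulus
    on the target against the opposite category's high-disc stimulus.
    """
    if level == "high":
        return (cal.high_disc(target_cat), target_cat, cal.high_disc(other_cat), other_cat)
    return (cal.low_disc(target_cat), target_cat, cal.high_disc(other_cat), other_cat)


def build_exp1_display(
    display_type: DisplayType,
    sufficient_attribute: str,
    calibration: CalibrationResult,
    rng: np.random.Generator,
) -> BatTrial:
    """Construct one critical bat-factory trial from a calibration.

    The sufficient attribute contrasts the target against both
    distractors; the redundant attribute is one stimulus shared by all
    three items, at the discriminability level dictated by the display
    type.
    """
    if not calibration.success:
        raise ValueError("cannot build displays from a failed calibration")
    if display_type is DisplayType.FILLER:
        raise ValueError("use build_exp1_filler for filler trials")
    redundant_attribute = "material" if sufficient_attribute == "colour" else "colour"
    suff_level, red_level = {
        DisplayType.BASELINE: ("high", "high"),
        DisplayType.S_HIGH_R_LOW: ("high", "low"),
        DisplayType.S_LOW_R_HIGH: ("low", "high"),
    }[display_type]

    suff_cal = calibration[sufficient_attribute]
    red_cal = calibration[redundant_attribute]
    cats = (suff_cal.label_A, suff_cal.label_B)
    target_cat = cats[rng.integers(2)]
    other_cat = cats[0] if target_cat == cats[1] else cats[1]
    t_idx, t_lab, d_idx, d_lab = _attribute_assignment(suff_cal, suff_level, target_cat, other_cat)

    red_cat = (red_cal.label_A, red_cal.label_B)[rng.integers(2)]
    red_idx = red_cal.high_disc(red_cat) if red_level == "high" else red_cal.low_disc(red_cat)

    target_index = int(rng.integers(3))
    items = []
    for i in range(3):
        suff_idx, suff_lab = (t_idx, t_lab) if i == target_index else (d_idx, d_lab)
        fields = {
            sufficient_attribute + "_index": suff_idx,
            sufficient_attribute + "_label": suff_lab,
            redundant_attribute + "_index": red_idx,
            redundant_attribute + "_label": red_cat,
        }
        items.append(BatItem(screen_position=_POSITIONS[i], **fields))
    return BatTrial(
        items=tuple(items),
        target_index=target_index,
        display_type=display_type,
        sufficient_attribute=sufficient_attribute,
        redundant_attribute=redundant_attribute,
    )


def build_exp1_filler(
    differing_attribute: str,
    calibration: CalibrationResult,
    rng: np.random.Generator,
) -> BatTrial:
    """A filler: all three items identical except the target differs in one attribute.

    Both contrasts use high-discriminability stimuli so the single
    difference is unmistakable; mentioning the shared attribute would be
    overinformative (and draws a shrug).
    """
    if not calibration.success:
        raise ValueError("cannot build displays from a failed calibration")
    shared_attribute = "material" if differing_attribute == "colour" else "colour"
    diff_cal = calibration[differing_attribute]
    shared_cal = calibration[shared_attribute]
    cats = (diff_cal.label_A, diff_cal.label_B)
    target_cat = cats[rng.integers(2)]
    other_cat = cats[0] if target_cat == cats[1] else cats[1]
    shared_cat = (shared_cal.label_A, shared_cal.label_B)[rng.integers(2)]
    shared_idx = shared_cal.high_disc(shared_cat)

    target_index = int(rng.integers(3))
    items = []
    for i in range(3):
        cat = target_cat if i == target_index else other_cat
        fields = {
            differing_attribute + "_index": diff_cal.high_disc(cat),
            differing_attribute + "_label": cat,
            shared_attribute + "_index": shared_idx,
            shared_attribute + "_label": shared_cat,
        }
        items.append(BatItem(screen_position=_POSITIONS[i], **fields))
    return BatTrial(
        items=tuple(items),
        target_index=target_index,
        display_type=DisplayType.FILLER,
        sufficient_attribute=differing_attribute,
        redundant_attribute=shared_attribute,
    )


def generate_exp1_session(
    calibration: CalibrationResult,
    rng: np.random.Generator,
) -> list[BatTrial]:
    """One participant's bat-factory session: 48 critical + 12 filler trials.

    Critical trials are balanced 24/24 by redundant attribute and 16 per
    display type (8 per display-type x redundant-attribute cell); fillers
    split 6/6 by differing attribute.  Presentation order is fully
    randomised.
    """
    trials: list[BatTrial] = []
    critical_types = (DisplayType.BASELINE, DisplayType.S_HIGH_R_LOW, DisplayType.S_LOW_R_HIGH)
    for display_type in critical_types:
        for sufficient in ("colour", "material"):  # sufficient colour => material redundant
            for _ in range(8):
                trials.append(build_exp1_display(display_type, sufficient, calibration, rng))
    for differing in ("colour", "material"):
        for _ in range(6):
            trials.append(build_exp1_filler(differing, calibration, rng))
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


# --- experiment two displays -------------------------------------------------

def _build_exp2_critical(
    set_size: int,
    n_distractors: int,
    condition: str,
    rng: np.random.Generator,
) -> ShapeTrial:
    values = EXP2_VALUE_PAIRS[condition]
    target_value = values[rng.integers(2)]
    other_value = values[0] if target_value == values[1] else values[1]
    target_shape = SHAPES[rng.integers(len(SHAPES))]
    other_shapes = [s for s in SHAPES if s != target_shape]
    target_index = int(rng.integers(set_size))

    non_target_slots = [i for i in range(set_size) if i != target_index]
    sharers = set(rng.choice(non_target_slots, size=n_distractors, replace=False))
    items: list[ShapeItem] = []
    for i in range(set_size):
        if i == target_index:
            items.append(ShapeItem(shape=target_shape, value=target_value))
        else:
            shape = other_shapes[rng.integers(len(other_shapes))]
            value = target_value if i in sharers else other_value
            items.append(ShapeItem(shape=shape, value=value))
    return ShapeTrial(
        items=tuple(items),
        target_index=target_index,
        set_size=set_size,
        n_distractors=n_distractors,
        condition=condition,
        is_filler=False,
    )


def _build_exp2_filler(condition: str, rng: np.random.Generator) -> ShapeTrial:
    """Filler: adjective and noun are jointly required.

    The target's shape is shared with at least one distractor (noun alone
    fails) while its attribute value is unique (adjective + noun
    succeeds).
    """
    set_size = int(rng.choice(list(EXP2_GRID)))
    values = EXP2_VALUE_PAIRS[condition]
    target_value = values[rng.integers(2)]
    other_value = values[0] if target_value == values[1] else values[1]
    target_shape = SHAPES[rng.integers(len(SHAPES))]
    target_index = int(rng.integers(set_size))
    non_target_slots = [i for i in range(set_size) if i != target_index]
    sharer = int(rng.choice(non_target_slots))
    items = []
    for i in range(set_size):
        if i == target_index:
            items.append(ShapeItem(shape=target_shape, value=target_value))
        else:
            shape = target_shape if i == sharer else SHAPES[rng.integers(len(SHAPES))]
            items.append(ShapeItem(shape=shape, value=other_value))
    return ShapeTrial(
        items=tuple(items),
        target_index=target_index,
        set_size=set_size,
        n_distractors=0,
        condition=condition,
        is_filler=True,
    )


def generate_exp2_session(condition: str, rng: np.random.Generator) -> list[ShapeTrial]:
    """One participant's shape session: 34 critical + 14 filler trials.

    Every admissible set-size x N-distractors combination appears exactly
    twice among the critical trials; order, target positions, shapes and
    attribute polarity are randomised.
    """
    if condition not in EXP2_VALUE_PAIRS:
        raise ValueError(f"unknown condition {condition!r}")
    trials: list[ShapeTrial] = []
    for set_size, levels in EXP2_GRID.items():
        for n_d in levels:
            for _ in range(2):
                trials.append(_build_exp2_critical(set_size, n_d, condition, rng))
    for _ in range(14):
        trials.append(_build_exp2_filler(condition, rng))
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


# --- expression scoring ------------------------------------------------------

def _match_set(trial, modifiers: dict, noun: Optional[str]) -> set:
    """Items matching every mentioned term (noun included when present)."""
    matched = set(range(trial.n_items))
    for attribute, term in modifiers.items():
        matched &= {i for i in matched if trial.item_label(i, attribute) == term}
    if noun is not None:
        matched &= {i for i in matched if trial.item_noun(i) == noun}
    return matched


def classify_expression(trial, expression: Expression) -> tuple[str, bool]:
    """Score an expression against a trial.

    Returns ``(category, identifiable)`` with category one of
    ``"underinformative"``, ``"minimal"`` or ``"overinformative"``.  An
    expression identifies the target when the set of items matching all
    its terms is exactly the target.  It is overinformative when some
    proper subset of its modifiers (keeping the noun) still identifies
    the target; because match sets shrink monotonically as terms are
    added, it suffices to test each single-modifier deletion.

    Raises :class:`MislabelError` for terms outside the trial's
    vocabulary, and ``ValueError`` for empty expressions or, on trials
    with an obligatory noun, noun-less expressions.
    """
    if expression.empty:
        raise ValueError("cannot classify an empty expression")
    if trial.noun_required and expression.noun is None:
        raise ValueError("this task requires a noun in every expression")
    modifiers = expression.modifiers
    for attribute, term in modifiers.items():
        if attribute not in trial.attributes:
            raise MislabelError(f"attribute {attribute!r} not present in this trial")
        if term not in trial.vocabulary(attribute):
            raise MislabelError(f"term {term!r} outside the trial's vocabulary")
    if expression.noun is not None:
        nouns = {trial.item_noun(i) for i in range(trial.n_items)}
        if expression.noun not in nouns:
            raise MislabelError(f"noun {expression.noun!r} outside the trial's vocabulary")

    matched = _match_set(trial, modifiers, expression.noun)
    identifiable = matched == {trial.target_index}
    if not identifiable:
        return "underinformative", False
    for attribute in modifiers:
        reduced = {a: t for a, t in modifiers.items() if a != attribute}
        if _match_set(trial, reduced, expression.noun) == {trial.target_index}:
            return "overinformative", True
    return "minimal", True


def feedback(trial, expression: Expression) -> Feedback:
    """Moderate feedback: thumbs-down for failed reference, shrug for
    overinforming on fillers, thumbs-up otherwise."""
    try:
        category, identifiable = classify_expression(trial, expression)
    except MislabelError:
        return Feedback.THUMBS_DOWN
    if not identifiable:
        return Feedback.THUMBS_DOWN
    if category == "overinformative" and trial.is_filler:
        return Feedback.SHRUG
    return Feedback.THUMBS_UP


# --- I/O ---------------------------------------------------------------------

def write_trial_table(path: str | Path, trials: Sequence, session_id: str = "") -> None:
    """One CSV row per display item."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["session", "trial", "item", "role", "kind", "attributes"])
        for t_i, trial in enumerate(trials):
            for i in range(trial.n_items):
                role = "target" if i == trial.target_index else "distractor"
                if isinstance(trial, BatTrial):
                    item = trial.items[i]
                    kind = trial.display_type.value
                    attrs = (f"colour={item.colour_label}:{item.colour_index};"
                             f"material={item.material_label}:{item.material_index}")
                else:
                    item = trial.items[i]
                    kind = "filler" if trial.is_filler else (
                        f"set{trial.set_size}-d{trial.n_distractors}")
                    attrs = f"shape={item.shape};{trial.attribute}={item.value}"
                writer.writerow([session_id, t_i, i, role, kind, attrs])


def write_expression_records(path: str | Path, rows: Sequence[dict]) -> None:
    """One CSV row per trial response."""
    if not rows:
        Path(path).write_text("")
        return
    fields = list(rows[0].keys())
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        writer.writerows(rows)
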