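"""Simulated participants: psychometric observers and logit-linear speakers.

The observer is a standard lapse-rate logistic psychometric model over
continuum position: with boundary ``b``, slope scale ``sigma`` and lapse
rate ``gamma``, the probability of categorising the stimulus at absolute
position ``x`` as the far-end category is

    P(far | x) = gamma/2 + (1 - gamma) * logistic((x - b) / sigma)

and the complementary probability for the near-end category.  Observers
answer the staircases and supply the mislabelling behaviour of speakers
(a speaker names a stimulus's category by sampling the observer's
response at its position, so boundary stimuli are mislabelled often and
prototypical stimuli almost never).

The speaker is the generative counterpart of the analysis model: on each
trial it produces the minimal sufficient expression and upgrades it to
the overinformative one with probability ``logistic(x'beta + u_j)``,
where ``x`` is the trial's dummy coding, ``beta`` the fixed effects and
``u_j ~ N(0, sigma_u^2)`` a by-subject intercept.  A small
``underinform_rate`` produces non-demarcating expressions to exercise
the exclusion rules; optional "fatigue" subjects go underinformative
wholesale to exercise the subject-level exclusion.

Default fixed effects are the published posterior means of the two
experiments' models; ``sigma_u`` defaults to 0.8, chosen to give
subject heterogeneity comparable to the spread of observed subject
means without degenerate cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from . import design
from .design import DisplayType, Expression
from .staircase import (
    COLOUR_STAIRCASE,
    MATERIAL_STAIRCASE,
    CalibrationResult,
    StaircaseConfig,
    run_dual_staircase,
)

__all__ = [
    "SimulatedObserver",
    "SimulatedSpeaker",
    "ObserverParams",
    "observer_response_prob",
    "make_responder",
    "sample_speaker_response",
    "simulate_experiment1",
    "simulate_experiment2",
    "EXP1_TRUE_COEFFICIENTS",
    "EXP2_TRUE_COEFFICIENTS",
    "EXP1_EFFECTS",
    "EXP2_EFFECTS",
]

#: published posterior means used as the default generative truth
EXP1_TRUE_COEFFICIENTS = {
    "intercept": -2.50,
    "material_redundant": -1.43,
    "baseline": -0.94,
    "s_high_r_low": -1.09,
}
EXP2_TRUE_COEFFICIENTS = {
    "intercept": 0.97,
    "lf_colour": -0.20,
    "orientation": -0.97,
}
EXP1_EFFECTS = ("material_redundant", "baseline", "s_high_r_low")
EXP2_EFFECTS = ("lf_colour", "orientation")


@dataclass(frozen=True)
class SimulatedObserver:
    """Lapse-rate logistic observer over an absolute continuum position."""

    boundary: float
    slope: float
    lapse: float = 0.02

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        if not 0.0 <= self.lapse < 0.5:
            raise ValueError("lapse must be in [0, 0.5)")

    def prob_far(self, position: float) -> float:
        """P(categorise as the far-end label) at an absolute position."""
        return float(
            self.lapse / 2.0
            + (1.0 - self.lapse) * expit((position - self.boundary) / self.slope)
        )

    def prob_label(self, position: float, label: str, label_A: str, label_B: str) -> float:
        p_far = self.prob_far(position)
        if label == label_B:
            return p_far
        if label == label_A:
            return 1.0 - p_far
        raise ValueError(f"label {label!r} not one of {label_A!r}/{label_B!r}")


def observer_response_prob(
    o: SimulatedObserver, position: float, toward_label: str,
    label_A: str = "A", label_B: str = "B",
) -> float:
    """P(observer answers ``toward_label``) at a position; ``label_B`` is the far end."""
    return o.prob_label(position, toward_label, label_A, label_B)


def make_responder(o: SimulatedObserver, rng: np.random.Generator) -> Callable[[int, str, str], str]:
    """Wrap an observer as a staircase response source."""

    def responder(position: int, label_A: str, label_B: str) -> str:
        return label_B if rng.random() < o.prob_far(position) else label_A

    return responder


@dataclass(frozen=True)
class ObserverParams:
    """Population distribution of observers for one attribute's continuum.

    Boundaries are drawn uniformly from the middle third of the
    continuum; slopes reflect sharp individual category boundaries
    (smooth average curves arise from boundary variation across
    observers).
    """

    n_steps: int
    slope: float
    lapse: float = 0.02

    def draw(self, rng: np.random.Generator) -> SimulatedObserver:
        lo, hi = self.n_steps / 3.0, 2.0 * self.n_steps / 3.0
        return SimulatedObserver(boundary=float(rng.uniform(lo, hi)),
                                 slope=self.slope, lapse=self.lapse)


#: defaults: sharp colour boundaries on the 50-step continuum, one-step-scale
#: material boundaries on the 10-step continuum
DEFAULT_OBSERVER_PARAMS = {
    "material": ObserverParams(n_steps=10, slope=0.75),
    "colour": ObserverParams(n_steps=50, slope=2.0),
}


@dataclass(frozen=True)
class SimulatedSpeaker:
    """Logit-linear speaker with by-subject intercepts and noise channels."""

    coefficients: dict
    subject_intercept_sd: float = 0.8
    underinform_rate: float = 0.01
    noun_error_rate: float = 0.0
    observers: dict = field(default_factory=dict)  # attribute -> (observer, label_A, label_B)

    def __post_init__(self) -> None:
        if self.subject_intercept_sd < 0:
            raise ValueError("subject_intercept_sd must be >= 0")
        for p in (self.underinform_rate, self.noun_error_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must be probabilities")

    def overinform_prob(self, x: dict, u_j: float) -> float:
        eta = u_j
        for name, value in x.items():
            eta += self.coefficients.get(name, 0.0) * value
        return float(expit(eta))


def _exp1_design_vector(trial: design.BatTrial) -> dict:
    x = {"intercept": 1.0,
         "material_redundant": 1.0 if trial.redundant_attribute == "material" else 0.0}
    if not trial.is_filler:
        x["baseline"] = 1.0 if trial.display_type is DisplayType.BASELINE else 0.0
        x["s_high_r_low"] = 1.0 if trial.display_type is DisplayType.S_HIGH_R_LOW else 0.0
        # product terms let a speaker config express attribute-by-display
        # interactions; their coefficients default to 0
        x["material_redundant:baseline"] = x["material_redundant"] * x["baseline"]
        x["material_redundant:s_high_r_low"] = x["material_redundant"] * x["s_high_r_low"]
    return x


def _exp2_design_vector(trial: design.ShapeTrial) -> dict:
    return {
        "intercept": 1.0,
        "lf_colour": 1.0 if trial.condition == "colour-LF" else 0.0,
        "orientation": 1.0 if trial.condition == "orientation" else 0.0,
    }


def _speaker_label(speaker: SimulatedSpeaker, attribute: str, index: int,
                   nominal: str, rng: np.random.Generator) -> tuple[str, bool]:
    """Name a stimulus's category by sampling the attached observer.

    Returns (label, mislabelled).  Without an attached observer the
    nominal label is used verbatim.
    """
    if attribute not in speaker.observers:
        return nominal, False
    observer, label_A, label_B = speaker.observers[attribute]
    p_nominal = observer.prob_label(index, nominal, label_A, label_B)
    if rng.random() < p_nominal:
        return nominal, False
    other = label_B if nominal == label_A else label_A
    return other, True


def sample_speaker_response(
    speaker: SimulatedSpeaker,
    trial,
    subject_intercept: float,
    rng: np.random.Generator,
) -> tuple[Expression, dict]:
    """Sample one referring expression for a trial.

    Returns the expression plus a dict of generative ground truth
    (intended overinforming/underinforming, mislabels) that the analysis
    never reads but tests can assert against.
    """
    truth = {"intended_underinform": False, "intended_overinform": False,
             "mislabelled": False}

    if isinstance(trial, design.BatTrial):
        x = _exp1_design_vector(trial)
        target = trial.items[trial.target_index]
        if rng.random() < speaker.underinform_rate:
            truth["intended_underinform"] = True
            return Expression(noun="bat"), truth  # bare noun matches all three bats
        suff = trial.sufficient_attribute
        suff_index = getattr(target, f"{suff}_index")
        suff_nominal = getattr(target, f"{suff}_label")
        suff_term, mis = _speaker_label(speaker, suff, suff_index, suff_nominal, rng)
        truth["mislabelled"] |= mis
        terms = {f"{suff}_term": suff_term, "noun": "bat"}
        if not trial.is_filler and rng.random() < speaker.overinform_prob(x, subject_intercept):
            truth["intended_overinform"] = True
            red = trial.redundant_attribute
            red_term, mis = _speaker_label(
                speaker, red, getattr(target, f"{red}_index"),
                getattr(target, f"{red}_label"), rng)
            truth["mislabelled"] |= mis
            terms[f"{red}_term"] = red_term
        elif trial.is_filler and rng.random() < speaker.overinform_prob(x, subject_intercept):
            # overinforming on a filler mentions the shared attribute (draws a shrug)
            truth["intended_overinform"] = True
            red = trial.redundant_attribute
            terms[f"{red}_term"] = getattr(target, f"{red}_label")
        return Expression(**terms), truth

    # experiment two: noun obligatory, attribute term optional
    x = _exp2_design_vector(trial)
    target = trial.items[trial.target_index]
    noun = target.shape
    if rng.random() < speaker.noun_error_rate:
        truth["intended_underinform"] = True
        others = [s for s in design.SHAPES if s != target.shape]
        noun = others[rng.integers(len(others))]
    slot = "orientation_term" if trial.attribute == "orientation" else "colour_term"
    if trial.is_filler:
        return Expression(**{slot: target.value, "noun": noun}), truth
    terms = {"noun": noun}
    if rng.random() < speaker.overinform_prob(x, subject_intercept):
        truth["intended_overinform"] = True
        terms[slot] = target.value
    return Expression(**terms), truth


# --- end-to-end simulations --------------------------------------------------

def _expression_columns(e: Expression) -> dict:
    return {"colour_term": e.colour_term, "material_term": e.material_term,
            "orientation_term": e.orientation_term, "noun": e.noun}


def simulate_experiment1(
    n_subjects: int = 72,
    observer_params: Optional[dict] = None,
    speaker: Optional[SimulatedSpeaker] = None,
    rng: Optional[np.random.Generator] = None,
    colour_labels: tuple[str, str] = ("blue", "green"),
    material_labels: tuple[str, str] = ("wood", "metal"),
    n_fatigue_subjects: int = 0,
    collect_staircase_logs: bool = False,
) -> tuple[pd.DataFrame, list[dict]]:
    """Simulate the full first experiment: staircases, sessions, responses.

    Per subject: draw an observer per attribute, run the interleaved dual
    staircases, skip the subject if calibration fails, then generate a
    48-critical + 12-filler session and sample one expression per trial.
    Returns the response dataset (one row per trial of every successfully
    calibrated subject) and per-subject calibration logs.
    """
    rng = np.random.default_rng() if rng is None else rng
    observer_params = dict(DEFAULT_OBSERVER_PARAMS if observer_params is None else observer_params)
    base_speaker = speaker if speaker is not None else SimulatedSpeaker(
        coefficients=dict(EXP1_TRUE_COEFFICIENTS))

    labels = {"colour": colour_labels, "material": material_labels}
    configs = {"colour": COLOUR_STAIRCASE, "material": MATERIAL_STAIRCASE}
    rows: list[dict] = []
    logs: list[dict] = []

    for j in range(n_subjects):
        observers = {}
        attributes = {}
        trial_log: Optional[list] = [] if collect_staircase_logs else None
        for attr in ("colour", "material"):
            obs = observer_params[attr].draw(rng)
            observers[attr] = (obs, *labels[attr])
            attributes[attr] = run_dual_staircase(
                make_responder(obs, rng), configs[attr], rng,
                label_A=labels[attr][0], label_B=labels[attr][1], log=trial_log,
            )
        calibration = CalibrationResult(attributes=attributes)
        logs.append({
            "subject": j,
            "success": calibration.success,
            "boundaries": {a: observers[a][0].boundary for a in observers},
            "calibration": calibration,
            "staircase_trials": trial_log,
        })
        if not calibration.success:
            continue

        subj_speaker = replace(base_speaker, observers=observers)
        u_j = float(rng.normal(0.0, subj_speaker.subject_intercept_sd))
        fatigued = j < n_fatigue_subjects
        session = design.generate_exp1_session(calibration, rng)
        for t_i, trial in enumerate(session):
            if fatigued and t_i >= 20:
                expr, truth = Expression(noun="bat"), {
                    "intended_underinform": True, "intended_overinform": False,
                    "mislabelled": False}
            else:
                expr, truth = sample_speaker_response(subj_speaker, trial, u_j, rng)
            suff_level, red_level = {
                DisplayType.BASELINE: ("high", "high"),
                DisplayType.S_HIGH_R_LOW: ("high", "low"),
                DisplayType.S_LOW_R_HIGH: ("low", "high"),
                DisplayType.FILLER: ("high", "high"),
            }[trial.display_type]
            row = {
                "experiment": "exp1",
                "subject": j,
                "trial": t_i,
                "is_filler": trial.is_filler,
                "display_type": trial.display_type.value,
                "sufficient_attribute": trial.sufficient_attribute,
                "redundant_attribute": trial.redundant_attribute,
                "suff_level": suff_level,
                "red_level": red_level,
                "target_index": trial.target_index,
                "subject_intercept": u_j,
            }
            for i, item in enumerate(trial.items):
                row[f"colour{i}"] = item.colour_label
                row[f"material{i}"] = item.material_label
            row.update(_expression_columns(expr))
            row.update(truth)
            rows.append(row)

    return pd.DataFrame(rows), logs


def simulate_experiment2(
    n_per_condition: int = 20,
    speaker: Optional[SimulatedSpeaker] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Simulate the second experiment: 3 conditions x ``n_per_condition`` subjects."""
    rng = np.random.default_rng() if rng is None else rng
    # the default speaker is the generative inverse of the published
    # second-experiment model, which is a plain logistic regression
    # (no by-subject intercepts) — so the inverse carries none either
    base_speaker = speaker if speaker is not None else SimulatedSpeaker(
        coefficients=dict(EXP2_TRUE_COEFFICIENTS), subject_intercept_sd=0.0,
        noun_error_rate=0.015, underinform_rate=0.0)

    rows: list[dict] = []
    subject = 0
    for condition in ("colour-HF", "colour-LF", "orientation"):
        for _ in range(n_per_condition):
            u_j = float(rng.normal(0.0, base_speaker.subject_intercept_sd))
            session = design.generate_exp2_session(condition, rng)
            for t_i, trial in enumerate(session):
                expr, truth = sample_speaker_response(base_speaker, trial, u_j, rng)
                row = {
                    "experiment": "exp2",
                    "subject": subject,
                    "condition": condition,
                    "trial": t_i,
                    "is_filler": trial.is_filler,
                    "set_size": trial.set_size,
                    "n_distractors": trial.n_distractors,
                    "target_index": trial.target_index,
                    "shapes": ";".join(it.shape for it in trial.items),
                    "values": ";".join(it.value for it in trial.items),
                    "subject_intercept": u_j,
                }
                row.update(_expression_columns(expr))
                row.update(truth)
                rows.append(row)
            subject += 1
    return pd.DataFrame(rows)
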