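"""Trial generation for both experiments and expression scoring."""

import itertools
from collections import Counter

import numpy as np
import pytest

from overinform.design import (
    EXP2_GRID,
    DisplayType,
    Expression,
    Feedback,
    MislabelError,
    build_exp1_display,
    build_exp1_filler,
    classify_expression,
    feedback,
    generate_exp1_session,
    generate_exp2_session,
    write_trial_table,
)


def brute_force_classify(trial, expression):
    """Independent oracle: enumerate all modifier subsets exhaustively.

    The noun (if any) is the head and is kept in every subset; the
    expression denotes the items matching every term.
    """
    def match(mods, noun):
        out = set()
        for i in range(trial.n_items):
            ok = all(trial.item_label(i, a) == t for a, t in mods.items())
            if noun is not None:
                ok = ok and trial.item_noun(i) == noun
            if ok:
                out.add(i)
        return out

    mods = expression.modifiers
    full = match(mods, expression.noun)
    if full != {trial.target_index}:
        return "underinformative", False
    names = list(mods)
    for r in range(len(names)):
        for keep in itertools.combinations(names, r):
            sub = {a: mods[a] for a in keep}
            if match(sub, expression.noun) == {trial.target_index}:
                return "overinformative", True
    return "minimal", True


class TestExp1Displays:
    def test_baseline_colour_sufficient_structure(self, calibration, rng):
        trial = build_exp1_display(DisplayType.BASELINE, "colour", calibration, rng)
        target = trial.items[trial.target_index]
        others = [it for i, it in enumerate(trial.items) if i != trial.target_index]
        # sufficient colour: target one category's high-disc, distractors the other's
        assert target.colour_index in (1, 50)
        assert {o.colour_index for o in others} <= {1, 50}
        assert all(o.colour_label != target.colour_label for o in others)
        # redundant material: one high-disc stimulus shared by all three
        assert len({it.material_index for it in trial.items}) == 1
        assert trial.items[0].material_index in (1, 10)

    def test_s_low_r_high_places_boundary_stimulus_on_target(self, calibration, rng):
        trial = build_exp1_display(DisplayType.S_LOW_R_HIGH, "colour", calibration, rng)
        target = trial.items[trial.target_index]
        others = [it for i, it in enumerate(trial.items) if i != trial.target_index]
        assert target.colour_index in (24, 27)  # the low-disc boundary stimuli
        assert all(o.colour_index in (1, 50) for o in others)
        assert len({it.material_index for it in trial.items}) == 1

    def test_s_high_r_low_redundant_is_low_disc(self, calibration, rng):
        trial = build_exp1_display(DisplayType.S_HIGH_R_LOW, "material", calibration, rng)
        # redundant colour shared and low-disc
        assert len({it.colour_index for it in trial.items}) == 1
        assert trial.items[0].colour_index in (24, 27)

    def test_filler_single_difference(self, calibration, rng):
        trial = build_exp1_filler("material", calibration, rng)
        target = trial.items[trial.target_index]
        others = [it for i, it in enumerate(trial.items) if i != trial.target_index]
        assert all(o.colour_index == target.colour_index for o in others)
        assert all(o.material_label != target.material_label for o in others)
        assert others[0].material_index == others[1].material_index

    def test_failed_calibration_rejected(self, calibration, rng):
        from overinform.staircase import AttributeCalibration, CalibrationResult

        bad = CalibrationResult(attributes={
            "colour": calibration["colour"],
            "material": AttributeCalibration("wood", "metal", None, 10, 5, 6, False),
        })
        with pytest.raises(ValueError):
            build_exp1_display(DisplayType.BASELINE, "colour", bad, rng)


class TestExp1Session:
    def test_counts(self, calibration, rng):
        session = generate_exp1_session(calibration, rng)
        assert len(session) == 60
        critical = [t for t in session if not t.is_filler]
        fillers = [t for t in session if t.is_filler]
        assert len(critical) == 48 and len(fillers) == 12
        by_redundant = Counter(t.redundant_attribute for t in critical)
        assert by_redundant == {"colour": 24, "material": 24}
        by_type = Counter(t.display_type for t in critical)
        assert all(v == 16 for v in by_type.values()) and len(by_type) == 3

    def test_cell_counts_seed_invariant(self, calibration):
        def cells(seed):
            session = generate_exp1_session(calibration, np.random.default_rng(seed))
            return Counter((t.display_type, t.redundant_attribute)
                           for t in session if not t.is_filler)

        c1, c2 = cells(1), cells(2)
        assert c1 == c2
        assert all(v == 8 for v in c1.values())

    def test_orders_differ_across_seeds(self, calibration):
        s1 = generate_exp1_session(calibration, np.random.default_rng(1))
        s2 = generate_exp1_session(calibration, np.random.default_rng(2))
        assert [t.display_type for t in s1] != [t.display_type for t in s2]

    def test_timing_metadata(self, calibration, rng):
        trial = generate_exp1_session(calibration, rng)[0]
        assert trial.timing_ms == (800, 1000, 1700)


class TestExp2Session:
    def test_counts(self, rng):
        session = generate_exp2_session("colour-HF", rng)
        critical = [t for t in session if not t.is_filler]
        fillers = [t for t in session if t.is_filler]
        assert len(session) == 48
        assert len(critical) == 34 and len(fillers) == 14

    def test_grid_combinations_each_twice(self, rng):
        session = generate_exp2_session("orientation", rng)
        combos = Counter((t.set_size, t.n_distractors)
                         for t in session if not t.is_filler)
        expected = {(s, d): 2 for s, levels in EXP2_GRID.items() for d in levels}
        assert combos == expected

    def test_set_size_three_limited_distractors(self, rng):
        session = generate_exp2_session("colour-LF", rng)
        for t in session:
            if not t.is_filler and t.set_size == 3:
                assert t.n_distractors in (0, 1)

    def test_critical_noun_alone_identifies(self, rng):
        for t in generate_exp2_session("colour-HF", rng):
            if t.is_filler:
                continue
            expr = Expression(noun=t.items[t.target_index].shape)
            category, identifiable = classify_expression(t, expr)
            assert identifiable and category == "minimal"

    def test_critical_distractor_count_by_construction(self, rng):
        for t in generate_exp2_session("colour-HF", rng):
            if t.is_filler:
                continue
            target = t.items[t.target_index]
            sharers = sum(it.value == target.value
                          for i, it in enumerate(t.items) if i != t.target_index)
            assert sharers == t.n_distractors

    def test_filler_requires_adjective_and_noun(self, rng):
        for t in generate_exp2_session("orientation", rng):
            if not t.is_filler:
                continue
            target = t.items[t.target_index]
            _, noun_alone = classify_expression(t, Expression(noun=target.shape))
            assert not noun_alone
            slot = {"orientation_term": target.value}
            category, identifiable = classify_expression(
                t, Expression(noun=target.shape, **slot))
            assert identifiable and category == "minimal"

    def test_unknown_condition_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_exp2_session("texture", rng)


class TestClassifyExpression:
    @pytest.fixture
    def simple_trial(self, calibration):
        # {green/metal target, blue/metal, blue/metal}
        rng = np.random.default_rng(5)
        for _ in range(50):
            t = build_exp1_display(DisplayType.BASELINE, "colour", calibration, rng)
            target = t.items[t.target_index]
            if target.colour_label == "green" and target.material_label == "metal":
                return t
        raise AssertionError("fixture trial not found")

    def test_minimal_sufficient_expression(self, simple_trial):
        category, ok = classify_expression(
            simple_trial, Expression(colour_term="green", noun="bat"))
        assert (category, ok) == ("minimal", True)

    def test_overinformative_with_redundant_material(self, simple_trial):
        category, ok = classify_expression(
            simple_trial, Expression(colour_term="green", material_term="metal", noun="bat"))
        assert (category, ok) == ("overinformative", True)

    def test_underinformative_shared_material(self, simple_trial):
        category, ok = classify_expression(
            simple_trial, Expression(material_term="metal", noun="bat"))
        assert (category, ok) == ("underinformative", False)

    def test_empty_expression_rejected(self, simple_trial):
        with pytest.raises(ValueError):
            classify_expression(simple_trial, Expression())

    def test_out_of_vocabulary_term(self, simple_trial):
        with pytest.raises(MislabelError):
            classify_expression(simple_trial, Expression(colour_term="red", noun="bat"))

    def test_noun_required_in_exp2(self, rng):
        trial = generate_exp2_session("colour-HF", rng)[0]
        with pytest.raises(ValueError, match="noun"):
            classify_expression(trial, Expression(colour_term="green"))

    def test_matches_brute_force_on_generated_trials(self, calibration):
        """Oracle equivalence across sessions, expressions, and experiments."""
        rng = np.random.default_rng(11)
        n_checked = 0
        for seed in range(3):
            r = np.random.default_rng(seed)
            for trial in generate_exp1_session(calibration, r):
                target = trial.items[trial.target_index]
                candidates = [
                    Expression(colour_term=target.colour_label, noun="bat"),
                    Expression(material_term=target.material_label, noun="bat"),
                    Expression(colour_term=target.colour_label,
                               material_term=target.material_label, noun="bat"),
                    Expression(noun="bat"),
                ]
                for expr in candidates:
                    assert classify_expression(trial, expr) == \
                        brute_force_classify(trial, expr)
                    n_checked += 1
            for trial in generate_exp2_session("colour-HF", r):
                target = trial.items[trial.target_index]
                for expr in (Expression(noun=target.shape),
                             Expression(colour_term=target.value, noun=target.shape)):
                    assert classify_expression(trial, expr) == \
                        brute_force_classify(trial, expr)
                    n_checked += 1
        assert n_checked > 500


class TestFeedback:
    def test_thumbs_down_for_failed_reference(self, calibration, rng):
        trial = build_exp1_display(DisplayType.BASELINE, "colour", calibration, rng)
        assert feedback(trial, Expression(noun="bat")) is Feedback.THUMBS_DOWN

    def test_thumbs_up_for_overinforming_on_critical(self, calibration, rng):
        trial = build_exp1_display(DisplayType.BASELINE, "colour", calibration, rng)
        target = trial.items[trial.target_index]
        expr = Expression(colour_term=target.colour_label,
                          material_term=target.material_label, noun="bat")
        assert feedback(trial, expr) is Feedback.THUMBS_UP

    def test_shrug_for_overinforming_on_filler(self, calibration, rng):
        trial = build_exp1_filler("colour", calibration, rng)
        target = trial.items[trial.target_index]
        expr = Expression(colour_term=target.colour_label,
                          material_term=target.material_label, noun="bat")
        assert feedback(trial, expr) is Feedback.SHRUG


def test_trial_table_export(tmp_path, calibration, rng):
    session = generate_exp1_session(calibration, rng)
    path = tmp_path / "trials.csv"
    write_trial_table(path, session, session_id="s0")
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 1 + 60 * 3  # header + one row per item
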