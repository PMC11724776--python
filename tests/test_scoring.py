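"""Unit and property tests for the item-scoring engine."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from med4child import (
    QuestionnaireResponse,
    assign_quartile,
    dichotomize,
    score_item,
    score_table,
    score_total,
)
from med4child.errors import (
    ConfigurationError,
    DomainError,
    IncompleteRecordError,
    MissingAnswerError,
)
from med4child.scoring import DEFAULT_QUARTILE_CUTPOINTS, QUARTILE_LABELS


def full_answers(registry, satisfy=True):
    """Answers that satisfy (or violate) every item criterion."""
    answers = {}
    for c in registry:
        if c.direction == "yes":
            answers[c.item_id] = 1.0 if satisfy else 0.0
        elif c.direction == "at_least":
            answers[c.item_id] = c.threshold + 1.0 if satisfy else max(c.threshold - 0.5, 0.0)
        else:
            answers[c.item_id] = max(c.threshold - 0.5, 0.0) if satisfy else c.threshold + 1.0
    return answers


class TestScoreItem:
    @pytest.mark.parametrize(
        "item_id, answer, expected",
        [
            (2, 3.0, 1),   # exactly at the "3 or more tablespoons" threshold
            (2, 2.9, 0),
            (12, 2.0, 0),  # "less than 2 times a week" excludes the boundary
            (12, 1.9, 1),
            (12, 0.0, 1),  # zero consumption satisfies any upper bound
            (15, 0.0, 1),
            (1, 1.0, 1),
            (1, 0.0, 0),
        ],
    )
    def test_threshold_directions(self, registry_index, item_id, answer, expected):
        assert score_item(registry_index[item_id], answer) == expected

    def test_missing_answer_signals_not_zero(self, registry_index):
        with pytest.raises(MissingAnswerError):
            score_item(registry_index[2], None)
        with pytest.raises(MissingAnswerError):
            score_item(registry_index[2], float("nan"))

    def test_negative_answer_rejected(self, registry_index):
        with pytest.raises(DomainError):
            score_item(registry_index[4], -1.0)

    def test_binary_item_rejects_quantities(self, registry_index):
        with pytest.raises(DomainError):
            score_item(registry_index[1], 2.0)

    def test_item3_sub_condition(self, registry_index):
        crit = registry_index[3]
        # main threshold met, raw/salad condition decides when supplied
        assert score_item(crit, 2.5, extra_answer=1.0) == 1
        assert score_item(crit, 2.5, extra_answer=0.0) == 0
        # without a sub-answer the main threshold alone decides
        assert score_item(crit, 2.5) == 1

    @given(
        answer=st.floats(0, 50, allow_nan=False),
        bump=st.floats(0, 10, allow_nan=False),
    )
    def test_monotone_in_direction(self, registry_index, answer, bump):
        """More consumption never loses a point on at_least items and never
        gains one on less_than items."""
        up = registry_index[9]      # nuts, at_least
        down = registry_index[14]   # sugary drinks, less_than
        assert score_item(up, answer + bump) >= score_item(up, answer)
        assert score_item(down, answer + bump) <= score_item(down, answer)


class TestScoreTotal:
    def test_all_satisfied_scores_18(self, registry):
        r = QuestionnaireResponse("c1", full_answers(registry, True), {3: 2.0})
        res = score_total(r, registry)
        assert res.total == 18
        assert res.adherence_class == "high"
        assert res.quartile == "Q4"

    def test_none_satisfied_scores_0(self, registry):
        r = QuestionnaireResponse("c2", full_answers(registry, False), {3: 0.0})
        res = score_total(r, registry)
        assert res.total == 0
        assert res.adherence_class == "low"
        assert res.quartile == "Q1"

    def test_selected_items_sum(self, registry):
        answers = full_answers(registry, False)
        for i in (1, 7, 9):
            c = next(x for x in registry if x.item_id == i)
            answers[i] = 1.0 if c.direction == "yes" else c.threshold + 1.0
        res = score_total(QuestionnaireResponse("c3", answers), registry)
        assert res.total == 3
        assert {i for i, p in res.item_points.items() if p == 1} == {1, 7, 9}

    def test_complete_case_policy_signals_exclusion(self, registry):
        answers = full_answers(registry, True)
        answers[5] = None
        r = QuestionnaireResponse("c4", answers)
        with pytest.raises(IncompleteRecordError):
            score_total(r, registry, policy="complete_case")
        res = score_total(r, registry, policy="score_zero")
        assert res.total == 17 and res.item_points[5] == 0

    def test_unknown_item_id_is_configuration_error(self, registry):
        r = QuestionnaireResponse("c5", {99: 1.0})
        with pytest.raises(ConfigurationError):
            score_total(r, registry)

    def test_items_used_restriction(self, registry):
        answers = full_answers(registry, True)
        res = score_total(
            QuestionnaireResponse("c6", answers), registry, items_used=range(1, 18)
        )
        assert res.total == 17
        assert 18 not in res.items_used

    @given(st.lists(st.booleans(), min_size=18, max_size=18))
    def test_total_equals_brute_force_sum(self, registry, pattern):
        answers = {}
        for c, sat in zip(registry, pattern):
            if c.direction == "yes":
                answers[c.item_id] = float(sat)
            elif c.direction == "at_least":
                answers[c.item_id] = c.threshold + 0.5 if sat else c.threshold * 0.5
            else:
                answers[c.item_id] = c.threshold * 0.5 if sat else c.threshold + 0.5
        res = score_total(QuestionnaireResponse("cx", answers), registry)
        brute = sum(
            score_item(c, answers[c.item_id]) for c in registry
        )
        assert res.total == brute == sum(pattern)


class TestQuartilesAndDichotomy:
    @pytest.mark.parametrize(
        "score, expected",
        [(0, "Q1"), (8, "Q1"), (9, "Q2"), (11, "Q2"), (12, "Q3"),
         (13, "Q3"), (14, "Q4"), (18, "Q4")],
    )
    def test_study_bands(self, score, expected):
        assert assign_quartile(score, DEFAULT_QUARTILE_CUTPOINTS) == expected

    def test_partition(self):
        """Every attainable score maps to exactly one quartile."""
        for s in range(19):
            q = assign_quartile(s)
            assert q in QUARTILE_LABELS

    def test_empirical_mode(self):
        totals = list(range(19))
        assert assign_quartile(0, "empirical", totals) == "Q1"
        assert assign_quartile(18, "empirical", totals) == "Q4"
        with pytest.raises(ConfigurationError):
            assign_quartile(5, "empirical")

    def test_out_of_range_score(self):
        with pytest.raises(DomainError):
            assign_quartile(19)
        with pytest.raises(DomainError):
            dichotomize(-1)

    @pytest.mark.parametrize("score, expected", [(9, "low"), (10, "high"), (18, "high")])
    def test_dichotomy_cutoff(self, score, expected):
        assert dichotomize(score) == expected


def test_score_table_counts_incomplete(registry):
    rows = []
    for k, miss in enumerate([False, True, False]):
        answers = full_answers(registry, True)
        row = {"child_id": f"c{k}"}
        row.update({f"q{i:02d}": v for i, v in answers.items()})
        if miss:
            row["q07"] = np.nan
        rows.append(row)
    out = score_table(pd.DataFrame(rows), registry)
    assert len(out) == 2
    assert out.attrs["n_excluded"] == 1
    assert (out["total"] == 18).all()
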