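"""Competency-question evaluation: answerability, scores, and answering."""

import random

import pytest
from fractions import Fraction

from genoschema import SchemaDef, project_view
from genoschema.competency import (
    NOT_ANSWERABLE,
    answer,
    display_fraction,
    evaluate_schema,
    is_answerable,
    load_questions,
    score,
)

#: The published answerability pattern: which questions each schema misses.
EXPECTED_MISSES = {
    "CSHG": {6, 9, 10, 11, 15},
    "CSCG": {2, 7, 14, 17, 18, 19, 20},
    "CSG": set(),
}


class TestAnswerability:
    @pytest.mark.parametrize("schema_id", list(EXPECTED_MISSES))
    def test_matrix_reproduces_all_cells(self, schemas, questions, schema_id):
        matrix = evaluate_schema(schemas[schema_id], questions)
        row = matrix.row(schema_id)
        assert len(row) == 20
        assert {q for q, ok in row.items() if not ok} == \
            EXPECTED_MISSES[schema_id]

    def test_empty_schema_answers_nothing(self, questions):
        matrix = evaluate_schema(SchemaDef(id="empty"), questions)
        assert not any(matrix.row("empty").values())

    def test_monotonicity_under_concept_addition(self, schemas, questions):
        """Adding concepts never turns an answerable question unanswerable:
        the generic schema answers a superset of the human schema."""
        cshg_row = evaluate_schema(schemas["CSHG"], questions).row("CSHG")
        csg_row = evaluate_schema(schemas["CSG"], questions).row("CSG")
        assert all(csg_row[q] for q, ok in cshg_row.items() if ok)

    def test_projection_monotonicity_over_random_subsets(self, schemas,
                                                         questions):
        """Projecting away concepts can only shrink the answerable set."""
        csg = schemas["CSG"]
        names = sorted(csg.concept_names())
        rng = random.Random(202_6)
        full_row = evaluate_schema(csg, questions).row("CSG")
        for _ in range(50):
            keep = rng.sample(names, rng.randint(0, len(names)))
            projection = project_view(csg, keep)
            row = evaluate_schema(projection, questions).row(projection.id)
            assert all(full_row[q] for q, ok in row.items() if ok)

    def test_projection_onto_human_concepts_recovers_its_row(self, schemas,
                                                             questions):
        projection = project_view(schemas["CSG"],
                                  schemas["CSHG"].concept_names())
        row = evaluate_schema(projection, questions).row(projection.id)
        expected = evaluate_schema(schemas["CSHG"], questions).row("CSHG")
        assert row == expected


class TestScores:
    def test_human_schema_scores(self, schemas, questions):
        matrix = evaluate_schema(schemas["CSHG"], questions)
        report = score(matrix, "CSHG", questions)
        assert report.global_display == "0.75"
        assert report.per_view_display == {
            "structural": "1", "transcription": "0.5", "variation": "0.75",
            "pathway": "1", "bibliography": "1"}

    def test_citrus_schema_scores(self, schemas, questions):
        """The citrus row: 2/3, 7/8, 3/4, 1/3, 0; the matrix-derived global
        is 13/20 = 0.65."""
        matrix = evaluate_schema(schemas["CSCG"], questions)
        report = score(matrix, "CSCG", questions)
        assert report.per_view_display == {
            "structural": "0.66", "transcription": "0.875",
            "variation": "0.75", "pathway": "0.33", "bibliography": "0"}
        assert report.global_fraction() == Fraction(13, 20)
        assert report.global_display == "0.65"

    def test_generic_schema_scores_everything(self, schemas, questions):
        report = score(evaluate_schema(schemas["CSG"], questions), "CSG",
                       questions)
        assert report.global_display == "1"
        assert set(report.per_view_display.values()) == {"1"}

    def test_scores_recomputed_from_matrix_rows(self, schemas, questions):
        matrix = evaluate_schema(schemas["CSCG"], questions)
        report = score(matrix, "CSCG", questions)
        row = matrix.row("CSCG")
        for question in questions:
            view = question.view.value
            answered, total = report.per_view[view]
            in_view = [q for q in questions if q.view is question.view]
            assert answered == sum(row[q.id] for q in in_view)
            assert total == len(in_view)

    def test_incomplete_matrix_rejected(self, schemas, questions):
        matrix = evaluate_schema(schemas["CSG"], questions[:10])
        with pytest.raises(ValueError, match="missing"):
            score(matrix, "CSG", questions)

    @pytest.mark.parametrize("fraction, text", [
        (Fraction(2, 3), "0.66"),
        (Fraction(1, 3), "0.33"),
        (Fraction(7, 8), "0.875"),
        (Fraction(3, 4), "0.75"),
        (Fraction(1, 2), "0.5"),
        (Fraction(1), "1"),
        (Fraction(0), "0"),
        (Fraction(13, 20), "0.65"),
    ])
    def test_display_truncation(self, fraction, text):
        assert display_fraction(fraction) == text


class TestAnswering:
    def test_all_twenty_nonempty_on_worked_example(self, cftr, schemas,
                                                   questions):
        for question in questions:
            result = answer(cftr, question, schemas["CSG"])
            assert result is not NOT_ANSWERABLE
            assert result, f"Q{question.id} returned no records"

    def test_pathway_question_returns_the_pathway(self, cftr, schemas,
                                                  questions):
        q16 = next(q for q in questions if q.id == 16)
        result = answer(cftr, q16, schemas["CSG"])
        assert {"variation": "CFTR_c.57G>A", "pathway": "ion_transport"} in result

    def test_not_answerable_under_narrow_schema(self, cftr, schemas,
                                                questions):
        q19 = next(q for q in questions if q.id == 19)
        assert answer(cftr, q19, schemas["CSCG"]) is NOT_ANSWERABLE
        for qid in (6, 9, 10, 11, 15):
            q = next(q for q in questions if q.id == qid)
            assert answer(cftr, q, schemas["CSHG"]) is NOT_ANSWERABLE

    def test_missing_data_yields_empty_not_notanswerable(self, cftr, schemas,
                                                         questions):
        """An answerable question with no matching data is an empty result,
        which is distinct from a capability gap."""
        q2 = next(q for q in questions if q.id == 2)
        cftr.variations["CFTR_c.57G>A"].positions.clear()
        result = answer(cftr, q2, schemas["CSG"])
        assert result == [] and result is not NOT_ANSWERABLE


def test_registry_layout():
    questions = load_questions()
    assert [q.id for q in questions] == list(range(1, 21))
    by_view = {}
    for q in questions:
        by_view.setdefault(q.view.value, []).append(q.id)
    assert by_view == {
        "structural": [1, 2, 3],
        "transcription": [4, 5, 6, 7, 8, 9, 10, 11],
        "variation": [12, 13, 14, 15],
        "pathway": [16, 17, 18],
        "bibliography": [19, 20],
    }
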