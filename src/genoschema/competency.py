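"""Competency-question evaluation: can a schema answer a domain question?

Twenty validation questions, partitioned over the five views, probe what a
conceptual schema can represent (structural 1-3, transcription 4-11,
variation 12-15, pathway 16-18, bibliography 19-20).  Answerability is a
static capability check — a question is answerable under a schema iff all
the concepts it requires exist there (canonical-name matching) — kept
separate from *answering* a question against a populated instance, which
returns the matching records.  An answerable question with no matching data
yields an empty result, which is distinct from NotAnswerable.

Score fractions are retained exactly (as rationals) and displayed truncated
toward zero: 2/3 -> 0.66, 1/3 -> 0.33, while fractions that terminate
within three decimals print exactly (7/8 -> 0.875, 3/4 -> 0.75).
"""

from __future__ import annotations

import json
from fractions import Fraction
from importlib import resources
from typing import Optional, Sequence, Union

from pydantic import BaseModel, Field, field_validator

from .genome_core import ElementKind, MessengerRNA, Role as ElementRole
from .instance import Instance
from .metamodel import SchemaDef, ViewName, VIEW_ORDER, canonical_name
from .pathway import EventVariant, Role as ParticipationRole
from .provenance import BibliographyEntry, DataBankEntry

#: Table layout of the question registry: view -> question ids.
_VIEW_PARTITION: dict[ViewName, range] = {
    ViewName.structural: range(1, 4),
    ViewName.transcription: range(4, 12),
    ViewName.variation: range(12, 16),
    ViewName.pathway: range(16, 19),
    ViewName.bibliography: range(19, 21),
}


class CompetencyQuestion(BaseModel):
    id: int = Field(ge=1, le=20)
    text: str
    view: ViewName
    requires: list[str] = Field(default_factory=list)

    @field_validator("text")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("question text must be non-empty")
        return v


def load_questions() -> list[CompetencyQuestion]:
    """The shipped 20-question registry, layout-checked against the table
    partition."""
    with resources.files("genoschema.data").joinpath("questions.json").open() as fh:
        raw = json.load(fh)
    questions = [CompetencyQuestion.model_validate(q) for q in raw["questions"]]
    ids = sorted(q.id for q in questions)
    if ids != list(range(1, 21)):
        raise ValueError(f"question registry must cover ids 1..20, got {ids}")
    for q in questions:
        if q.id not in _VIEW_PARTITION[q.view]:
            raise ValueError(
                f"question {q.id} is filed under {q.view.value}, outside the "
                f"registry partition")
    return sorted(questions, key=lambda q: q.id)


class AnswerabilityMatrix(BaseModel):
    """Mapping (schema id, question id) -> answerable."""

    entries: dict[str, bool] = Field(default_factory=dict)

    @staticmethod
    def _key(schema_id: str, question_id: int) -> str:
        return f"{schema_id}:{question_id}"

    def set(self, schema_id: str, question_id: int, answerable: bool) -> None:
        self.entries[self._key(schema_id, question_id)] = answerable

    def get(self, schema_id: str, question_id: int) -> bool:
        return self.entries[self._key(schema_id, question_id)]

    def row(self, schema_id: str) -> dict[int, bool]:
        prefix = f"{schema_id}:"
        return {int(k[len(prefix):]): v for k, v in self.entries.items()
                if k.startswith(prefix)}

    def update(self, other: "AnswerabilityMatrix") -> None:
        self.entries.update(other.entries)


def is_answerable(schema: SchemaDef, question: CompetencyQuestion) -> bool:
    """A question is answerable iff every required concept exists in the
    schema (canonical names)."""
    have = schema.canonical_names()
    return all(canonical_name(c) in have for c in question.requires)


def evaluate_schema(
    schema: SchemaDef,
    questions: Optional[Sequence[CompetencyQuestion]] = None,
) -> AnswerabilityMatrix:
    questions = list(questions) if questions is not None else load_questions()
    matrix = AnswerabilityMatrix()
    for q in questions:
        matrix.set(schema.id, q.id, is_answerable(schema, q))
    return matrix


def display_fraction(value: Fraction) -> str:
    """Display form of a score fraction.

    Fractions that terminate within three decimal places print exactly with
    trailing zeros dropped; everything else is truncated toward zero at two
    decimals.
    """
    value = Fraction(value)
    if (value * 1000).denominator == 1:
        text = f"{float(value):.3f}".rstrip("0").rstrip(".")
        return text if text else "0"
    truncated = (value * 100).numerator // (value * 100).denominator
    return f"{truncated / 100:.2f}"


class ScoreReport(BaseModel):
    """Per-view and global answerability of one schema."""

    schema_id: str
    per_view: dict[str, tuple[int, int]]     # view -> (answered, total)
    global_score: tuple[int, int]            # (answered, 20)
    per_view_display: dict[str, str]
    global_display: str

    def per_view_fraction(self, view: str) -> Fraction:
        answered, total = self.per_view[view]
        return Fraction(answered, total)

    def global_fraction(self) -> Fraction:
        return Fraction(*self.global_score)


def score(
    matrix: AnswerabilityMatrix,
    schema_id: str,
    questions: Optional[Sequence[CompetencyQuestion]] = None,
) -> ScoreReport:
    """Recompute per-view and global fractions from a matrix row."""
    questions = list(questions) if questions is not None else load_questions()
    row = matrix.row(schema_id)
    missing = [q.id for q in questions if q.id not in row]
    if missing:
        raise ValueError(f"matrix row for {schema_id} is missing questions "
                         f"{missing}")
    per_view: dict[str, tuple[int, int]] = {}
    for view in VIEW_ORDER:
        in_view = [q for q in questions if q.view is view]
        answered = sum(row[q.id] for q in in_view)
        per_view[view.value] = (answered, len(in_view))
    answered_total = sum(row[q.id] for q in questions)
    return ScoreReport(
        schema_id=schema_id,
        per_view=per_view,
        global_score=(answered_total, len(questions)),
        per_view_display={v: display_fraction(Fraction(a, t))
                          for v, (a, t) in per_view.items()},
        global_display=display_fraction(Fraction(answered_total, len(questions))),
    )


# ----------------------------------------------------------------------
# answering questions against an instance


class _NotAnswerableType:
    """Sentinel: the governing schema cannot represent the needed data."""

    _instance: Optional["_NotAnswerableType"] = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NotAnswerable"

    def __bool__(self) -> bool:
        return False


NOT_ANSWERABLE = _NotAnswerableType()

AnswerResult = Union[list, _NotAnswerableType]


def _affected_genes(instance: Instance, variation) -> list:
    affected = set(variation.affected_elements)
    return [g for _, g in sorted(instance.genes.items())
            if affected & set(g.elements)]


def _gene_elements_of_kind(instance: Instance, genes, kind: ElementKind) -> list:
    out = []
    for gene in genes:
        for eid in gene.elements:
            element = instance.elements.get(eid)
            if element is not None and element.kind is kind:
                out.append({"gene": gene.id, "element": eid})
    return out


def _affected_proteins(instance: Instance, variation) -> list:
    gene_ids = {g.id for g in _affected_genes(instance, variation)}
    transcript_ids = {tid for tid, t in instance.transcripts.items()
                      if gene_ids & set(t.genes)}
    return [p for _, p in sorted(instance.proteins.items())
            if transcript_ids & set(p.coded_by)]


def _regulated_processes(instance: Instance, variation) -> list:
    """Processes regulated by an entity standing for an affected protein."""
    proteins = _affected_proteins(instance, variation)
    matches = {eid for eid, entity in instance.entities.items()
               if any(entity.name == p.name or eid == p.id for p in proteins)}
    process_ids = {tp.event for tp in instance.takes_part.values()
                   if tp.role is ParticipationRole.regulator
                   and tp.entity in matches}
    return [instance.events[pid] for pid in sorted(process_ids)
            if pid in instance.events]


def _containing_pathways(instance: Instance, event_ids: set[str]) -> list:
    out = []
    for pid, event in sorted(instance.events.items()):
        if event.variant is EventVariant.Pathway and set(event.children) & event_ids:
            out.append(event)
    return out


def _positions_in(instance: Instance, variation, assembly: str) -> list:
    position = variation.positions.get(assembly)
    return ([] if position is None
            else [{"variation": variation.id, "assembly": assembly,
                   "position": position}])


def answer(instance: Instance, question: CompetencyQuestion,
           schema: SchemaDef) -> AnswerResult:
    """Answer one question against an instance governed by ``schema``.

    Returns NotAnswerable when the schema lacks the capability; otherwise a
    (possibly empty) list of result records.  Questions are phrased around
    "the variation [under study]": every variation in the instance is
    considered in turn.
    """
    if not is_answerable(schema, question):
        return NOT_ANSWERABLE
    results: list = []
    for _, variation in sorted(instance.variations.items()):
        results.extend(_HANDLERS[question.id](instance, variation))
    return results


def _q1(instance, variation):
    return [{"variation": variation.id, "chromosome": pos.chromosome}
            for pos in variation.positions.values()]


def _q2(instance, variation):
    return _positions_in(instance, variation, "GRCh37")


def _q3(instance, variation):
    return _positions_in(instance, variation, "GRCh38")


def _q4(instance, variation):
    return [{"variation": variation.id, "gene": g.id}
            for g in _affected_genes(instance, variation)]


def _q5(instance, variation):
    return _gene_elements_of_kind(
        instance, _affected_genes(instance, variation), ElementKind.exon)


def _q6(instance, variation):
    return _gene_elements_of_kind(
        instance, _affected_genes(instance, variation), ElementKind.intron)


def _q7(instance, variation):
    out = []
    for gene in _affected_genes(instance, variation):
        for eid in gene.elements:
            element = instance.elements.get(eid)
            if element is not None and ElementRole.regulatory in element.roles:
                out.append({"gene": gene.id, "element": eid})
    return out


def _q8(instance, variation):
    return [{"variation": variation.id, "protein": p.id}
            for p in _affected_proteins(instance, variation)]


def _q9(instance, variation):
    return [{"protein": p.id, "domain": d.id}
            for p in _affected_proteins(instance, variation) for d in p.domains]


def _affected_mrnas(instance, variation):
    gene_ids = {g.id for g in _affected_genes(instance, variation)}
    return [t for _, t in sorted(instance.transcripts.items())
            if isinstance(t, MessengerRNA) and gene_ids & set(t.genes)]


def _q10(instance, variation):
    return [{"transcript": t.id, "cds": t.cds}
            for t in _affected_mrnas(instance, variation)]


def _q11(instance, variation):
    return [{"transcript": t.id, "utr5": t.utr5, "utr3": t.utr3}
            for t in _affected_mrnas(instance, variation)
            if t.utr5 is not None or t.utr3 is not None]


def _q12(instance, variation):
    return [{"variation": variation.id, "kind": variation.kind.value}]


def _q13(instance, variation):
    return [{"variation": variation.id,
             "reference": variation.reference_allele,
             "alternatives": list(variation.alternative_alleles)}]


def _q14(instance, variation):
    return [record for (var, _), record in
            sorted(instance.population_frequencies.items())
            if var == variation.id]


def _q15(instance, variation):
    return [obs for (var, _), obs in sorted(instance.observations.items())
            if var == variation.id]


def _q16(instance, variation):
    processes = _regulated_processes(instance, variation)
    direct = [e for e in processes if e.variant is EventVariant.Pathway]
    parents = _containing_pathways(
        instance, {e.id for e in processes})
    seen, out = set(), []
    for event in direct + parents:
        if event.id not in seen:
            seen.add(event.id)
            out.append({"variation": variation.id, "pathway": event.id})
    return out


def _q17(instance, variation):
    return [{"variation": variation.id, "process": e.id}
            for e in _regulated_processes(instance, variation)
            if e.variant is EventVariant.Process]


def _q18(instance, variation):
    process_ids = {e.id for e in _regulated_processes(instance, variation)
                   if e.variant is EventVariant.Process}
    return [tp for key, tp in sorted(instance.takes_part.items())
            if tp.event in process_ids
            and tp.role in (ParticipationRole.input, ParticipationRole.output)]


def _q19(instance, variation):
    return [entry for entry in instance.references_of(variation.id)
            if isinstance(entry, DataBankEntry)]


def _q20(instance, variation):
    out = []
    for gene in _affected_genes(instance, variation):
        out.extend(entry for entry in instance.references_of(gene.id)
                   if isinstance(entry, BibliographyEntry))
    return out


_HANDLERS = {i + 1: h for i, h in enumerate([
    _q1, _q2, _q3, _q4, _q5, _q6, _q7, _q8, _q9, _q10,
    _q11, _q12, _q13, _q14, _q15, _q16, _q17, _q18, _q19, _q20,
])}
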