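"""Conceptual schemas as data: counting, intersection, growth, and projection.

The package ships three calibrated schema inventories: the human-genome
schema (CSHG), the citrus-genome schema (CSCG), and the species-independent
genome schema (CSG) that generalizes both.  Each schema partitions its
concepts into five views (structural, transcription, variation, pathway,
bibliography).  Concept matching across schemas is canonical-name based:
an explicit synonym table maps the citrus "SequencePart" onto
"ChromosomeElement" and the protein-coding-transcript / mRNA naming variants
onto "MessengerRNA".
"""

from __future__ import annotations

import json
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from importlib import resources
from typing import Iterable, Literal, Optional, Union

from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import UnknownConceptError, UnknownSchemaError


class ViewName(str, Enum):
    """The five thematic views every schema is partitioned into."""

    structural = "structural"
    transcription = "transcription"
    variation = "variation"
    pathway = "pathway"
    bibliography = "bibliography"


VIEW_ORDER: tuple[ViewName, ...] = (
    ViewName.structural,
    ViewName.transcription,
    ViewName.variation,
    ViewName.pathway,
    ViewName.bibliography,
)


def _load_data(name: str) -> dict:
    with resources.files("genoschema.data").joinpath(name).open("r") as fh:
        return json.load(fh)


def _build_synonym_map() -> dict[str, str]:
    table = _load_data("synonyms.json")
    mapping: dict[str, str] = {}
    for group in table["canonical_groups"]:
        canonical = group[0]
        for name in group:
            mapping[name] = canonical
    return mapping


_SYNONYMS: dict[str, str] = _build_synonym_map()


def canonical_name(name: str) -> str:
    """Map a concept name onto its canonical form via the synonym table."""
    return _SYNONYMS.get(name, name)


class Multiplicity(BaseModel):
    """A (min, max) multiplicity; ``max=None`` means unbounded."""

    min: int = Field(ge=0)
    max: Optional[int] = Field(default=None, ge=1)

    @model_validator(mode="after")
    def _ordered(self) -> "Multiplicity":
        if self.max is not None and self.min > self.max:
            raise ValueError(f"multiplicity min {self.min} exceeds max {self.max}")
        return self

    @field_validator("max", mode="before")
    @classmethod
    def _star(cls, v):
        return None if v in ("*", "n") else v


class ConceptDef(BaseModel):
    name: str
    view: ViewName
    description: str = ""

    @field_validator("name")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("concept name must be non-empty")
        return v


RelationshipKind = Literal["association", "generalization", "composition"]


class RelationshipDef(BaseModel):
    name: str
    source: str
    target: str
    kind: RelationshipKind
    source_multiplicity: Multiplicity = Multiplicity(min=0, max=None)
    target_multiplicity: Multiplicity = Multiplicity(min=1, max=1)


class SchemaDef(BaseModel):
    """A named conceptual schema: concepts in views plus typed relationships."""

    id: str
    concepts: list[ConceptDef] = Field(default_factory=list)
    relationships: list[RelationshipDef] = Field(default_factory=list)

    @model_validator(mode="after")
    def _consistent(self) -> "SchemaDef":
        names = [c.name for c in self.concepts]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate concept names in {self.id}: {dupes}")
        declared = set(names)
        for rel in self.relationships:
            for endpoint in (rel.source, rel.target):
                if endpoint not in declared:
                    raise ValueError(
                        f"relationship {rel.name!r} references undeclared "
                        f"concept {endpoint!r}"
                    )
        return self

    # -- convenience ---------------------------------------------------

    def concept_names(self) -> set[str]:
        return {c.name for c in self.concepts}

    def canonical_names(self) -> set[str]:
        return {canonical_name(c.name) for c in self.concepts}

    def has_concept(self, name: str) -> bool:
        """Membership test under canonical naming."""
        return canonical_name(name) in self.canonical_names()

    def view_of(self, name: str) -> ViewName:
        wanted = canonical_name(name)
        for c in self.concepts:
            if canonical_name(c.name) == wanted:
                return c.view
        raise UnknownConceptError(name)


def concept_counts(schema: SchemaDef) -> dict[str, int]:
    """Per-view concept tally plus a ``total`` key.

    Counts distinct concept names; the per-view counts always sum to the
    total because every concept belongs to exactly one view.
    """
    counts = {view.value: 0 for view in VIEW_ORDER}
    for concept in schema.concepts:
        counts[concept.view.value] += 1
    counts["total"] = len(schema.concepts)
    return counts


def shared_concepts(a: SchemaDef, b: SchemaDef) -> set[str]:
    """Canonical concept names present in both schemas (symmetric)."""
    return a.canonical_names() & b.canonical_names()


def shared_concepts_by_view(a: SchemaDef, b: SchemaDef) -> dict[str, int]:
    """Per-view breakdown of the shared concepts (views taken from ``a``)."""
    counts = {view.value: 0 for view in VIEW_ORDER}
    for name in shared_concepts(a, b):
        counts[a.view_of(name).value] += 1
    counts["total"] = sum(counts[v.value] for v in VIEW_ORDER)
    return counts


def relative_increase(from_schema: SchemaDef, to_schema: SchemaDef) -> float:
    """Percentage growth in concept count, rounded half-up to two decimals."""
    n_from = len(from_schema.concepts)
    n_to = len(to_schema.concepts)
    if n_from == 0:
        raise ValueError("relative increase from an empty schema is undefined")
    pct = Decimal(100 * (n_to - n_from)) / Decimal(n_from)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def shared_fraction(a: SchemaDef, b: SchemaDef) -> tuple[int, int]:
    """Shared-concept share of each schema, as whole display percentages."""
    n = len(shared_concepts(a, b))
    pct = []
    for schema in (a, b):
        total = len(schema.concepts)
        if total == 0:
            raise ValueError(f"schema {schema.id} has no concepts")
        ratio = Decimal(100 * n) / Decimal(total)
        pct.append(int(ratio.quantize(Decimal("1"), rounding=ROUND_HALF_UP)))
    return pct[0], pct[1]


def project_view(schema: SchemaDef, keep: Iterable[str]) -> SchemaDef:
    """Restrict a schema to a subset of its concepts.

    Relationships survive only when both endpoints are kept; generalization
    edges follow the same rule (no transitive re-wiring).  ``keep`` is
    matched canonically, so the CSHG's protein-coding-transcript name selects
    the CSG's MessengerRNA concept.
    """
    wanted = {canonical_name(n) for n in keep}
    known = schema.canonical_names()
    unknown = wanted - known
    if unknown:
        raise UnknownConceptError(
            f"concepts not in schema {schema.id}: {sorted(unknown)}"
        )
    kept_concepts = [c for c in schema.concepts if canonical_name(c.name) in wanted]
    kept_names = {c.name for c in kept_concepts}
    kept_rels = [
        r for r in schema.relationships
        if r.source in kept_names and r.target in kept_names
    ]
    return SchemaDef(
        id=f"{schema.id}-projection",
        concepts=kept_concepts,
        relationships=kept_rels,
    )


class SchemaRegistry:
    """Registry of schemas, pre-loaded with the three shipped inventories."""

    _SHIPPED = ("cshg.json", "cscg.json", "csg.json")

    def __init__(self, load_shipped: bool = True) -> None:
        self._schemas: dict[str, SchemaDef] = {}
        if load_shipped:
            for fname in self._SHIPPED:
                self.register(SchemaDef.model_validate(_load_data(fname)))

    def register(self, schema: SchemaDef) -> None:
        self._schemas[schema.id] = schema

    def get(self, schema_id: str) -> SchemaDef:
        try:
            return self._schemas[schema_id]
        except KeyError:
            raise UnknownSchemaError(schema_id) from None

    def ids(self) -> list[str]:
        return sorted(self._schemas)

    def __contains__(self, schema_id: str) -> bool:
        return schema_id in self._schemas


_default_registry: Optional[SchemaRegistry] = None


def default_registry() -> SchemaRegistry:
    """Process-wide registry holding the shipped CSHG/CSCG/CSG inventories."""
    global _default_registry
    if _default_registry is None:
        _default_registry = SchemaRegistry()
    return _default_registry
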