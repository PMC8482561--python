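"""The pathway view: entity taxonomy, recursive events, and the roll-up.

Entities are Simple (atomic), Complex (>= 2 components), EntitySet (>= 2
independent members), or Polymer (a repeated simple-or-complex unit).
Events are atomic processes or pathways, a pathway being an ordered list of
events that may nest.  Participation of an entity in an event is reified as
a takes-part record with role input, output, or regulator.

The roll-up derives a pathway's net inputs, outputs, and regulators from
its processes' participations.  An entity produced by an earlier process
and consumed by a later one is an *intermediate* and is cancelled out of
the pathway-level input and output sets (the ``gross`` flag disables the
cancellation).  The rule uses declared order: an entity produced only
*after* it is consumed is not an intermediate, and an entity that is both
input and output of one and the same process (a catalytic cycle) stays in
both sets.  Regulators are always the plain union; stoichiometry is carried
as an opaque attribute and ignored.
"""

from __future__ import annotations

from enum import Enum
from typing import Any, Iterable, Mapping, Optional

from pydantic import BaseModel, Field, model_validator

from .errors import CycleError, MissingParticipationError

class EntityVariant(str, Enum):
    Simple = "Simple"
    Complex = "Complex"
    EntitySet = "EntitySet"
    Polymer = "Polymer"


class BioEntity(BaseModel):
    id: str
    name: str = ""
    variant: EntityVariant
    components: list[str] = Field(default_factory=list)  # Complex only
    members: list[str] = Field(default_factory=list)     # EntitySet only
    unit: Optional[str] = None                           # Polymer only
    count: Optional[int] = Field(default=None, ge=2)     # Polymer; None = unspecified

    @model_validator(mode="after")
    def _variant_fields(self) -> "BioEntity":
        v = self.variant
        if v is not EntityVariant.Complex and self.components:
            raise ValueError(f"entity {self.id}: only a Complex has components")
        if v is not EntityVariant.EntitySet and self.members:
            raise ValueError(f"entity {self.id}: only an EntitySet has members")
        if v is not EntityVariant.Polymer and (self.unit or self.count):
            raise ValueError(f"entity {self.id}: only a Polymer has a unit/count")
        if v is EntityVariant.Complex and len(self.components) < 2:
            raise ValueError(f"entity {self.id}: a Complex needs >= 2 components")
        if v is EntityVariant.EntitySet and len(self.members) < 2:
            raise ValueError(f"entity {self.id}: an EntitySet needs >= 2 members")
        if v is EntityVariant.Polymer and not self.unit:
            raise ValueError(f"entity {self.id}: a Polymer needs a unit")
        return self

    def children(self) -> list[str]:
        if self.variant is EntityVariant.Complex:
            return list(self.components)
        if self.variant is EntityVariant.EntitySet:
            return list(self.members)
        if self.variant is EntityVariant.Polymer:
            return [self.unit] if self.unit else []
        return []


class EventVariant(str, Enum):
    Process = "Process"
    Pathway = "Pathway"


class Event(BaseModel):
    id: str
    name: str = ""
    variant: EventVariant
    children: list[str] = Field(default_factory=list)  # Pathway only, ordered

    @model_validator(mode="after")
    def _variant_fields(self) -> "Event":
        if self.variant is EventVariant.Process and self.children:
            raise ValueError(f"process {self.id} cannot contain events")
        if self.variant is EventVariant.Pathway and not self.children:
            raise ValueError(f"pathway {self.id} must order at least one event")
        return self


class Role(str, Enum):
    input = "input"
    output = "output"
    regulator = "regulator"


class TakesPart(BaseModel):
    """Reified participation of an entity in an event."""

    entity: str
    event: str
    role: Role
    attributes: dict[str, Any] = Field(default_factory=dict)

    def key(self) -> tuple[str, str, str]:
        return (self.entity, self.event, self.role.value)


class PathwayIO(BaseModel):
    """Net pathway-level participation sets produced by the roll-up."""

    inputs: set[str] = Field(default_factory=set)
    outputs: set[str] = Field(default_factory=set)
    regulators: set[str] = Field(default_factory=set)
    intermediates: set[str] = Field(default_factory=set)

    @model_validator(mode="after")
    def _disjoint(self) -> "PathwayIO":
        if self.inputs & self.intermediates or self.outputs & self.intermediates:
            raise ValueError("intermediates must be disjoint from inputs/outputs")
        return self


def flatten(events: Mapping[str, Event], pathway_id: str) -> list[Event]:
    """Depth-first expansion of a pathway into its ordered atomic processes."""
    root = events[pathway_id]
    if root.variant is not EventVariant.Pathway:
        raise ValueError(f"{pathway_id} is not a pathway")
    out: list[Event] = []
    stack: list[str] = []

    def visit(event_id: str) -> None:
        if event_id in stack:
            cycle = " -> ".join([*stack[stack.index(event_id):], event_id])
            raise CycleError(f"event containment cycle: {cycle}")
        try:
            event = events[event_id]
        except KeyError:
            raise KeyError(f"pathway references unknown event {event_id!r}") from None
        if event.variant is EventVariant.Process:
            out.append(event)
            return
        stack.append(event_id)
        for child in event.children:
            visit(child)
        stack.pop()

    visit(pathway_id)
    return out


def _participations_by_process(
    takes_part: Iterable[TakesPart],
) -> dict[str, dict[Role, set[str]]]:
    table: dict[str, dict[Role, set[str]]] = {}
    for tp in takes_part:
        table.setdefault(tp.event, {r: set() for r in Role})[tp.role].add(tp.entity)
    return table


def rollup(
    events: Mapping[str, Event],
    takes_part: Iterable[TakesPart],
    pathway_id: str,
    gross: bool = False,
) -> PathwayIO:
    """Merge process participations into pathway-level inputs/outputs/regulators.

    With ``gross=True`` the intermediate cancellation is skipped and the
    plain unions are returned.
    """
    processes = flatten(events, pathway_id)
    table = _participations_by_process(takes_part)
    for process in processes:
        if not any(table.get(process.id, {}).values()):
            raise MissingParticipationError(
                f"process {process.id} has no takes-part records")
    ins = [table[p.id][Role.input] for p in processes]
    outs = [table[p.id][Role.output] for p in processes]
    regs = [table[p.id][Role.regulator] for p in processes]

    intermediates: set[str] = set()
    if not gross:
        for i, produced in enumerate(outs):
            for entity in produced:
                if any(entity in ins[j] for j in range(i + 1, len(processes))):
                    intermediates.add(entity)
    return PathwayIO(
        inputs=set().union(*ins) - intermediates if ins else set(),
        outputs=set().union(*outs) - intermediates if outs else set(),
        regulators=set().union(*regs) if regs else set(),
        intermediates=intermediates,
    )


class Violation(BaseModel):
    entity: str
    problem: str


def validate_entities(entities: Mapping[str, BioEntity]) -> list[Violation]:
    """Report every composition-graph violation (acyclicity, variants).

    Returns a report instead of raising so that a store can be audited as a
    whole; an empty list means the entity taxonomy is hierarchical.
    """
    report: list[Violation] = []
    for entity in entities.values():
        if entity.variant is EntityVariant.Polymer and entity.unit:
            unit = entities.get(entity.unit)
            if unit is None:
                report.append(Violation(
                    entity=entity.id, problem=f"unknown unit {entity.unit!r}"))
            elif unit.variant in (EntityVariant.EntitySet, EntityVariant.Polymer):
                report.append(Violation(
                    entity=entity.id,
                    problem=f"a Polymer repeats simple or complex entities, "
                            f"not {unit.variant.value}"))
        for child in entity.children():
            if child not in entities:
                report.append(Violation(
                    entity=entity.id, problem=f"unknown component {child!r}"))

    # cycle detection over the composition graph
    WHITE, GREY, BLACK = 0, 1, 2
    color = {eid: WHITE for eid in entities}
    def visit(eid: str, path: list[str]) -> None:
        color[eid] = GREY
        for child in entities[eid].children():
            if child not in entities:
                continue
            if color[child] == GREY:
                cycle = " -> ".join([*path[path.index(child):], eid, child]) \
                    if child in path else f"{eid} -> {child}"
                report.append(Violation(entity=child,
                                        problem=f"composition cycle: {cycle}"))
            elif color[child] == WHITE:
                visit(child, [*path, child])
        color[eid] = BLACK

    for eid in sorted(entities):
        if color[eid] == WHITE:
            visit(eid, [eid])
    return report
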