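"""Pathway flattening, roll-up with intermediate cancellation, and the
entity taxonomy."""

import pytest
from hypothesis import given, strategies as st

from genoschema import CycleError, MissingParticipationError
from genoschema.pathway import (
    BioEntity,
    EntityVariant,
    Event,
    EventVariant,
    Role,
    TakesPart,
    flatten,
    rollup,
    validate_entities,
)


def process(pid):
    return Event(id=pid, variant=EventVariant.Process)


def pathway(pid, children):
    return Event(id=pid, variant=EventVariant.Pathway, children=children)


def tp(entity, event, role):
    return TakesPart(entity=entity, event=event, role=Role(role))


class TestFlatten:
    def test_two_step_module(self, m00021):
        assert [e.id for e in m00021.flatten("M00021")] == ["R00586", "R00897"]

    def test_nested_pathway_expands_depth_first(self):
        events = {e.id: e for e in [
            process("A"), process("B"), process("C"),
            pathway("P1", ["A", "B"]), pathway("top", ["P1", "C"])]}
        assert [e.id for e in flatten(events, "top")] == ["A", "B", "C"]

    def test_single_child_wrapper_is_invisible(self):
        events = {e.id: e for e in [
            process("A"), process("B"), pathway("inner", ["A", "B"]),
            pathway("outer", ["inner"])]}
        assert ([e.id for e in flatten(events, "outer")]
                == [e.id for e in flatten(events, "inner")])

    def test_cycle_detected(self):
        events = {e.id: e for e in [
            pathway("P1", ["P2"]), pathway("P2", ["P1"])]}
        with pytest.raises(CycleError):
            flatten(events, "P1")
        with pytest.raises(CycleError):
            flatten({"P": pathway("P", ["P"])}, "P")

    def test_flattening_a_process_rejected(self):
        with pytest.raises(ValueError):
            flatten({"A": process("A")}, "A")


class TestRollup:
    def test_cysteine_biosynthesis_net_sets(self, m00021):
        """O-acetyl-L-serine (C00979) is produced by the first reaction and
        consumed by the second, so it cancels out of the module-level sets."""
        result = m00021.rollup("M00021")
        assert result.inputs == {"C00065", "C00024", "C00283"}
        assert result.outputs == {"C00010", "C00097", "C00033"}
        assert result.regulators == {"2.3.1.30", "2.5.1.47"}
        assert result.intermediates == {"C00979"}

    def test_gross_mode_keeps_plain_unions(self, m00021):
        result = m00021.rollup("M00021", gross=True)
        assert "C00979" in result.inputs and "C00979" in result.outputs
        assert result.intermediates == set()

    def test_single_process_identity(self):
        events = {"A": process("A"), "P": pathway("P", ["A"])}
        parts = [tp("x", "A", "input"), tp("y", "A", "output"),
                 tp("e", "A", "regulator")]
        result = rollup(events, parts, "P")
        assert (result.inputs, result.outputs, result.regulators,
                result.intermediates) == ({"x"}, {"y"}, {"e"}, set())

    def test_independent_processes_union(self):
        events = {"A": process("A"), "B": process("B"),
                  "P": pathway("P", ["A", "B"])}
        parts = [tp("a_in", "A", "input"), tp("a_out", "A", "output"),
                 tp("b_in", "B", "input"), tp("b_out", "B", "output")]
        result = rollup(events, parts, "P")
        assert result.inputs == {"a_in", "b_in"}
        assert result.outputs == {"a_out", "b_out"}
        assert result.intermediates == set()

    def test_order_sensitivity(self):
        """An entity produced only after it is consumed is not an
        intermediate."""
        events = {"A": process("A"), "B": process("B"),
                  "P": pathway("P", ["A", "B"])}
        parts = [tp("x", "A", "input"), tp("y", "A", "output"),
                 tp("z", "B", "input"), tp("x", "B", "output")]
        result = rollup(events, parts, "P")
        assert result.intermediates == set()
        assert "x" in result.inputs and "x" in result.outputs

    def test_catalytic_cycle_never_intermediate(self):
        events = {"A": process("A"), "P": pathway("P", ["A"])}
        parts = [tp("x", "A", "input"), tp("x", "A", "output")]
        result = rollup(events, parts, "P")
        assert result.inputs == {"x"} and result.outputs == {"x"}
        assert result.intermediates == set()

    def test_process_without_participations_rejected(self):
        events = {"A": process("A"), "P": pathway("P", ["A"])}
        with pytest.raises(MissingParticipationError):
            rollup(events, [], "P")


def brute_force_rollup(order, parts):
    """Independent oracle: enumerate all (entity, role, position) triples."""
    triples = [(p.entity, p.role.value, i)
               for i, pid in enumerate(order) for p in parts if p.event == pid]
    intermediates = {
        e for (e, r, i) in triples if r == "output"
        and any(e2 == e and r2 == "input" and j > i for (e2, r2, j) in triples)
    }
    role_set = lambda role: {e for (e, r, _) in triples if r == role}
    return (role_set("input") - intermediates,
            role_set("output") - intermediates,
            role_set("regulator"),
            intermediates)


@st.composite
def random_pathways(draw):
    n_proc = draw(st.integers(1, 6))
    entities = [f"e{i}" for i in range(draw(st.integers(1, 12)))]
    order = [f"proc{i}" for i in range(n_proc)]
    parts = []
    for pid in order:
        n_parts = draw(st.integers(1, 5))
        for _ in range(n_parts):
            parts.append(tp(draw(st.sampled_from(entities)), pid,
                            draw(st.sampled_from(["input", "output",
                                                  "regulator"]))))
    return order, parts


@given(random_pathways())
def test_rollup_matches_brute_force_oracle(case):
    order, parts = case
    events = {pid: process(pid) for pid in order}
    events["P"] = pathway("P", order)
    # deduplicate as the instance store would: (entity, event, role) unique
    unique = {p.key(): p for p in parts}
    result = rollup(events, unique.values(), "P")
    expected = brute_force_rollup(order, unique.values())
    assert (result.inputs, result.outputs, result.regulators,
            result.intermediates) == expected
    # conservation: every net input is an input of some process
    all_inputs = {p.entity for p in unique.values() if p.role is Role.input}
    all_outputs = {p.entity for p in unique.values() if p.role is Role.output}
    assert result.inputs <= all_inputs and result.outputs <= all_outputs


class TestEntityTaxonomy:
    def test_simple_entity_clean(self):
        entities = {"a": BioEntity(id="a", variant=EntityVariant.Simple)}
        assert validate_entities(entities) == []

    def test_complex_needs_two_components(self):
        with pytest.raises(ValueError):
            BioEntity(id="c", variant=EntityVariant.Complex, components=["a"])

    def test_polymer_of_entity_set_reported(self):
        entities = {
            "a": BioEntity(id="a", variant=EntityVariant.Simple),
            "b": BioEntity(id="b", variant=EntityVariant.Simple),
            "s": BioEntity(id="s", variant=EntityVariant.EntitySet,
                           members=["a", "b"]),
            "p": BioEntity(id="p", variant=EntityVariant.Polymer, unit="s",
                           count=3),
        }
        report = validate_entities(entities)
        assert any(v.entity == "p" and "Polymer" in v.problem for v in report)

    def test_composition_cycle_reported(self):
        entities = {
            "x": BioEntity(id="x", variant=EntityVariant.Complex,
                           components=["y", "z"]),
            "y": BioEntity(id="y", variant=EntityVariant.Complex,
                           components=["x", "z"]),
            "z": BioEntity(id="z", variant=EntityVariant.Simple),
        }
        report = validate_entities(entities)
        assert any("cycle" in v.problem for v in report)

    def test_polymer_of_complex_allowed(self):
        entities = {
            "a": BioEntity(id="a", variant=EntityVariant.Simple),
            "b": BioEntity(id="b", variant=EntityVariant.Simple),
            "c": BioEntity(id="c", variant=EntityVariant.Complex,
                           components=["a", "b"]),
            "p": BioEntity(id="p", variant=EntityVariant.Polymer, unit="c"),
        }
        assert validate_entities(entities) == []
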