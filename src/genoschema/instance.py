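"""The instance store: typed records for all five views, cross-referenced
by id, with whole-instance validation and schema-capability emulation.

All writes go through ``add_*`` methods; cheap local invariants are checked
at write time by the pydantic record types, while cross-reference integrity
is checked by :meth:`Instance.validate`.  The ``mode`` selects which
conceptual schema governs the instance (see :mod:`genoschema.modes`), and
``strict`` validation additionally enforces the species-independent
definition that a protein is a set of at least one domain.
"""

from __future__ import annotations

from typing import Iterable, Optional

from . import genome_core as gc
from . import pathway as pw
from . import variation as vn
from .errors import CycleError, InstanceValidationError
from .modes import SchemaMode
from .provenance import BibliographyEntry, DataBankEntry, Entry, ProvenanceStore


class Instance:
    """A population of the genome schema's instance types."""

    def __init__(self, mode: SchemaMode = SchemaMode.CSG,
                 metadata: Optional[dict] = None) -> None:
        self.mode = SchemaMode(mode)
        self.metadata: dict = dict(metadata or {})
        # structural
        self.assemblies: dict[str, gc.Assembly] = {}
        self.chromosomes: dict[str, gc.Chromosome] = {}
        self.scaffolds: dict[str, gc.Scaffold] = {}
        self.elements: dict[str, gc.ChromosomeElement] = {}
        # transcription
        self.genes: dict[str, gc.Gene] = {}
        self.transcripts: dict[str, gc.Transcript] = {}
        self.proteins: dict[str, gc.Protein] = {}
        self.ortholog_groups: dict[str, gc.OrthologGroup] = {}
        # variation
        self.variations: dict[str, vn.Variation] = {}
        self.populations: dict[str, vn.Population] = {}
        self.individuals: dict[str, vn.Individual] = {}
        self.population_frequencies: dict[tuple[str, str],
                                          vn.PopulationFrequencyRecord] = {}
        self.observations: dict[tuple[str, str], vn.IndividualObservation] = {}
        # pathway
        self.entities: dict[str, pw.BioEntity] = {}
        self.events: dict[str, pw.Event] = {}
        self.takes_part: dict[tuple[str, str, str], pw.TakesPart] = {}
        # provenance
        self.provenance = ProvenanceStore(self.element_exists, self.mode)

    # ------------------------------------------------------------------
    # id bookkeeping

    def _record_maps(self) -> list[dict]:
        return [self.assemblies, self.chromosomes, self.scaffolds,
                self.elements, self.genes, self.transcripts, self.proteins,
                self.ortholog_groups, self.variations, self.populations,
                self.individuals, self.entities, self.events]

    def element_exists(self, element_id: str) -> bool:
        return any(element_id in m for m in self._record_maps())

    def _add(self, store: dict, record) -> None:
        if self.element_exists(record.id):
            raise ValueError(f"duplicate instance id {record.id!r}")
        store[record.id] = record

    # ------------------------------------------------------------------
    # structural / transcription writes

    def add_assembly(self, assembly: gc.Assembly) -> gc.Assembly:
        self._add(self.assemblies, assembly)
        return assembly

    def add_chromosome(self, chromosome: gc.Chromosome) -> gc.Chromosome:
        self._add(self.chromosomes, chromosome)
        return chromosome

    def add_scaffold(self, scaffold_id: str, chromosome: str, sequence: str,
                     placement: Optional[gc.Placement] = None) -> gc.Scaffold:
        scaffold = gc.add_scaffold(scaffold_id, chromosome, sequence, placement)
        self._add(self.scaffolds, scaffold)
        return scaffold

    def add_element(self, element: gc.ChromosomeElement) -> gc.ChromosomeElement:
        if self.mode is SchemaMode.CSCG and len(element.positions) > 1:
            from .errors import CapabilityError
            raise CapabilityError(
                "the CSCG works with a single assembly; multi-assembly "
                "positions cannot be represented")
        self._add(self.elements, element)
        return element

    def add_gene(self, gene: gc.Gene) -> gc.Gene:
        self._add(self.genes, gene)
        return gene

    def add_transcript(self, transcript: gc.Transcript) -> gc.Transcript:
        self._add(self.transcripts, transcript)
        return transcript

    def add_protein(self, protein: gc.Protein) -> gc.Protein:
        self._add(self.proteins, protein)
        return protein

    def add_ortholog_group(self, group: gc.OrthologGroup) -> gc.OrthologGroup:
        self._add(self.ortholog_groups, group)
        return group

    def locate(self, element_id: str, assembly: str) -> gc.GenomicPosition:
        return gc.locate(self.elements[element_id], assembly)

    # ------------------------------------------------------------------
    # variation writes

    def add_variation(self, record: vn.Variation | dict) -> vn.Variation:
        variation = vn.register_variation(record)
        self._add(self.variations, variation)
        return variation

    def add_population(self, population: vn.Population) -> vn.Population:
        self._add(self.populations, population)
        return population

    def add_individual(self, individual: vn.Individual) -> vn.Individual:
        self._add(self.individuals, individual)
        return individual

    def set_population_frequencies(
        self, variation_id: str, population_id: str,
        allele_freqs: dict[str, float], genotype_freqs: dict[str, float],
    ) -> vn.PopulationFrequencyRecord:
        record = vn.make_population_frequencies(
            self.variations[variation_id], self.populations[population_id],
            allele_freqs, genotype_freqs, mode=self.mode)
        self.population_frequencies[(variation_id, population_id)] = record
        return record

    def add_individual_observation(
        self, variation_id: str, individual_id: str,
        genotype: Iterable[str],
        allele_fractions: Optional[dict[str, float]] = None,
    ) -> vn.IndividualObservation:
        obs = vn.make_individual_observation(
            self.variations[variation_id], self.individuals[individual_id],
            list(genotype), allele_fractions, mode=self.mode)
        self.observations[(variation_id, individual_id)] = obs
        return obs

    def aggregate_frequencies(self, population_id: str,
                              variation_id: str) -> vn.PopulationFrequencyRecord:
        population = self.populations[population_id]
        variation = self.variations[variation_id]
        per_member = {
            ind: obs for (var, ind), obs in self.observations.items()
            if var == variation_id
        }
        return vn.aggregate_frequencies(population, variation, per_member)

    # ------------------------------------------------------------------
    # pathway writes and queries

    def add_entity(self, entity: pw.BioEntity) -> pw.BioEntity:
        self._add(self.entities, entity)
        return entity

    def add_event(self, event: pw.Event) -> pw.Event:
        self._add(self.events, event)
        return event

    def add_takes_part(self, record: pw.TakesPart) -> pw.TakesPart:
        self.takes_part[record.key()] = record
        return record

    def flatten(self, pathway_id: str) -> list[pw.Event]:
        return pw.flatten(self.events, pathway_id)

    def rollup(self, pathway_id: str, gross: bool = False) -> pw.PathwayIO:
        return pw.rollup(self.events, self.takes_part.values(), pathway_id,
                         gross=gross)

    # ------------------------------------------------------------------
    # provenance

    def attach_reference(self, element_id: str, entry: Entry):
        return self.provenance.attach_reference(element_id, entry)

    def references_of(self, element_id: str) -> list[Entry]:
        return self.provenance.references_of(element_id)

    def delete_element(self, element_id: str) -> None:
        """Remove a record and every provenance link pointing at it."""
        for store in self._record_maps():
            if element_id in store:
                del store[element_id]
                self.provenance.drop_element(element_id)
                return
        raise KeyError(element_id)

    # ------------------------------------------------------------------
    # validation

    def validate(self, strict: bool = True) -> list[str]:
        """Return all cross-reference and invariant violations."""
        v: list[str] = []

        def ref(ok: bool, message: str) -> None:
            if not ok:
                v.append(message)

        for scaffold in self.scaffolds.values():
            ref(scaffold.chromosome in self.chromosomes,
                f"scaffold {scaffold.id}: unknown chromosome {scaffold.chromosome!r}")
            if scaffold.placement is not None:
                ref(scaffold.placement.assembly in self.assemblies,
                    f"scaffold {scaffold.id}: unknown assembly "
                    f"{scaffold.placement.assembly!r}")
        for element in self.elements.values():
            for assembly, pos in element.positions.items():
                ref(assembly in self.assemblies,
                    f"element {element.id}: unknown assembly {assembly!r}")
                ref(pos.chromosome in self.chromosomes,
                    f"element {element.id}: unknown chromosome {pos.chromosome!r}")
        for gene in self.genes.values():
            for eid in gene.elements:
                ref(eid in self.elements,
                    f"gene {gene.id}: unknown element {eid!r}")
        for transcript in self.transcripts.values():
            for gid in transcript.genes:
                ref(gid in self.genes,
                    f"transcript {transcript.id}: unknown gene {gid!r}")
            for eid in transcript.exonic_elements:
                ref(eid in self.elements,
                    f"transcript {transcript.id}: unknown element {eid!r}")
        for protein in self.proteins.values():
            for tid in protein.coded_by:
                ref(tid in self.transcripts,
                    f"protein {protein.id}: unknown transcript {tid!r}")
            if strict and not protein.domains:
                v.append(f"protein {protein.id}: a protein is a set of at "
                         "least one domain (strict validation)")
        for group in self.ortholog_groups.values():
            for gid in group.genes:
                ref(gid in self.genes,
                    f"ortholog group {group.id}: unknown gene {gid!r}")
            for pid in group.proteins:
                ref(pid in self.proteins,
                    f"ortholog group {group.id}: unknown protein {pid!r}")
        for variation in self.variations.values():
            for eid in variation.affected_elements:
                ref(eid in self.elements,
                    f"variation {variation.id}: unknown element {eid!r}")
            for assembly in variation.positions:
                ref(assembly in self.assemblies,
                    f"variation {variation.id}: unknown assembly {assembly!r}")
        for population in self.populations.values():
            for member in population.members:
                ref(member in self.individuals,
                    f"population {population.id}: unknown individual {member!r}")
        for individual in self.individuals.values():
            for pid in individual.populations:
                ref(pid in self.populations,
                    f"individual {individual.id}: unknown population {pid!r}")
        for (var, pop) in self.population_frequencies:
            ref(var in self.variations, f"frequency record: unknown variation {var!r}")
            ref(pop in self.populations, f"frequency record: unknown population {pop!r}")
        for (var, ind) in self.observations:
            ref(var in self.variations, f"observation: unknown variation {var!r}")
            ref(ind in self.individuals, f"observation: unknown individual {ind!r}")
        for tp in self.takes_part.values():
            ref(tp.entity in self.entities,
                f"takes-part: unknown entity {tp.entity!r}")
            ref(tp.event in self.events, f"takes-part: unknown event {tp.event!r}")
        for event in self.events.values():
            for child in event.children:
                ref(child in self.events,
                    f"pathway {event.id}: unknown event {child!r}")
        for event in self.events.values():
            if event.variant is pw.EventVariant.Pathway and all(
                    c in self.events for c in event.children):
                try:
                    pw.flatten(self.events, event.id)
                except CycleError as exc:
                    v.append(str(exc))
                except KeyError:
                    pass
        v.extend(f"entity {viol.entity}: {viol.problem}"
                 for viol in pw.validate_entities(self.entities))
        for link in self.provenance.links:
            ref(self.element_exists(link.element),
                f"reference link: unknown element {link.element!r}")
        return v

    def check_valid(self, strict: bool = True) -> None:
        violations = self.validate(strict=strict)
        if violations:
            raise InstanceValidationError(violations)
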