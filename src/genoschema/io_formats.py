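"""Readers and writers: the canonical instance JSON document, FASTA and
VCF-lite input, pathway tables, and knowledge-graph export.

The instance document is a single JSON object with one list of typed
records per view.  Every record carries ``id`` and ``type`` (a concept name
of the governing schema) and refers to other records by id.  Coordinates in
the document are 1-based inclusive, identical to the in-memory model.

Graph export mirrors a property-graph instantiation: one node per record,
one edge per resolved cross-reference, with nodes coloured by view
(structural green, transcription blue, variation light brown, provenance
yellow, pathway pink).  Takes-part records are exported as role-labelled
edges between entity and event nodes.  Output ordering is stable (sorted
by id), so two exports of one instance are byte-identical.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Optional, Union

import networkx as nx
from Bio import SeqIO

from . import genome_core as gc
from . import pathway as pw
from . import variation as vn
from .errors import FormatError
from .instance import Instance
from .metamodel import SchemaDef, default_registry
from .modes import SchemaMode
from .provenance import BibliographyEntry, DataBankEntry, ReferenceLink

FORMAT_VERSION = "1.0"

VIEW_COLORS = {
    "structural": "green",
    "transcription": "blue",
    "variation": "light brown",
    "provenance": "yellow",
    "pathway": "pink",
}

#: Document record type -> (view, schema concepts the type instantiates).
TYPE_CONCEPTS: dict[str, tuple[str, tuple[str, ...]]] = {
    "Assembly": ("structural", ("Assembly",)),
    "Chromosome": ("structural", ("Chromosome",)),
    "Scaffold": ("structural", ("Scaffold",)),
    "ChromosomeElement": ("structural", ("ChromosomeElement",)),
    "Gene": ("transcription", ("Gene",)),
    "Transcript": ("transcription", ("Transcript",)),
    "MessengerRNA": ("transcription", ("MessengerRNA",)),
    "Protein": ("transcription", ("Protein",)),
    "OrthologGroup": ("transcription", ("OrthologGroup",)),
    "Variation": ("variation", ("Variation",)),
    "Population": ("variation", ("Population",)),
    "Individual": ("variation", ("Individual",)),
    "PopulationFrequency": ("variation", ("PopulationAlleleFrequency",
                                          "PopulationGenotypeFrequency")),
    "IndividualObservation": ("variation", ("IndividualAlleleFrequency",
                                            "IndividualGenotypeFrequency")),
    "BioEntity": ("pathway", ("BioEntity",)),
    "Event": ("pathway", ("Event",)),
    "TakesPart": ("pathway", ("TakesPart",)),
    "DataBankEntry": ("provenance", ("DataBankEntry",)),
    "BibliographyEntry": ("provenance", ("BibliographyEntry",)),
    "ReferenceLink": ("provenance", ("ReferenceLink",)),
}

_SECTIONS = ("structural", "transcription", "variation", "pathway", "provenance")


def _dump(record, rtype: str, rid: str) -> dict:
    data = record.model_dump(mode="json")
    if rtype == "ChromosomeElement":
        data["roles"] = sorted(data["roles"])
    return {"id": rid, "type": rtype, **data}


def instance_to_document(instance: Instance) -> dict:
    """Serialize an instance into the canonical JSON document (dict form)."""
    doc: dict = {
        "format_version": FORMAT_VERSION,
        "governing_schema": instance.mode.value,
        "metadata": instance.metadata,
    }
    sections: dict[str, list[dict]] = {name: [] for name in _SECTIONS}

    def emit(section: str, rtype: str, store: dict) -> None:
        for rid in sorted(store):
            sections[section].append(_dump(store[rid], rtype, rid))

    emit("structural", "Assembly", instance.assemblies)
    emit("structural", "Chromosome", instance.chromosomes)
    emit("structural", "Scaffold", instance.scaffolds)
    emit("structural", "ChromosomeElement", instance.elements)
    emit("transcription", "Gene", instance.genes)
    for tid in sorted(instance.transcripts):
        record = instance.transcripts[tid]
        rtype = ("MessengerRNA" if isinstance(record, gc.MessengerRNA)
                 else "Transcript")
        sections["transcription"].append(_dump(record, rtype, tid))
    emit("transcription", "Protein", instance.proteins)
    emit("transcription", "OrthologGroup", instance.ortholog_groups)
    emit("variation", "Variation", instance.variations)
    emit("variation", "Population", instance.populations)
    emit("variation", "Individual", instance.individuals)
    for (var, pop) in sorted(instance.population_frequencies):
        record = instance.population_frequencies[(var, pop)]
        sections["variation"].append(_dump(record, "PopulationFrequency",
                                           f"freq:{var}:{pop}"))
    for (var, ind) in sorted(instance.observations):
        record = instance.observations[(var, ind)]
        sections["variation"].append(_dump(record, "IndividualObservation",
                                           f"obs:{var}:{ind}"))
    emit("pathway", "BioEntity", instance.entities)
    emit("pathway", "Event", instance.events)
    for key in sorted(instance.takes_part):
        record = instance.takes_part[key]
        sections["pathway"].append(_dump(record, "TakesPart",
                                         "tp:" + ":".join(key)))
    for key in sorted(instance.provenance.entries):
        entry = instance.provenance.entries[key]
        rtype = ("DataBankEntry" if isinstance(entry, DataBankEntry)
                 else "BibliographyEntry")
        sections["provenance"].append(_dump(entry, rtype, key))
    for link in sorted(instance.provenance.links,
                       key=lambda x: (x.element, x.entry)):
        sections["provenance"].append(_dump(link, "ReferenceLink",
                                            f"link:{link.element}:{link.entry}"))
    doc.update(sections)
    return doc


def document_to_instance(doc: dict,
                         schema: Optional[SchemaDef] = None,
                         strict: bool = True) -> Instance:
    """Materialize an instance from a document, checking record types
    against the governing schema (capability violations raise in strict
    mode)."""
    governing = doc.get("governing_schema", SchemaMode.CSG.value)
    if schema is None:
        registry = default_registry()
        schema = registry.get(governing) if governing in registry else None
    instance = Instance(mode=SchemaMode(governing) if governing in
                        SchemaMode._value2member_map_ else SchemaMode.CSG,
                        metadata=doc.get("metadata"))

    for section in _SECTIONS:
        for raw in doc.get(section, []):
            rtype = raw.get("type")
            if rtype not in TYPE_CONCEPTS:
                raise FormatError(f"unknown concept type {rtype!r}")
            if schema is not None and strict:
                missing = [c for c in TYPE_CONCEPTS[rtype][1]
                           if not schema.has_concept(c)]
                if missing:
                    raise FormatError(
                        f"record type {rtype!r} instantiates concepts "
                        f"{missing} absent from schema {schema.id}")
            data = {k: v for k, v in raw.items() if k not in ("type",)}
            _load_record(instance, rtype, data)
    return instance


#: Record types whose models carry no ``id`` field; the document id for
#: these is synthesized from their natural key and dropped on load.
_SYNTHETIC_ID_TYPES = frozenset({
    "PopulationFrequency", "IndividualObservation", "TakesPart",
    "DataBankEntry", "ReferenceLink",
})


def _load_record(instance: Instance, rtype: str, data: dict) -> None:
    if rtype in _SYNTHETIC_ID_TYPES:
        data.pop("id", None)
    if rtype == "Assembly":
        instance.add_assembly(gc.Assembly.model_validate(data))
    elif rtype == "Chromosome":
        instance.add_chromosome(gc.Chromosome.model_validate(data))
    elif rtype == "Scaffold":
        scaffold = gc.Scaffold.model_validate(data)
        instance._add(instance.scaffolds, scaffold)
    elif rtype == "ChromosomeElement":
        instance.add_element(gc.ChromosomeElement.model_validate(data))
    elif rtype == "Gene":
        instance.add_gene(gc.Gene.model_validate(data))
    elif rtype == "Transcript":
        instance.add_transcript(gc.Transcript.model_validate(data))
    elif rtype == "MessengerRNA":
        instance.add_transcript(gc.MessengerRNA.model_validate(data))
    elif rtype == "Protein":
        instance.add_protein(gc.Protein.model_validate(data))
    elif rtype == "OrthologGroup":
        instance.add_ortholog_group(gc.OrthologGroup.model_validate(data))
    elif rtype == "Variation":
        instance.add_variation(vn.Variation.model_validate(data))
    elif rtype == "Population":
        instance.add_population(vn.Population.model_validate(data))
    elif rtype == "Individual":
        instance.add_individual(vn.Individual.model_validate(data))
    elif rtype == "PopulationFrequency":
        record = vn.PopulationFrequencyRecord.model_validate(data)
        instance.population_frequencies[(record.variation, record.population)] = record
    elif rtype == "IndividualObservation":
        record = vn.IndividualObservation.model_validate(data)
        instance.observations[(record.variation, record.individual)] = record
    elif rtype == "BioEntity":
        instance.add_entity(pw.BioEntity.model_validate(data))
    elif rtype == "Event":
        instance.add_event(pw.Event.model_validate(data))
    elif rtype == "TakesPart":
        instance.add_takes_part(pw.TakesPart.model_validate(data))
    elif rtype == "DataBankEntry":
        entry = DataBankEntry.model_validate(data)
        instance.provenance.entries[entry.key()] = entry
    elif rtype == "BibliographyEntry":
        entry = BibliographyEntry.model_validate(data)
        instance.provenance.entries[entry.key()] = entry
    elif rtype == "ReferenceLink":
        instance.provenance.links.append(ReferenceLink.model_validate(data))


def save_instance(instance: Instance, path: Union[str, Path]) -> dict:
    """Write the canonical document to ``path``; returns the document."""
    doc = instance_to_document(instance)
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
    return doc


def load_instance(path: Union[str, Path],
                  schema: Optional[SchemaDef] = None,
                  strict: bool = True) -> Instance:
    with open(path) as fh:
        doc = json.load(fh)
    return document_to_instance(doc, schema=schema, strict=strict)


# ----------------------------------------------------------------------
# graph export

def _graph_parts(instance: Instance) -> tuple[list[tuple], list[tuple]]:
    """(nodes, edges) of the knowledge graph, in deterministic order.

    Nodes: (id, label, view, color).  Edges: (source, target, type).
    Takes-part and reference-link records become edges, not nodes.
    """
    nodes: list[tuple] = []
    edges: list[tuple] = []

    def node(rid: str, label: str) -> None:
        view = TYPE_CONCEPTS[label][0]
        nodes.append((rid, label, view, VIEW_COLORS[view]))

    for rid in sorted(instance.assemblies):
        node(rid, "Assembly")
    for rid in sorted(instance.chromosomes):
        node(rid, "Chromosome")
    for rid, s in sorted(instance.scaffolds.items()):
        node(rid, "Scaffold")
        edges.append((rid, s.chromosome, "in_chromosome"))
    for rid, e in sorted(instance.elements.items()):
        node(rid, "ChromosomeElement")
        for assembly in sorted(e.positions):
            edges.append((rid, assembly, "positioned_in"))
    for rid, g in sorted(instance.genes.items()):
        node(rid, "Gene")
        edges.extend((rid, eid, "combines") for eid in g.elements)
    for rid, t in sorted(instance.transcripts.items()):
        node(rid, "MessengerRNA" if isinstance(t, gc.MessengerRNA)
             else "Transcript")
        edges.extend((rid, gid, "transcribed_from") for gid in t.genes)
        edges.extend((rid, eid, "uses_exon") for eid in t.exonic_elements)
    for rid, p in sorted(instance.proteins.items()):
        node(rid, "Protein")
        edges.extend((rid, tid, "coded_by") for tid in p.coded_by)
    for rid, og in sorted(instance.ortholog_groups.items()):
        node(rid, "OrthologGroup")
        edges.extend((rid, gid, "groups_gene") for gid in og.genes)
        edges.extend((rid, pid, "groups_protein") for pid in og.proteins)
    for rid, var in sorted(instance.variations.items()):
        node(rid, "Variation")
        edges.extend((rid, eid, "affects") for eid in var.affected_elements)
    for rid, pop in sorted(instance.populations.items()):
        node(rid, "Population")
        edges.extend((rid, ind, "has_member") for ind in pop.members)
    for rid in sorted(instance.individuals):
        node(rid, "Individual")
    for (var, pop) in sorted(instance.population_frequencies):
        rid = f"freq:{var}:{pop}"
        node(rid, "PopulationFrequency")
        edges.append((rid, var, "frequency_of"))
        edges.append((rid, pop, "observed_in"))
    for (var, ind) in sorted(instance.observations):
        rid = f"obs:{var}:{ind}"
        node(rid, "IndividualObservation")
        edges.append((rid, var, "frequency_of"))
        edges.append((rid, ind, "observed_in"))
    for rid, entity in sorted(instance.entities.items()):
        node(rid, "BioEntity")
        edges.extend((rid, child, "composed_of") for child in entity.children())
    for rid, event in sorted(instance.events.items()):
        node(rid, "Event")
        edges.extend((rid, child, "contains") for child in event.children)
    for key in sorted(instance.takes_part):
        entity, event, role = key
        edges.append((entity, event, role))
    for ekey in sorted(instance.provenance.entries):
        entry = instance.provenance.entries[ekey]
        node(ekey, "DataBankEntry" if isinstance(entry, DataBankEntry)
             else "BibliographyEntry")
    for link in sorted(instance.provenance.links,
                       key=lambda x: (x.element, x.entry)):
        edges.append((link.element, link.entry, "references"))

    edges.sort()
    return nodes, edges


def export_graph(instance: Instance, fmt: str,
                 out: Union[str, Path]) -> list[Path]:
    """Write the instance as a knowledge graph.

    ``fmt`` is ``graphml`` (one file at ``out``) or ``csv`` (``nodes.csv``
    and ``edges.csv`` inside the directory ``out``).  Returns the paths
    written.
    """
    nodes, edges = _graph_parts(instance)
    out = Path(out)
    if fmt == "graphml":
        graph = nx.MultiDiGraph()
        for rid, label, view, color in nodes:
            graph.add_node(rid, label=label, view=view, color=color)
        for source, target, etype in edges:
            graph.add_edge(source, target, type=etype)
        nx.write_graphml(graph, out)
        return [out]
    if fmt == "csv":
        out.mkdir(parents=True, exist_ok=True)
        nodes_path, edges_path = out / "nodes.csv", out / "edges.csv"
        with open(nodes_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "label", "view", "color"])
            writer.writerows(nodes)
        with open(edges_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["source", "target", "type"])
            writer.writerows(edges)
        return [nodes_path, edges_path]
    raise ValueError(f"unsupported graph format {fmt!r}")


# ----------------------------------------------------------------------
# external format readers

def read_pathway_table(path: Union[str, Path]) -> Instance:
    """Read a pathway table (KEGG-style module JSON) into an instance.

    Expected shape: ``{"module": id, "reactions": [{"id", "inputs",
    "outputs", "enzymes"}, ...]}``; identifiers are opaque strings (KEGG
    C/R/M codes and EC numbers pass through unchanged).  Compound and
    enzyme names may be supplied in an optional ``"names"`` mapping.
    """
    with open(path) as fh:
        table = json.load(fh)
    return pathway_table_to_instance(table)


def pathway_table_to_instance(table: dict) -> Instance:
    names = table.get("names", {})
    instance = Instance()
    order = []
    for reaction in table["reactions"]:
        rid = reaction["id"]
        order.append(rid)
        instance.add_event(pw.Event(id=rid, name=names.get(rid, ""),
                                    variant=pw.EventVariant.Process))
        for role, field in (("input", "inputs"), ("output", "outputs"),
                            ("regulator", "enzymes")):
            for entity_id in reaction.get(field, []):
                if entity_id not in instance.entities:
                    instance.add_entity(pw.BioEntity(
                        id=entity_id, name=names.get(entity_id, ""),
                        variant=pw.EntityVariant.Simple))
                instance.add_takes_part(pw.TakesPart(
                    entity=entity_id, event=rid, role=pw.Role(role)))
    instance.add_event(pw.Event(id=table["module"],
                                name=names.get(table["module"], ""),
                                variant=pw.EventVariant.Pathway,
                                children=order))
    return instance


def read_vcf_lite(path: Union[str, Path],
                  assembly: str = "default") -> Instance:
    """Read the VCF-lite dialect into an instance.

    Tab-separated ``CHROM POS ID REF ALT QUAL FILTER INFO FORMAT sample+``
    with 1-based POS.  Only the GT subfield of FORMAT is interpreted; INFO
    is deliberately ignored.  Missing ("." ) alleles in a genotype are
    rejected.  One line maps to one (possibly multi-allelic) variation.
    """
    instance = Instance()
    instance.add_assembly(gc.Assembly(id=assembly, species="unspecified"))
    sample_names: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#"):
                sample_names = line.lstrip("#").split("\t")[9:]
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise FormatError(
                    f"expected at least 10 tab-separated fields, got "
                    f"{len(fields)}", line=lineno)
            chrom, pos, vid, ref, alt, _qual, _filter, _info, fmt = fields[:9]
            samples = fields[9:]
            try:
                pos_i = int(pos)
            except ValueError:
                raise FormatError(f"POS {pos!r} is not an integer", line=lineno)
            if pos_i < 1:
                raise FormatError("POS must be 1-based and positive", line=lineno)
            alts = alt.split(",")
            if "." in (ref, *alts):
                raise FormatError("missing ('.') alleles are not supported",
                                  line=lineno)
            if chrom not in instance.chromosomes:
                instance.add_chromosome(gc.Chromosome(
                    id=chrom, name=chrom, species="unspecified"))
            alleles = [ref, *alts]
            kind = _infer_kind(ref, alts)
            end = pos_i + len(ref) - 1
            try:
                variation = instance.add_variation(vn.Variation(
                    id=vid if vid != "." else f"{chrom}:{pos_i}",
                    kind=kind, reference_allele=ref, alternative_alleles=alts,
                    positions={assembly: gc.GenomicPosition(
                        assembly=assembly, chromosome=chrom,
                        start=pos_i, end=end)},
                ))
            except ValueError as exc:
                raise FormatError(str(exc), line=lineno) from exc
            gt_index = fmt.split(":").index("GT") if "GT" in fmt.split(":") else None
            if gt_index is None:
                continue
            for i, sample in enumerate(samples):
                name = (sample_names[i] if i < len(sample_names)
                        else f"sample{i + 1}")
                gt = sample.split(":")[gt_index]
                genotype = []
                for token in gt.replace("|", "/").split("/"):
                    if token == ".":
                        raise FormatError(
                            f"missing allele in genotype {gt!r} of {name}",
                            line=lineno)
                    try:
                        genotype.append(alleles[int(token)])
                    except (ValueError, IndexError):
                        raise FormatError(
                            f"invalid allele index {token!r} in genotype "
                            f"{gt!r}", line=lineno) from None
                if name not in instance.individuals:
                    instance.add_individual(vn.Individual(
                        id=name, species="unspecified",
                        ploidy=len(genotype)))
                instance.add_individual_observation(
                    variation.id, name, genotype)
    return instance


def _infer_kind(ref: str, alts: list[str]) -> vn.VariationKind:
    if len(ref) == 1 and all(len(a) == 1 for a in alts):
        return vn.VariationKind.SNP
    if len(ref) == 1 and all(len(a) > 1 for a in alts):
        return vn.VariationKind.insertion
    if len(ref) > 1 and all(len(a) == 1 for a in alts):
        return vn.VariationKind.deletion
    return vn.VariationKind.indel


def read_fasta(path: Union[str, Path],
               chromosome: str = "unplaced") -> list[gc.Scaffold]:
    """Read line-wrapped FASTA (case-insensitive) into scaffolds.

    The record id becomes the scaffold id; gaps are derived from N-runs.
    The returned scaffolds all point at ``chromosome``, which the caller is
    responsible for registering when building an instance.
    """
    scaffolds = []
    for record in SeqIO.parse(str(path), "fasta"):
        scaffolds.append(gc.add_scaffold(record.id, chromosome,
                                         str(record.seq)))
    return scaffolds
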