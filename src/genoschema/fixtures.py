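"""Worked-example and synthetic instances.

``cysteine_pathway`` builds the two-step cysteine biosynthesis module
M00021 (KEGG identifiers as opaque strings); ``cftr_example`` builds a
minimal cystic-fibrosis variation instance around the HGVS expression
NM_000492.3(CFTR):c.57G>A(p.Trp19Ter) with ClinVar accession 487391.  The
genomic coordinates in the CFTR instance are synthetic placeholders (the
``synthetic_coordinates`` metadata flag marks them as such) — the example
exercises the model's structure, not real annotation.

``synthetic`` generates seeded instances of arbitrary size for testing.
Population frequencies are produced by first drawing individual genotypes
and then aggregating them, so frequency aggregation recovers them exactly
by construction.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, Field, model_validator

from . import genome_core as gc
from . import pathway as pw
from . import variation as vn
from .instance import Instance
from .io_formats import pathway_table_to_instance
from .provenance import BibliographyEntry, DataBankEntry

#: The M00021 module exactly as tabulated: ordered reactions with their
#: compound inputs/outputs and EC-numbered enzyme regulators.
M00021_TABLE = {
    "module": "M00021",
    "reactions": [
        {"id": "R00586",
         "inputs": ["C00065", "C00024"],
         "outputs": ["C00979", "C00010"],
         "enzymes": ["2.3.1.30"]},
        {"id": "R00897",
         "inputs": ["C00979", "C00283"],
         "outputs": ["C00097", "C00033"],
         "enzymes": ["2.5.1.47"]},
    ],
    "names": {
        "M00021": "Cysteine biosynthesis",
        "R00586": "acetyl-CoA:L-serine O-acetyltransferase",
        "R00897": "O3-acetyl-L-serine acetate-lyase",
        "C00065": "L-Serine",
        "C00024": "Acetyl-CoA",
        "C00979": "O-Acetyl-L-serine",
        "C00010": "CoA",
        "C00283": "Hydrogen sulfide",
        "C00097": "L-Cysteine",
        "C00033": "Acetate",
        "2.3.1.30": "serine O-acetyltransferase",
        "2.5.1.47": "cysteine synthase",
    },
}


def cysteine_pathway() -> Instance:
    """The cysteine biosynthesis module M00021 as a pathway instance."""
    instance = pathway_table_to_instance(M00021_TABLE)
    instance.metadata["fixture"] = "cysteine_pathway"
    return instance


def cftr_example() -> Instance:
    """A minimal CFTR variation instance spanning all five views.

    CFTR has twenty-seven exons; one representative exon (plus one intron
    and one promoter) stands in for the full structure.  Numeric genomic
    coordinates are synthetic placeholders, flagged in the metadata.
    """
    instance = Instance(metadata={
        "fixture": "cftr_example",
        "synthetic_coordinates": True,
    })
    instance.add_assembly(gc.Assembly(id="GRCh37", species="Homo sapiens",
                                      version="GRCh37"))
    instance.add_assembly(gc.Assembly(id="GRCh38", species="Homo sapiens",
                                      version="GRCh38"))
    chrom = instance.add_chromosome(gc.Chromosome(
        id="chr7", name="7", species="Homo sapiens"))

    def positions(start37: int, end37: int, start38: int, end38: int):
        return {
            "GRCh37": gc.GenomicPosition(assembly="GRCh37", chromosome=chrom.id,
                                         start=start37, end=end37),
            "GRCh38": gc.GenomicPosition(assembly="GRCh38", chromosome=chrom.id,
                                         start=start38, end=end38),
        }

    promoter = instance.add_element(gc.ChromosomeElement(
        id="CFTR_promoter", kind=gc.ElementKind.promoter,
        positions=positions(1000, 1999, 2000, 2999)))
    exon1 = instance.add_element(gc.ChromosomeElement(
        id="CFTR_exon1", kind=gc.ElementKind.exon,
        positions=positions(2000, 2184, 3000, 3184)))
    intron1 = instance.add_element(gc.ChromosomeElement(
        id="CFTR_intron1", kind=gc.ElementKind.intron,
        positions=positions(2185, 4999, 3185, 5999)))

    gene = instance.add_gene(gc.Gene(
        id="CFTR", symbol="CFTR", species="Homo sapiens",
        elements=[promoter.id, exon1.id, intron1.id]))

    transcript = gc.Transcript(id="NM_000492.3", genes=[gene.id],
                               exonic_elements=[exon1.id], length=6132)
    mrna = gc.build_mrna(transcript, utr5_len=70, cds_len=4443, utr3_len=1619)
    instance.add_transcript(mrna)

    protein = instance.add_protein(gc.Protein(
        id="CFTR_protein", name="CFTR", coded_by=[mrna.id], length=1480,
        domains=[gc.ProteinDomain(id="CFTR_protein_dom1",
                                  name="whole-length placeholder domain",
                                  start=1, end=1480)]))

    variation = instance.add_variation(vn.Variation(
        id="CFTR_c.57G>A", kind=vn.VariationKind.SNP,
        reference_allele="G", alternative_alleles=["A"],
        hgvs="NM_000492.3(CFTR):c.57G>A(p.Trp19Ter)",
        affected_elements=[exon1.id],
        clinical_significance="pathogenic",
        positions=positions(2056, 2056, 3056, 3056)))

    population = instance.add_population(vn.Population(
        id="European", description="European population",
        members=["individual_under_study"]))
    instance.add_individual(vn.Individual(
        id="individual_under_study", species="Homo sapiens",
        populations=[population.id]))
    instance.add_individual_observation(variation.id, "individual_under_study",
                                        ("G", "A"))
    instance.set_population_frequencies(
        variation.id, population.id,
        allele_freqs={"G": 0.99997, "A": 0.00003},
        genotype_freqs={"G/G": 0.99994, "A/G": 0.00006})

    # a small pathway in which the CFTR protein acts as regulator
    chloride_out = instance.add_entity(pw.BioEntity(
        id="chloride_extracellular", name="chloride (extracellular)",
        variant=pw.EntityVariant.Simple))
    chloride_in = instance.add_entity(pw.BioEntity(
        id="chloride_intracellular", name="chloride (intracellular)",
        variant=pw.EntityVariant.Simple))
    channel = instance.add_entity(pw.BioEntity(
        id="CFTR_channel", name="CFTR", variant=pw.EntityVariant.Simple))
    process = instance.add_event(pw.Event(
        id="chloride_transport", name="chloride transport",
        variant=pw.EventVariant.Process))
    instance.add_event(pw.Event(
        id="ion_transport", name="transmembrane ion transport",
        variant=pw.EventVariant.Pathway, children=[process.id]))
    instance.add_takes_part(pw.TakesPart(entity=chloride_in.id,
                                         event=process.id, role=pw.Role.input))
    instance.add_takes_part(pw.TakesPart(entity=chloride_out.id,
                                         event=process.id, role=pw.Role.output))
    instance.add_takes_part(pw.TakesPart(entity=channel.id,
                                         event=process.id, role=pw.Role.regulator))

    instance.attach_reference(variation.id, DataBankEntry(
        databank="ClinVar", accession="487391",
        uri="https://www.ncbi.nlm.nih.gov/clinvar/variation/487391/"))
    instance.attach_reference(gene.id, BibliographyEntry(
        id="cftr_review", citation="Review of CFTR structure and function",
        identifier="PMID:0000000"))
    return instance


class SyntheticSpec(BaseModel):
    """Parameters of the seeded synthetic-instance generator."""

    seed: int = 0
    chromosome_count: int = Field(default=2, ge=1)
    scaffolds_per_chromosome: int = Field(default=2, ge=1)
    gap_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    genes_per_chromosome: int = Field(default=3, ge=0)
    exons_per_gene: tuple[int, int] = (2, 4)
    variation_count: int = Field(default=10, ge=0)
    snp_indel_ratio: float = Field(default=0.8, ge=0.0, le=1.0)
    population_count: int = Field(default=1, ge=0)
    individuals_per_population: int = Field(default=4, ge=1)

    @model_validator(mode="after")
    def _feasible(self) -> "SyntheticSpec":
        lo, hi = self.exons_per_gene
        if not (1 <= lo <= hi):
            raise ValueError("exons_per_gene must be an increasing range >= 1")
        if self.variation_count and not (self.chromosome_count
                                         and self.genes_per_chromosome):
            raise ValueError("variations require at least one gene to affect")
        return self


def allocate_kinds(count: int, snp_ratio: float) -> tuple[int, int]:
    """Deterministic SNP/indel split: floor(count * ratio + 0.5) SNPs."""
    n_snp = int(count * snp_ratio + 0.5)
    return n_snp, count - n_snp

_BASES = np.array(list("ACGT"))
_SPECIES = ("Citrus clementina", "Citrus sinensis")


def synthetic(spec: SyntheticSpec) -> Instance:
    """Generate a deterministic instance satisfying every model invariant."""
    rng = np.random.default_rng(spec.seed)
    instance = Instance(metadata={
        "fixture": "synthetic",
        "spec": spec.model_dump(mode="json"),
    })
    assembly = instance.add_assembly(gc.Assembly(
        id="ASM1", species=_SPECIES[0], version="1.0"))

    genes: list[gc.Gene] = []
    for ci in range(spec.chromosome_count):
        species = _SPECIES[ci % len(_SPECIES)]
        chrom = instance.add_chromosome(gc.Chromosome(
            id=f"chr{ci + 1}", name=str(ci + 1), species=species))
        for si in range(spec.scaffolds_per_chromosome):
            instance.add_scaffold(f"{chrom.id}_scaf{si + 1}", chrom.id,
                                  _random_sequence(rng, spec.gap_rate))
        cursor = 1
        for gi in range(spec.genes_per_chromosome):
            gene_id = f"{chrom.id}_g{gi + 1}"
            n_exons = int(rng.integers(spec.exons_per_gene[0],
                                       spec.exons_per_gene[1] + 1))
            element_ids: list[str] = []
            exon_lengths: list[int] = []
            for xi in range(n_exons):
                if xi:  # intron between consecutive exons
                    ilen = int(rng.integers(30, 120))
                    intron = instance.add_element(gc.ChromosomeElement(
                        id=f"{gene_id}_i{xi}", kind=gc.ElementKind.intron,
                        positions={assembly.id: gc.GenomicPosition(
                            assembly=assembly.id, chromosome=chrom.id,
                            start=cursor, end=cursor + ilen - 1)}))
                    element_ids.append(intron.id)
                    cursor += ilen
                elen = int(rng.integers(60, 300)) * 3
                exon = instance.add_element(gc.ChromosomeElement(
                    id=f"{gene_id}_x{xi + 1}", kind=gc.ElementKind.exon,
                    positions={assembly.id: gc.GenomicPosition(
                        assembly=assembly.id, chromosome=chrom.id,
                        start=cursor, end=cursor + elen - 1)}))
                element_ids.append(exon.id)
                exon_lengths.append(elen)
                cursor += elen + int(rng.integers(20, 80))
            gene = instance.add_gene(gc.Gene(
                id=gene_id, symbol=gene_id.upper(), species=species,
                elements=element_ids))
            genes.append(gene)
            exonic = [e for e in element_ids if "_x" in e]
            total = sum(exon_lengths)
            utr5 = min(12, max(0, total - 6))
            utr3 = max(0, total - utr5 - max(3, ((total - utr5) // 3) * 3))
            cds = total - utr5 - utr3
            transcript = gc.Transcript(id=f"{gene_id}_t1", genes=[gene.id],
                                       exonic_elements=exonic, length=total)
            mrna = gc.build_mrna(transcript, utr5, cds, utr3)
            instance.add_transcript(mrna)
            plen = max(1, cds // 3 - 1)
            instance.add_protein(gc.Protein(
                id=f"{gene_id}_p1", name=gene_id.upper(), coded_by=[mrna.id],
                length=plen,
                domains=[gc.ProteinDomain(id=f"{gene_id}_p1_dom1",
                                          name="whole-length", start=1,
                                          end=plen)]))

    # ortholog groups pair genes across the two species when possible
    by_species: dict[str, list[gc.Gene]] = {}
    for gene in genes:
        by_species.setdefault(gene.species, []).append(gene)
    if len(by_species) >= 2:
        first, second = (by_species[s] for s in sorted(by_species)[:2])
        for oi, (a, b) in enumerate(zip(first, second)):
            instance.add_ortholog_group(gc.create_ortholog_group(
                f"og{oi + 1}", [a, b],
                [instance.proteins[f"{a.id}_p1"], instance.proteins[f"{b.id}_p1"]]))

    n_snp, n_indel = allocate_kinds(spec.variation_count, spec.snp_indel_ratio)
    variations = []
    for vi in range(spec.variation_count):
        gene = genes[int(rng.integers(len(genes)))]
        element_id = gene.elements[int(rng.integers(len(gene.elements)))]
        ref, alts, kind = _random_alleles(rng, is_snp=vi < n_snp)
        pos = instance.elements[element_id].positions[assembly.id]
        offset = int(rng.integers(pos.start, pos.end + 1))
        variations.append(instance.add_variation(vn.Variation(
            id=f"var{vi + 1}", kind=kind, reference_allele=ref,
            alternative_alleles=alts, affected_elements=[element_id],
            positions={assembly.id: gc.GenomicPosition(
                assembly=assembly.id, chromosome=pos.chromosome,
                start=offset, end=offset + len(ref) - 1)})))

    for pi in range(spec.population_count):
        members = [f"pop{pi + 1}_ind{ii + 1}"
                   for ii in range(spec.individuals_per_population)]
        population = instance.add_population(vn.Population(
            id=f"pop{pi + 1}", description=f"synthetic population {pi + 1}",
            members=members))
        for member in members:
            instance.add_individual(vn.Individual(
                id=member, species=_SPECIES[0], populations=[population.id]))
        for variation in variations:
            alleles = sorted(variation.alleles())
            probs = rng.dirichlet(np.ones(len(alleles)))
            for member in members:
                genotype = tuple(rng.choice(alleles, size=2, p=probs))
                instance.add_individual_observation(variation.id, member,
                                                    genotype)
            record = instance.aggregate_frequencies(population.id, variation.id)
            instance.population_frequencies[(variation.id, population.id)] = record
    return instance


def _random_sequence(rng, gap_rate: float, length: int = 240) -> str:
    seq = rng.choice(_BASES, size=length)
    n_gaps = rng.binomial(4, gap_rate)
    for _ in range(n_gaps):
        start = int(rng.integers(1, length - 12))
        seq[start:start + int(rng.integers(3, 9))] = "N"
    return "".join(seq)


def _random_alleles(rng, is_snp: bool):
    if is_snp:
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        return str(ref), [str(alt)], vn.VariationKind.SNP
    ref = str(rng.choice(_BASES))
    insert = "".join(rng.choice(_BASES, size=int(rng.integers(1, 4))))
    return ref, [ref + insert], vn.VariationKind.indel
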