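# genoschema

A species-independent **conceptual schema of the genome (CSG)** as a
validated, queryable data model — together with the two species-specific
schemas it generalizes (the human-genome schema **CSHG** and the
citrus-genome schema **CSCG**), the machinery to compare and project
schemas, a pathway roll-up computation, and a 20-question competency
evaluation.

It is aimed at people who model genomic information systems: the same
biological backbone (chromosomes and their elements, genes, transcripts,
mRNA structure, proteins and domains, variations and their frequencies,
pathways, provenance) recurs across species, but each working domain keeps
rebuilding its own schema. This package treats schemas themselves as data,
so they can be counted, intersected, projected onto use-case views, and
scored against competency questions.

## The model in brief

Every schema partitions its concepts into five views:

| view | what it covers |
|---|---|
| structural | species, assemblies, chromosomes, scaffolds (with gaps of known length), chromosome elements |
| transcription | genes as combinations of elements, transcripts, mRNA = 5′ UTR + CDS + 3′ UTR, proteins as sets of ≥ 1 domain, ortholog groups of ≥ 2 genes |
| variation | variations at three levels — general characterization, population frequencies, individual observations — with genotype frequencies for **every** variation kind |
| pathway | an entity taxonomy (Simple / Complex / EntitySet / Polymer), recursive ordered events, and reified `takes_part` participations with roles input / output / regulator |
| bibliography | databank accessions and literature references attachable to any element |

Two schema-level statistics drive the comparison: per-view concept counts
(CSHG 8/10/11/13/4 = 46, CSCG 4/13/4/2/0 = 23, CSG 9/17/16/13/4 = 59, with
12 concepts shared between CSHG and CSCG) and the relative growth
100 · (|to| − |from|) / |from| (CSHG → CSG: 28.26 %, CSCG → CSG: 156.52 %).
Concept matching is canonical-name based: an explicit synonym table equates
the citrus *sequence part* with *chromosome element* and
*protein-coding transcript* with *mRNA*.

The **roll-up** derives a pathway's net inputs, outputs, and regulators
from its processes: an entity produced by an earlier process and consumed
by a later one is an *intermediate* and cancels out of the pathway-level
input/output sets (`--gross` disables the cancellation).

The **competency engine** evaluates which of 20 validation questions a
schema can answer (a question is answerable iff the schema contains all the
concepts it requires) and also answers them against a populated instance.

## Worked example

Schema comparison from the command line:

```
$ genoschema counts CSG
structural      9
transcription   17
variation       16
pathway         13
bibliography    4
total           59

$ genoschema compare CSHG CSCG
shared_total            12
shared_structural       3
shared_transcription    6
shared_variation        1
shared_pathway          2
shared_bibliography     0
shared_pct_of_CSHG      26
shared_pct_of_CSCG      52
```

The 12 shared concepts are 26 % of the human schema and 52 % of the citrus
schema — the two use cases overlap far less than their common subject
suggests, which is the argument for a single generic schema with projected
views (`genoschema project CSG --keep my_concepts.txt`).

Rolling up the two-step cysteine biosynthesis module M00021 (KEGG
compound/reaction ids, EC-numbered enzymes):

```
$ genoschema fixture m00021 --out m00021.json
$ genoschema rollup m00021.json --pathway M00021
{
 "inputs":        ["C00024", "C00065", "C00283"],
 "intermediates": ["C00979"],
 "outputs":       ["C00010", "C00033", "C00097"],
 "regulators":    ["2.3.1.30", "2.5.1.47"]
}
```

O-acetyl-L-serine (C00979) is produced by the first reaction (R00586) and
consumed by the second (R00897), so it is an intermediate: at module level
the pathway consumes L-serine, acetyl-CoA, and hydrogen sulfide and yields
CoA, acetate, and L-cysteine, regulated by the two enzymes.

Scoring a schema against the competency questions:

```
$ genoschema competency --schema CSHG --report table
...
global              0.75
view_structural     1
view_transcription  0.5
view_variation      0.75
view_pathway        1
view_bibliography   1
```

The human schema answers 15/20 questions; it misses the intron, domain,
CDS, and UTR questions (no such concepts) and the individual-level allele
frequency question (it only models populations). Score displays are
truncated toward zero (2/3 → 0.66) unless the fraction terminates within
three decimals (7/8 → 0.875); exact rationals are kept alongside.

A second worked instance, `genoschema fixture cftr --out cftr.json`, builds
a cystic-fibrosis variation (HGVS
`NM_000492.3(CFTR):c.57G>A(p.Trp19Ter)`, ClinVar accession 487391) spanning
all five views; under the CSG all 20 questions return non-empty answers on
it. Instances can be exported as knowledge graphs
(`genoschema export cftr.json --format graphml|csv --out ...`) with nodes
coloured by view.

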