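# Methods

## Schemas as data

A conceptual schema is stored as a JSON inventory (`src/genoschema/data/`):
concepts with a name, one of five views, and a description; relationships
with endpoints, a kind (association, generalization, composition), and
(min, max) multiplicities. The three shipped inventories — CSHG (human),
CSCG (citrus), CSG (species-independent) — are reconstructions: the
published material fixes the per-view concept *counts* of each schema, the
per-view *shared* counts between CSHG and CSCG, and the per-view additions
that turn the CSHG into the CSG, but not the complete membership lists.
The inventories were therefore assembled from the described model content
and calibrated so that every count holds exactly. They are declarative
data files on purpose: a membership correction is a data edit, not a code
change.

Concept matching across schemas is canonical-name based through an explicit
synonym table (`sequence part ≡ chromosome element`,
`protein-coding transcript ≡ mRNA ≡ MessengerRNA`) rather than string
similarity — deterministic and auditable. Two reconstruction choices are
worth recording:

* Because the mRNA concept is a *rename* of the human schema's
  protein-coding transcript (one canonical concept), the seven
  transcription-view concepts that the generic schema adds are counted
  here as intron, protein domain, ortholog group, CDS, 5′ UTR, 3′ UTR, and
  a generic *untranslated region* superclass; the renamed mRNA itself is
  already present canonically.
* The shared-concept membership is constrained only by its per-view counts
  (3/6/1/2/0). The reconstruction used here is: Species, Chromosome,
  ChromosomeElement; Gene, Exon, MessengerRNA, Protein, Enzyme, Promoter;
  Variation; Pathway, TakesPart. Promoter-in-both is consistent with the
  human schema being *more detailed* about transcription regulators (it
  additionally has Enhancer and the regulatory/transcriptable element
  classification, which is why the regulatory-elements competency question
  still fails under the citrus schema).

`project_view` keeps a chosen concept subset and every relationship whose
*both* endpoints survive; generalization edges follow the same rule with no
transitive re-wiring (the simplest defensible rule; nothing in the source
material constrains it). Growth percentages are rounded half-up to two
decimals; shared-concept shares are displayed as whole percentages.

## Instance model

Coordinates are 1-based inclusive everywhere (HGVS/VCF convention);
conversion to 0-based half-open coordinates would happen only at export
boundaries, and no current exporter emits coordinates. Strand defaults to
unspecified and nothing ever reverse-complements implicitly.

Scaffold gaps are maximal runs of `N`, auto-derived and bookkept as
(start, length) pairs; re-emitting a scaffold from its non-gap segments
plus gap list reproduces the sequence exactly (property-tested). Element
roles are definitional per kind — intron ⇒ {regulatory, transcriptable},
exon ⇒ transcriptable, promoter/enhancer/terminator ⇒ regulatory — with
explicit overrides honoured only for kind `other`. mRNA segments are laid
out consecutively from position 1; an empty CDS is an error, a CDS length
that is not a multiple of three is a warning (partial annotations exist).
Protein domains may overlap (real domains can); overlap warns. A
domain-less protein fails *strict* validation (the generic schema defines a
protein as ≥ 1 domain) but passes permissive validation, which is what the
human-schema emulation needs since that schema has no domain concept.
Ortholog groups require ≥ 2 genes; a single-species group warns rather than
errors, since the orthology call may still be right across subspecies
labels the model cannot see.

### Variation levels and modes

Genotypes are unordered allele pairs (no phasing); ploidy is a
per-individual field defaulting to 2. Frequency mappings must lie in
[0, 1] and sum to 1 within 1e−6 — a tolerance chosen to absorb decimal
rounding in published inputs, nothing deeper. Aggregation from individuals
counts alleles over total allele copies and genotypes over members, and the
synthetic generator produces population records *by* aggregation, so
recovery is exact by construction. Multi-allelic variations keep one
record with several alternatives; the VCF-lite reader maps one line to one
variation.

Capability emulation (`SchemaMode`) turns documented blind spots into
`CapabilityError`: under CSHG, individual-level observations and non-SNP
genotype frequencies are rejected; under CSCG, population-level records,
any provenance attachment (zero bibliography concepts), and multi-assembly
element positions are rejected. The accepted writes under an emulated mode
are a strict subset of those under CSG, which the tests assert.

## Pathway roll-up

`flatten` expands a pathway depth-first in declared child order into its
atomic processes, detecting containment cycles. `rollup` merges
participations: intermediates are entities output by an earlier process
and input to a later one (strict order — an entity produced only after it
is consumed is *not* an intermediate, and an input-and-output of one and
the same process is a catalytic cycle, never an intermediate); pathway
inputs/outputs are the unions minus intermediates, regulators always the
plain union (a regulator produced mid-pathway stays a regulator — nothing
in the source material licenses cancelling it). The net-set rule is
adopted because it gives the biologically expected module-level answer on
the cysteine-biosynthesis example (the acetylated intermediate is not a
module input or output); `gross=True` returns plain unions instead.
Stoichiometry rides along as an opaque takes-part attribute and is ignored
by the roll-up. Correctness is checked against a brute-force oracle that
enumerates (entity, role, position) triples on randomized pathways.

## Competency evaluation

Answerability is a static schema-capability check — a question is
answerable iff the schema contains every concept the question requires
(canonical matching) — kept strictly separate from answering a question
against a populated instance, because the published evaluation scores
*schemas*, not datasets. The requirement sets are shipped as data
(`data/questions.json`) and are the calibration surface: they were derived
from the question texts and the published answerable/not-answerable
pattern, and are reviewable without code changes. Two calibration notes:
the two position questions differ only in assembly, which a concept-level
check cannot see, so the GRCh37 question requires the multi-assembly
concepts (Assembly, GenomicPosition) while the GRCh38 question requires
only element-level position data — the citrus schema's single working
assembly is GRCh38 in the worked example; and the alleles question
requires only the Variation concept, alleles being attributes of it.

One published inconsistency is knowingly not reproduced: the citrus
schema's printed global score (0.7) contradicts its own printed per-view
pattern, which sums to 13/20 = 0.65. The implementation reports the
matrix-derived 0.65.

Score displays truncate toward zero at two decimals (2/3 → 0.66,
1/3 → 0.33) except that fractions terminating within three decimals print
exactly with trailing zeros dropped (7/8 → 0.875, 3/4 → 0.75); the exact
rationals are always retained alongside the display strings.

## Fixtures and the synthetic generator

The cysteine-biosynthesis fixture encodes the module exactly as tabulated
(two ordered reactions, ten participations). The cystic-fibrosis fixture
is a minimal structural stand-in: one representative exon out of
twenty-seven, a whole-length placeholder protein domain, and synthetic
genomic coordinates flagged by `synthetic_coordinates: true` in the
metadata so they cannot be mistaken for reference values. Its published
content is limited to the HGVS expression, the ClinVar accession, the
chromosome, the two assembly names, and the European-population framing.

The synthetic generator emulates the data shapes the model must support —
scaffolds with gaps, multi-exon genes with introns, mRNA with UTR/CDS
structure, proteins with domains, cross-species ortholog pairs, SNP/indel
variations, and diploid populations — at desk scale (defaults: 2
chromosomes, 2 scaffolds and 3 genes per chromosome, 10 variations at an
0.8 SNP:indel ratio, one population of 4 individuals). Sizes and rates are
plausible miniatures chosen for fast, exhaustive testing; the generator
does not emulate linkage, realistic allele-frequency spectra, sequencing
error, or annotation noise, so passing tests demonstrate model-invariant
preservation and round-trip fidelity, not robustness to real-world data
quality. The SNP/indel split is a deterministic allocation
(`floor(count·ratio + 0.5)`), not sampling; genotypes are drawn from
per-variation Dirichlet(1) allele weights and population frequencies are
then computed by aggregation. Everything is driven by one seeded
generator, so equal seeds give byte-identical instances.

## Serialization and graph export

The instance document is JSON with five per-view record lists; records
carry `id` and `type`, cross-reference by id, and round-trip identically
(load ∘ save = identity on documents, tested on fixtures and randomized
instances). Record types are checked against the governing schema on
load, so a document using a concept the schema lacks (e.g. a haplotype,
deliberately absent from the CSG) is rejected in strict mode.

Graph export writes one node per record and one edge per resolved
reference, except that takes-part and reference-link records — reified
relationships — become role-labelled edges rather than nodes. Nodes carry
their view and the view's display colour (structural green, transcription
blue, variation light brown, provenance yellow, pathway pink), stored as
names, not hex. Both the GraphML and the CSV dialect (nodes.csv +
edges.csv, header row, UTF-8) are emitted in sorted order, making exports
byte-deterministic.

The VCF-lite reader is deliberately minimal: tab-separated
`CHROM POS ID REF ALT QUAL FILTER INFO FORMAT sample+`, 1-based positions,
only the GT subfield interpreted, INFO ignored by design (keeping only
biologically interpreted fields is the point of separating technological
from biological data), `.` alleles rejected with the line number. FASTA
goes through Biopython.

## Known limitations

* Schema inventories are count-calibrated reconstructions; individual
  membership choices beyond the documented constraints are judgment calls
  recorded above.
* No haplotype model (deferred by design), no phasing, no variant calling
  or effect annotation, no kinetic/flux pathway modeling, no sequence
  alignment or translation.
* A scaffold maps to exactly one chromosome; the community definition is
  ambiguous and the one-chromosome reading was chosen pending a use case.
* The bibliography view's internal four-concept structure is itself a
  count-calibrated reconstruction; no figure of it exists.
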