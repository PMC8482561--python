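"""Instance types for the structural and transcription views.

Coordinates are 1-based inclusive throughout, as in HGVS and VCF usage;
conversion to 0-based half-open coordinates happens only at export
boundaries.  Strand defaults to "unspecified" and no reverse-complement
logic is ever applied implicitly.
"""

from __future__ import annotations

import re
import warnings
from enum import Enum
from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import NoPositionForAssembly

_SEQUENCE_RE = re.compile(r"^[ACGTN]+$")


class Strand(str, Enum):
    plus = "+"
    minus = "-"
    unspecified = "unspecified"


class Assembly(BaseModel):
    id: str
    species: str
    version: str = ""


class Chromosome(BaseModel):
    id: str
    name: str
    species: str


class GenomicPosition(BaseModel):
    assembly: str
    chromosome: str
    start: int = Field(ge=1)
    end: int = Field(ge=1)
    strand: Strand = Strand.unspecified

    @model_validator(mode="after")
    def _ordered(self) -> "GenomicPosition":
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        return self


class Placement(BaseModel):
    """Optional anchoring of a scaffold on an assembled chromosome."""

    assembly: str
    start: int = Field(ge=1)
    end: int = Field(ge=1)

    @model_validator(mode="after")
    def _ordered(self) -> "Placement":
        if self.start > self.end:
            raise ValueError(f"placement start {self.start} > end {self.end}")
        return self


def derive_gaps(sequence: str) -> list[tuple[int, int]]:
    """Maximal N-runs of a sequence as sorted (1-based start, length) pairs."""
    return [(m.start() + 1, m.end() - m.start())
            for m in re.finditer(r"N+", sequence)]


class Scaffold(BaseModel):
    """An assembled sequence holding all or part of one chromosome.

    Gaps (runs of N of known length) are bookkept explicitly so that a
    scaffold can be re-emitted from its non-gap segments plus its gap list.
    """

    id: str
    chromosome: str
    sequence: str
    gaps: list[tuple[int, int]] = Field(default_factory=list)
    placement: Optional[Placement] = None

    @field_validator("sequence", mode="before")
    @classmethod
    def _normalize(cls, v: str) -> str:
        if not isinstance(v, str) or not v:
            raise ValueError("scaffold sequence must be a non-empty string")
        v = v.upper()
        if not _SEQUENCE_RE.match(v):
            bad = sorted(set(v) - set("ACGTN"))
            raise ValueError(f"invalid sequence characters: {bad}")
        return v

    @model_validator(mode="after")
    def _gaps_match(self) -> "Scaffold":
        expected = derive_gaps(self.sequence)
        if not self.gaps:
            self.gaps = expected
        elif [tuple(g) for g in self.gaps] != expected:
            raise ValueError(
                f"scaffold {self.id}: recorded gaps {self.gaps} do not match "
                f"the N-runs of the sequence {expected}"
            )
        return self

    def reassemble(self) -> str:
        """Rebuild the sequence from non-gap segments plus the gap list."""
        out = list(self.sequence.replace("N", ""))
        for start, length in self.gaps:
            out[start - 1:start - 1] = "N" * length
        return "".join(out)


def add_scaffold(
    scaffold_id: str,
    chromosome: str,
    sequence: str,
    placement: Optional[Placement] = None,
) -> Scaffold:
    """Build a scaffold with gaps auto-derived from its N-runs."""
    return Scaffold(id=scaffold_id, chromosome=chromosome,
                    sequence=sequence, placement=placement)


class ElementKind(str, Enum):
    exon = "exon"
    intron = "intron"
    promoter = "promoter"
    enhancer = "enhancer"
    terminator = "terminator"
    other = "other"


class Role(str, Enum):
    regulatory = "regulatory"
    transcriptable = "transcriptable"


#: Default role assignment per element kind.  The intron is the one element
#: that is intrinsically both regulatory and transcriptable.
_KIND_ROLES: dict[ElementKind, frozenset[Role]] = {
    ElementKind.exon: frozenset({Role.transcriptable}),
    ElementKind.intron: frozenset({Role.regulatory, Role.transcriptable}),
    ElementKind.promoter: frozenset({Role.regulatory}),
    ElementKind.enhancer: frozenset({Role.regulatory}),
    ElementKind.terminator: frozenset({Role.regulatory}),
}


def element_roles(kind: ElementKind | str,
                  explicit: Optional[set[Role]] = None) -> frozenset[Role]:
    """Roles carried by an element of the given kind.

    Explicit overrides are honoured only for kind "other"; the named kinds
    have definitional roles (an exon is transcriptable, an intron is both).
    """
    kind = ElementKind(kind)
    if kind is ElementKind.other:
        if explicit:
            return frozenset(Role(r) for r in explicit)
        return frozenset({Role.regulatory})
    return _KIND_ROLES[kind]


class ChromosomeElement(BaseModel):
    id: str
    kind: ElementKind
    roles: frozenset[Role] = frozenset()
    positions: dict[str, GenomicPosition] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _role_invariants(self) -> "ChromosomeElement":
        if not self.roles:
            self.roles = element_roles(self.kind)
        if self.kind is ElementKind.intron and self.roles != frozenset(
                {Role.regulatory, Role.transcriptable}):
            raise ValueError("an intron is both regulatory and transcriptable")
        if self.kind is ElementKind.exon and Role.transcriptable not in self.roles:
            raise ValueError("an exon must carry the transcriptable role")
        if not self.roles:
            raise ValueError("element roles must be non-empty")
        return self

    def locate(self, assembly: str) -> GenomicPosition:
        try:
            return self.positions[assembly]
        except KeyError:
            raise NoPositionForAssembly(
                f"element {self.id} has no position in assembly {assembly!r}"
            ) from None


def locate(element: ChromosomeElement, assembly: str) -> GenomicPosition:
    """Stored position of an element in one assembly.

    Raises :class:`NoPositionForAssembly` when the element carries no
    position for that assembly — the situation a single-assembly schema
    (the citrus one) is permanently stuck in.
    """
    return element.locate(assembly)


class Gene(BaseModel):
    """A gene as an ordered combination of chromosome elements.

    Elements are referenced by id and may be shared between genes, which is
    what permits nested and overlapping genes.
    """

    id: str
    symbol: str
    species: str
    elements: list[str] = Field(min_length=1)


class Transcript(BaseModel):
    id: str
    genes: list[str] = Field(min_length=1)  # >1 under trans-splicing
    exonic_elements: list[str] = Field(default_factory=list)
    length: int = Field(gt=0)


class MessengerRNA(Transcript):
    """A protein-coding transcript: 5' UTR, CDS, 3' UTR in transcript coords."""

    utr5: Optional[tuple[int, int]] = None
    cds: tuple[int, int]
    utr3: Optional[tuple[int, int]] = None

    @model_validator(mode="after")
    def _intervals(self) -> "MessengerRNA":
        intervals = [iv for iv in (self.utr5, self.cds, self.utr3) if iv is not None]
        for s, e in intervals:
            if not (1 <= s <= e <= self.length):
                raise ValueError(
                    f"mRNA {self.id}: interval ({s}, {e}) outside [1, {self.length}]")
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            if e1 >= s2:
                raise ValueError(
                    f"mRNA {self.id}: intervals must be ordered "
                    "5' UTR < CDS < 3' UTR without overlap")
        return self


def build_mrna(transcript: Transcript, utr5_len: int, cds_len: int,
               utr3_len: int) -> MessengerRNA:
    """Lay out 5' UTR / CDS / 3' UTR consecutively from position 1.

    The CDS must be non-empty (at least one codon); a CDS length that is not
    a multiple of three only warns, since partial CDS annotations exist.
    """
    if min(utr5_len, utr3_len) < 0:
        raise ValueError("UTR lengths must be non-negative")
    if cds_len < 3:
        raise ValueError("CDS must span at least one codon (length >= 3)")
    total = utr5_len + cds_len + utr3_len
    if total != transcript.length:
        raise ValueError(
            f"segment lengths sum to {total} but transcript {transcript.id} "
            f"has length {transcript.length}")
    if cds_len % 3:
        warnings.warn(
            f"CDS length {cds_len} of {transcript.id} is not a multiple of 3",
            stacklevel=2)
    utr5 = (1, utr5_len) if utr5_len else None
    cds = (utr5_len + 1, utr5_len + cds_len)
    utr3 = (utr5_len + cds_len + 1, total) if utr3_len else None
    base = {field: getattr(transcript, field)
            for field in ("id", "genes", "exonic_elements", "length")}
    return MessengerRNA(**base, utr5=utr5, cds=cds, utr3=utr3)


class ProteinDomain(BaseModel):
    id: str
    name: str = ""
    start: int = Field(ge=1)
    end: int = Field(ge=1)

    @model_validator(mode="after")
    def _ordered(self) -> "ProteinDomain":
        if self.start > self.end:
            raise ValueError(f"domain {self.id}: start > end")
        return self


class Protein(BaseModel):
    """A protein, defined as a set of at least one domain when validated
    strictly; domain-less proteins pass only permissive validation (the
    human-genome schema has no domain concept)."""

    id: str
    name: str = ""
    coded_by: list[str] = Field(default_factory=list)
    length: int = Field(gt=0)
    domains: list[ProteinDomain] = Field(default_factory=list)

    @model_validator(mode="after")
    def _domains_fit(self) -> "Protein":
        for dom in self.domains:
            if dom.end > self.length:
                raise ValueError(
                    f"protein {self.id}: domain {dom.id} exceeds length "
                    f"{self.length}")
        overlapping = [
            (a.id, b.id) for a, b in zip(self.domains, self.domains[1:])
            if a.end >= b.start and a.start <= b.end
        ]
        if overlapping:
            warnings.warn(
                f"protein {self.id}: overlapping domains {overlapping}",
                stacklevel=2)
        return self


class OrthologGroup(BaseModel):
    id: str
    genes: list[str] = Field(min_length=2)
    proteins: list[str] = Field(default_factory=list)


def create_ortholog_group(group_id: str, genes: list[Gene],
                          proteins: Optional[list[Protein]] = None) -> OrthologGroup:
    """Relate at least two genes (and optionally proteins) as orthologs.

    Orthologs arise through speciation, so a group whose genes all share one
    species is suspicious — it is accepted with a warning, not rejected.
    """
    if len(genes) < 2:
        raise ValueError("an ortholog group relates at least two genes")
    species = {g.species for g in genes}
    if len(species) == 1:
        warnings.warn(
            f"ortholog group {group_id}: all genes belong to {species.pop()!r}",
            stacklevel=2)
    return OrthologGroup(
        id=group_id,
        genes=[g.id for g in genes],
        proteins=[p.id for p in (proteins or [])],
    )
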