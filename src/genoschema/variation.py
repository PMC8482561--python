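"""The variation view: general, population, and individual levels.

A variation is characterized once at the general level (alleles, kind,
positions, clinical significance).  Population-level records carry allele
and genotype frequencies within a population; individual-level observations
carry one organism's genotype and per-allele support fractions.  Genotype
frequencies apply to *every* variation kind here; restricting them to SNPs
is a documented limitation of the human-genome schema, reproduced by the
CSHG emulation mode.

Genotypes are unordered allele pairs (no phasing).  Diploidy is the default
but ploidy is a per-individual field, so the model is not hard-wired to it.
"""

from __future__ import annotations

from collections import Counter
from enum import Enum
from typing import Optional, Sequence

from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import CapabilityError
from .genome_core import GenomicPosition
from .modes import SchemaMode

#: Tolerance for frequency-sum checks; absorbs decimal rounding in inputs.
FREQUENCY_TOLERANCE = 1e-6


class VariationKind(str, Enum):
    SNP = "SNP"
    insertion = "insertion"
    deletion = "deletion"
    indel = "indel"
    other = "other"


class Variation(BaseModel):
    """General-level characterization of a sequence variation."""

    id: str
    kind: VariationKind
    reference_allele: str = Field(min_length=1)
    alternative_alleles: list[str] = Field(min_length=1)
    positions: dict[str, GenomicPosition] = Field(default_factory=dict)
    hgvs: Optional[str] = None
    affected_elements: list[str] = Field(default_factory=list)
    clinical_significance: Optional[str] = None

    @model_validator(mode="after")
    def _allele_rules(self) -> "Variation":
        alleles = [self.reference_allele, *self.alternative_alleles]
        if len(set(alleles)) != len(alleles):
            raise ValueError(f"variation {self.id}: alleles must be pairwise distinct")
        if self.kind is VariationKind.SNP and any(len(a) != 1 for a in alleles):
            raise ValueError(
                f"variation {self.id}: a SNP requires single-base alleles")
        return self

    def alleles(self) -> set[str]:
        return {self.reference_allele, *self.alternative_alleles}


def register_variation(record: Variation | dict) -> Variation:
    """Validate and return a general-level variation record."""
    if isinstance(record, Variation):
        return record
    return Variation.model_validate(record)


class Population(BaseModel):
    id: str
    description: str = ""
    members: list[str] = Field(default_factory=list)


class Individual(BaseModel):
    id: str
    species: str = ""
    populations: list[str] = Field(default_factory=list)
    ploidy: int = Field(default=2, ge=1)


def genotype_key(alleles: Sequence[str]) -> str:
    """Canonical string for an unordered genotype, e.g. ('A', 'G') -> 'A/G'."""
    return "/".join(sorted(alleles))


def _check_sum(freqs: dict[str, float], what: str,
               tolerance: float = FREQUENCY_TOLERANCE) -> None:
    if not freqs:
        return
    for key, value in freqs.items():
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{what} {key!r} has frequency {value} outside [0, 1]")
    total = sum(freqs.values())
    if abs(total - 1.0) > tolerance:
        raise ValueError(f"{what} frequencies sum to {total}, not 1")


class PopulationFrequencyRecord(BaseModel):
    """Allele and genotype frequencies of one variation in one population."""

    variation: str
    population: str
    allele_frequencies: dict[str, float] = Field(default_factory=dict)
    genotype_frequencies: dict[str, float] = Field(default_factory=dict)

    @field_validator("genotype_frequencies", mode="before")
    @classmethod
    def _canonical_genotypes(cls, v: dict) -> dict:
        return {genotype_key(k.split("/")) if isinstance(k, str) else genotype_key(k): f
                for k, f in v.items()}

    @model_validator(mode="after")
    def _sums(self) -> "PopulationFrequencyRecord":
        _check_sum(self.allele_frequencies, "allele")
        _check_sum(self.genotype_frequencies, "genotype")
        return self


class IndividualObservation(BaseModel):
    """One individual's genotype for a variation, with allele fractions
    (e.g. read-support proportions; their biological semantics are left to
    the user)."""

    variation: str
    individual: str
    genotype: tuple[str, ...] = Field(min_length=1)
    allele_fractions: dict[str, float] = Field(default_factory=dict)

    @field_validator("genotype", mode="before")
    @classmethod
    def _sorted(cls, v):
        return tuple(sorted(v))

    @model_validator(mode="after")
    def _sums(self) -> "IndividualObservation":
        _check_sum(self.allele_fractions, "allele")
        return self


def check_alleles_known(variation: Variation, names: Sequence[str],
                        context: str) -> None:
    unknown = sorted(set(names) - variation.alleles())
    if unknown:
        raise ValueError(
            f"{context}: alleles {unknown} are neither the reference nor a "
            f"listed alternative of {variation.id}")


def make_population_frequencies(
    variation: Variation,
    population: Population,
    allele_freqs: dict[str, float],
    genotype_freqs: dict[str, float],
    mode: SchemaMode = SchemaMode.CSG,
) -> PopulationFrequencyRecord:
    """Build a validated population-level frequency record.

    Under CSHG emulation, genotype frequencies are accepted for SNPs only;
    under CSCG emulation the population level does not exist at all.
    """
    if mode is SchemaMode.CSCG:
        raise CapabilityError(
            "the CSCG has no population level; variation frequencies can "
            "only be recorded per individual")
    if (mode is SchemaMode.CSHG and genotype_freqs
            and variation.kind is not VariationKind.SNP):
        raise CapabilityError(
            f"genotype frequencies of {variation.kind.value} variations "
            "cannot be represented in the CSHG")
    record = PopulationFrequencyRecord(
        variation=variation.id,
        population=population.id,
        allele_frequencies=dict(allele_freqs),
        genotype_frequencies=dict(genotype_freqs),
    )
    check_alleles_known(variation, list(record.allele_frequencies), "allele frequencies")
    genotype_alleles = [a for key in record.genotype_frequencies for a in key.split("/")]
    check_alleles_known(variation, genotype_alleles, "genotype frequencies")
    return record


def make_individual_observation(
    variation: Variation,
    individual: Individual,
    genotype: Sequence[str],
    allele_fractions: Optional[dict[str, float]] = None,
    mode: SchemaMode = SchemaMode.CSG,
) -> IndividualObservation:
    """Build a validated individual-level observation.

    Under CSHG emulation the individual level does not exist.  When allele
    fractions are omitted they default to the genotype's allele proportions.
    """
    if mode is SchemaMode.CSHG:
        raise CapabilityError(
            "the CSHG has no individual level; variation frequencies can "
            "only be recorded per population")
    genotype = tuple(sorted(genotype))
    if len(genotype) != individual.ploidy:
        raise ValueError(
            f"genotype {genotype} has {len(genotype)} alleles but individual "
            f"{individual.id} has ploidy {individual.ploidy}")
    check_alleles_known(variation, genotype, f"genotype of {individual.id}")
    if allele_fractions is None:
        counts = Counter(genotype)
        allele_fractions = {a: n / len(genotype) for a, n in counts.items()}
    else:
        check_alleles_known(variation, list(allele_fractions),
                            f"allele fractions of {individual.id}")
    return IndividualObservation(
        variation=variation.id,
        individual=individual.id,
        genotype=genotype,
        allele_fractions=allele_fractions,
    )


def aggregate_frequencies(
    population: Population,
    variation: Variation,
    observations: dict[str, IndividualObservation],
) -> PopulationFrequencyRecord:
    """Roll individual genotypes up into population frequencies.

    Allele frequencies are allele counts over total allele copies (2 x
    members under diploidy); genotype frequencies are genotype counts over
    members.  Every member must have an observation for the variation.
    """
    if not population.members:
        raise ValueError(f"population {population.id} has no members")
    missing = [m for m in population.members if m not in observations]
    if missing:
        raise ValueError(
            f"population {population.id}: members without an observation for "
            f"{variation.id}: {missing}")
    allele_counts: Counter[str] = Counter()
    genotype_counts: Counter[str] = Counter()
    total_copies = 0
    for member in population.members:
        obs = observations[member]
        allele_counts.update(obs.genotype)
        genotype_counts[genotype_key(obs.genotype)] += 1
        total_copies += len(obs.genotype)
    n = len(population.members)
    return PopulationFrequencyRecord(
        variation=variation.id,
        population=population.id,
        allele_frequencies={a: c / total_copies for a, c in sorted(allele_counts.items())},
        genotype_frequencies={g: c / n for g, c in sorted(genotype_counts.items())},
    )
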