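"""Three-level variation representation and frequency aggregation."""

from collections import Counter

import pytest
from hypothesis import given, strategies as st

from genoschema import CapabilityError, Instance, SchemaMode
from genoschema.variation import (
    Individual,
    Population,
    Variation,
    VariationKind,
    aggregate_frequencies,
    genotype_key,
    make_individual_observation,
    make_population_frequencies,
    register_variation,
)


def snp(vid="v1", ref="G", alts=("A",)):
    return Variation(id=vid, kind=VariationKind.SNP, reference_allele=ref,
                     alternative_alleles=list(alts))


class TestRegistration:
    def test_snp_with_hgvs(self):
        v = register_variation({
            "id": "v1", "kind": "SNP", "reference_allele": "G",
            "alternative_alleles": ["A"],
            "hgvs": "NM_000492.3(CFTR):c.57G>A(p.Trp19Ter)"})
        assert v.alleles() == {"G", "A"}

    def test_snp_multibase_allele_rejected(self):
        with pytest.raises(ValueError):
            snp(alts=("AT",))

    def test_indel_registered(self):
        v = Variation(id="v2", kind=VariationKind.indel, reference_allele="A",
                      alternative_alleles=["ATTG"])
        assert v.kind is VariationKind.indel

    def test_duplicate_alleles_rejected(self):
        with pytest.raises(ValueError):
            snp(alts=("G",))

    def test_empty_alternatives_rejected(self):
        with pytest.raises(ValueError):
            Variation(id="v3", kind=VariationKind.SNP, reference_allele="G",
                      alternative_alleles=[])


class TestPopulationFrequencies:
    def test_hardy_weinberg_toy_accepted_in_all_modes(self):
        pop = Population(id="p1")
        for mode in SchemaMode:
            if mode is SchemaMode.CSCG:
                continue
            record = make_population_frequencies(
                snp(), pop, {"G": 0.9, "A": 0.1},
                {"G/G": 0.81, "G/A": 0.18, "A/A": 0.01}, mode=mode)
            assert record.genotype_frequencies["A/G"] == 0.18  # canonical key

    def test_sum_violation_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            make_population_frequencies(snp(), Population(id="p1"),
                                        {"G": 0.6, "A": 0.6}, {})

    def test_unknown_allele_rejected(self):
        with pytest.raises(ValueError, match="neither the reference"):
            make_population_frequencies(snp(), Population(id="p1"),
                                        {"G": 0.5, "T": 0.5}, {})

    def test_indel_genotype_frequencies_mode_guard(self):
        """Genotype frequencies generalize to every variation kind under the
        species-independent schema, but the human schema accepts them for
        SNPs only and the citrus schema has no population level at all."""
        indel = Variation(id="v2", kind=VariationKind.indel,
                          reference_allele="A", alternative_alleles=["ATTG"])
        pop = Population(id="p1")
        freqs = ({"A": 0.7, "ATTG": 0.3},
                 {"A/A": 0.49, "A/ATTG": 0.42, "ATTG/ATTG": 0.09})
        record = make_population_frequencies(indel, pop, *freqs,
                                             mode=SchemaMode.CSG)
        assert abs(sum(record.genotype_frequencies.values()) - 1) < 1e-6
        with pytest.raises(CapabilityError):
            make_population_frequencies(indel, pop, *freqs,
                                        mode=SchemaMode.CSHG)
        with pytest.raises(CapabilityError):
            make_population_frequencies(indel, pop, *freqs,
                                        mode=SchemaMode.CSCG)

    def test_individual_level_mode_guard(self):
        ind = Individual(id="i1")
        obs = make_individual_observation(snp(), ind, ("G", "A"),
                                          mode=SchemaMode.CSCG)
        assert obs.allele_fractions == {"A": 0.5, "G": 0.5}
        with pytest.raises(CapabilityError):
            make_individual_observation(snp(), ind, ("G", "A"),
                                        mode=SchemaMode.CSHG)


class TestAggregation:
    def _population(self, genotypes):
        pop = Population(id="p1",
                         members=[f"i{k}" for k in range(len(genotypes))])
        variation = snp()
        observations = {
            f"i{k}": make_individual_observation(
                variation, Individual(id=f"i{k}"), g)
            for k, g in enumerate(genotypes)}
        return pop, variation, observations

    def test_hand_counted_example(self):
        pop, variation, obs = self._population(
            [("G", "G"), ("G", "A"), ("G", "A"), ("A", "A")])
        record = aggregate_frequencies(pop, variation, obs)
        assert record.allele_frequencies == {"G": 0.5, "A": 0.5}
        assert record.genotype_frequencies == {
            "G/G": 0.25, "A/G": 0.5, "A/A": 0.25}

    def test_single_member(self):
        pop, variation, obs = self._population([("G", "G")])
        record = aggregate_frequencies(pop, variation, obs)
        assert record.allele_frequencies == {"G": 1.0}
        assert record.genotype_frequencies == {"G/G": 1.0}

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError, match="no members"):
            aggregate_frequencies(Population(id="p1"), snp(), {})

    def test_member_without_observation_rejected(self):
        pop, variation, obs = self._population([("G", "G"), ("G", "A")])
        del obs["i1"]
        with pytest.raises(ValueError, match="without an observation"):
            aggregate_frequencies(pop, variation, obs)

    @given(genotypes=st.lists(
        st.tuples(st.sampled_from("GA"), st.sampled_from("GA")),
        min_size=1, max_size=30))
    def test_aggregation_matches_brute_force_counting(self, genotypes):
        """Aggregated frequencies equal direct counting over the multiset of
        member genotypes (diploid)."""
        pop, variation, obs = self._population(genotypes)
        record = aggregate_frequencies(pop, variation, obs)
        allele_counts = Counter(a for g in genotypes for a in g)
        genotype_counts = Counter(genotype_key(g) for g in genotypes)
        n = len(genotypes)
        assert record.allele_frequencies == {
            a: c / (2 * n) for a, c in allele_counts.items()}
        assert record.genotype_frequencies == {
            g: c / n for g, c in genotype_counts.items()}


class TestLevelSeparation:
    def test_general_level_survives_frequency_deletion(self):
        instance = Instance()
        instance.add_variation(snp())
        instance.add_population(Population(id="p1", members=["i1"]))
        instance.add_individual(Individual(id="i1", populations=["p1"]))
        instance.add_individual_observation("v1", "i1", ("G", "A"))
        instance.set_population_frequencies("v1", "p1", {"G": 0.5, "A": 0.5},
                                            {"A/G": 1.0})
        instance.population_frequencies.clear()
        instance.observations.clear()
        assert instance.variations["v1"].alleles() == {"G", "A"}
        assert instance.validate() == []
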