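"""Expected progeny distributions and sire-scenario enumeration."""

import itertools

import numpy as np
import pytest

from trioecy.crosses import (
    CANONICAL_FEMALE,
    CrossType,
    PHENOTYPE_ORDER,
    enumerate_sire_scenarios,
    expected_ratio_named_model,
    progeny_distribution,
)
from trioecy.genetics import (
    Cytotype,
    INDEPENDENT_MAP,
    Phenotype,
    PlantGenotype,
    RecombinationMap,
    classify_phenotype,
    gamete_distribution,
)


def brute_force_progeny(mother, father, rmap):
    """Oracle: enumerate every (ovule, pollen) haplotype pair and classify
    the zygote, independently of the vectorised path."""
    probs = dict.fromkeys(PHENOTYPE_ORDER, 0.0)
    for hm, pm in gamete_distribution(mother, rmap).items():
        for hf, pf in gamete_distribution(father, rmap).items():
            z = PlantGenotype(hm, hf, mother.cytotype)
            probs[classify_phenotype(z)] += pm * pf
    return np.array([probs[ph] for ph in PHENOTYPE_ORDER])


class TestProgenyDistribution:
    def test_fxh_het_single_locus_half_females(self, independent_map):
        """A female crossed to a sire heterozygous at one restorer locus
        leaves half the progeny unrestored (female)."""
        for cyto in ("S", "N"):
            sire = PlantGenotype.from_string(f"RXr/rXr;{cyto}")
            dist = progeny_distribution(CANONICAL_FEMALE, sire, independent_map)
            assert dist.p_female == pytest.approx(0.5)
            assert dist.p_male == dist.p_sterile_male == 0.0

    def test_selfed_het_hermaphrodite_quarter_females(self, independent_map):
        herm = PlantGenotype.from_string("RXr/rXr;S")
        dist = progeny_distribution(herm, herm, independent_map)
        assert dist.p_female == pytest.approx(0.25)

    def test_fxm_coupling_sire_fitted_map(self, fitted_map):
        """Sire with both restorers on the Y: half the progeny are male,
        31.5% female, 18.5% hermaphrodite, no sterile males."""
        sire = PlantGenotype.from_string("RYR/rXr;N")
        dist = progeny_distribution(CANONICAL_FEMALE, sire, fitted_map)
        assert dist.as_array() == pytest.approx([0.5, 0.0, 0.315, 0.185])
        assert dist.as_array() == pytest.approx(
            brute_force_progeny(CANONICAL_FEMALE, sire, fitted_map)
        )

    def test_fxm_repulsion_sire_fitted_map(self, fitted_map):
        """Sire with both restorers on the X: the parental Y gamete is
        unrestored, so sterile males replace males at the parental rate."""
        sire = PlantGenotype.from_string("rYr/RXR;N")
        dist = progeny_distribution(CANONICAL_FEMALE, sire, fitted_map)
        assert dist.as_array() == pytest.approx([0.185, 0.315, 0.0, 0.5])
        assert dist.as_array() == pytest.approx(
            brute_force_progeny(CANONICAL_FEMALE, sire, fitted_map)
        )

    @pytest.mark.parametrize("bad_mother", ["RYR/rXr;S", "rYr/rXr;S"])
    def test_rejects_male_mothers(self, fitted_map, bad_mother):
        with pytest.raises(ValueError, match="ovules"):
            progeny_distribution(
                PlantGenotype.from_string(bad_mother),
                PlantGenotype.from_string("RYR/rXr;N"),
                fitted_map,
            )

    @pytest.mark.parametrize("bad_father", ["rXr/rXr;S", "rYr/rXr;S"])
    def test_rejects_pollenless_fathers(self, fitted_map, bad_father):
        with pytest.raises(ValueError, match="pollen"):
            progeny_distribution(
                CANONICAL_FEMALE, PlantGenotype.from_string(bad_father), fitted_map
            )

    def test_n_cytotype_mother_no_females_or_sterile_males(self, fitted_map):
        """Male sterility is maternal: an N mother cannot have unrestored
        offspring whatever the sire contributes."""
        mother = PlantGenotype.from_string("rXr/rXr;N")
        for sire_s in ("RYR/rXr;N", "rYr/rXr;N", "RXr/rXR;N"):
            dist = progeny_distribution(
                mother, PlantGenotype.from_string(sire_s), fitted_map
            )
            assert dist.p_female == 0.0
            assert dist.p_sterile_male == 0.0

    def test_complete_linkage_coupling_sire_is_dioecy_like(self):
        rmap = RecombinationMap(0.0, 0.0)
        sire = PlantGenotype.from_string("RYR/rXr;N")
        dist = progeny_distribution(CANONICAL_FEMALE, sire, rmap)
        assert dist.as_array() == pytest.approx([0.5, 0.0, 0.5, 0.0])

    def test_matches_brute_force_over_many_crosses(self, fitted_map):
        sires = ["RYR/rXr;N", "RYr/rXR;N", "rYR/RXr;N", "RXR/rXr;N", "RXr/rXR;S"]
        mothers = ["rXr/rXr;S", "rXr/rXr;N", "RXr/rXr;S"]
        for ms, fs in itertools.product(mothers, sires):
            mother = PlantGenotype.from_string(ms)
            father = PlantGenotype.from_string(fs)
            dist = progeny_distribution(mother, father, fitted_map)
            assert dist.as_array() == pytest.approx(
                brute_force_progeny(mother, father, fitted_map)
            )
            assert dist.as_array().sum() == pytest.approx(1.0, abs=1e-12)


class TestNamedModels:
    def test_two_locus_unlinked_fxh_quarter_females(self):
        dist = expected_ratio_named_model("two_locus_unlinked_het_both", CrossType.FxH)
        assert dist.p_female == pytest.approx(0.25)

    def test_one_locus_het_fxm_1_1_2(self):
        """female : hermaphrodite : Y-carrier = 1 : 1 : 2."""
        dist = expected_ratio_named_model("one_locus_het", CrossType.FxM)
        assert dist.p_female == pytest.approx(0.25)
        assert dist.p_hermaphrodite == pytest.approx(0.25)
        assert dist.p_male + dist.p_sterile_male == pytest.approx(0.5)

    def test_two_locus_het_fxm_1_3_4(self):
        dist = expected_ratio_named_model("two_locus_unlinked_het_both", CrossType.FxM)
        assert dist.p_female == pytest.approx(0.125)
        assert dist.p_hermaphrodite == pytest.approx(0.375)
        assert dist.p_male + dist.p_sterile_male == pytest.approx(0.5)

    def test_linked_coupled_sire_fxh(self, fitted_map):
        dist = expected_ratio_named_model(
            "linked_coupled_sire", CrossType.FxH, fitted_map
        )
        assert dist.p_female == pytest.approx(0.315)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            expected_ratio_named_model("five_locus", CrossType.FxH)


class TestScenarioEnumeration:
    def test_coupling_scenario_present_fxm(self, fitted_map):
        scen = enumerate_sire_scenarios(CrossType.FxM, fitted_map)
        dists = {s.label: d.as_array() for s, d in scen}
        assert "RYR/rXr" in dists
        assert dists["RYR/rXr"] == pytest.approx([0.5, 0.0, 0.315, 0.185])

    def test_all_distributions_sum_to_one_and_distinct(self, fitted_map):
        for cross_type in (CrossType.FxM, CrossType.FxH):
            scen = enumerate_sire_scenarios(cross_type, fitted_map)
            arrays = [d.as_array() for _, d in scen]
            for arr in arrays:
                assert arr.sum() == pytest.approx(1.0, abs=1e-9)
            for a, b in itertools.combinations(arrays, 2):
                assert np.abs(a - b).max() > 1e-9

    def test_fxh_never_produces_males(self, fitted_map, independent_map):
        for rmap in (fitted_map, independent_map):
            for _, d in enumerate_sire_scenarios(CrossType.FxH, rmap):
                assert d.p_male == 0.0
                assert d.p_sterile_male == 0.0

    def test_fxh_independent_female_fractions(self, independent_map):
        """Free recombination: hermaphrodite sires produce exactly 0, 1/4
        or 1/2 females depending on restorer zygosity."""
        scen = enumerate_sire_scenarios(CrossType.FxH, independent_map)
        fracs = sorted({round(d.p_female, 9) for _, d in scen})
        assert fracs == [0.0, 0.25, 0.5]

    def test_complete_linkage_collapses(self):
        rmap = RecombinationMap(0.0, 0.0)
        scen = enumerate_sire_scenarios(CrossType.FxM, rmap)
        assert len(scen) <= 4

    def test_scenario_sires_are_fertile(self, fitted_map):
        for cross_type, required in (
            (CrossType.FxM, Phenotype.MALE),
            (CrossType.FxH, Phenotype.HERMAPHRODITE),
        ):
            for s, _ in enumerate_sire_scenarios(cross_type, fitted_map):
                assert classify_phenotype(s.genotype) is required
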