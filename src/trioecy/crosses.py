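"""Expected progeny phenotype distributions for controlled crosses.

Three cross types occur in the breeding design: female × male (FxM),
female × hermaphrodite (FxH), and self-fertilised hermaphrodites
(HxH_self). The canonical female mother is homozygous non-restoring at
both restorer loci on the sterility cytoplasm, ``rXr/rXr;S`` — under the
cytoplasmic-male-sterility model a female must lack both the Y and any
restorer allele.

Expected distributions are exact: the maternal and paternal gamete
distributions are convolved, the offspring cytotype is set to the
mother's, and each zygote is classified.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .genetics import (
    HAPLOTYPES,
    INDEPENDENT_MAP,
    Cytotype,
    Haplotype,
    Phenotype,
    PlantGenotype,
    RecombinationMap,
    SegregationMode,
    classify_phenotype,
    gamete_probs,
)

__all__ = [
    "CrossType",
    "SireScenario",
    "PhenotypeDistribution",
    "CANONICAL_FEMALE",
    "progeny_distribution",
    "expected_ratio_named_model",
    "enumerate_sire_scenarios",
]

#: Phenotype ordering used throughout for count/probability vectors.
PHENOTYPE_ORDER: Tuple[Phenotype, ...] = (
    Phenotype.MALE,
    Phenotype.STERILE_MALE,
    Phenotype.FEMALE,
    Phenotype.HERMAPHRODITE,
)


class CrossType(str, enum.Enum):
    FxM = "FxM"
    FxH = "FxH"
    HxH_self = "HxH_self"


@dataclass(frozen=True)
class PhenotypeDistribution:
    """Probabilities of the four offspring phenotype classes."""

    p_male: float
    p_sterile_male: float
    p_female: float
    p_hermaphrodite: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if np.any(arr < -1e-12):
            raise ValueError("phenotype probabilities must be non-negative")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"phenotype probabilities must sum to 1, got {arr.sum()}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.p_male, self.p_sterile_male, self.p_female, self.p_hermaphrodite]
        )

    def as_dict(self) -> Dict[Phenotype, float]:
        return dict(zip(PHENOTYPE_ORDER, self.as_array()))

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "PhenotypeDistribution":
        return cls(*(float(x) for x in arr))


@dataclass(frozen=True)
class SireScenario:
    """A candidate sire genotype: a phase assignment of restorer alleles
    across the two homologs (Y/X for males, X/X for hermaphrodites)."""

    label: str
    genotype: PlantGenotype
    description: str = ""


#: Canonical female mother: no Y, no restorers, sterility cytoplasm.
CANONICAL_FEMALE = PlantGenotype.from_string("rXr/rXr;S")


def progeny_distribution(
    mother: PlantGenotype,
    father: PlantGenotype,
    rmap: RecombinationMap,
) -> PhenotypeDistribution:
    """Exact phenotype distribution of the progeny of one cross.

    The offspring cytotype equals the mother's (strict maternal
    inheritance); the sire's cytotype is carried but never transmitted.
    For a selfed hermaphrodite pass the same genotype as both parents.
    """
    mother_ph = classify_phenotype(mother)
    father_ph = classify_phenotype(father)
    if mother_ph in (Phenotype.MALE, Phenotype.STERILE_MALE):
        raise ValueError(f"mother {mother} is {mother_ph.value}: produces no ovules")
    if father_ph in (Phenotype.FEMALE, Phenotype.STERILE_MALE):
        raise ValueError(f"father {father} is {father_ph.value}: produces no pollen")

    ovules = gamete_probs(mother, rmap)
    pollen = gamete_probs(father, rmap)
    probs = np.zeros(len(PHENOTYPE_ORDER))
    pheno_pos = {ph: i for i, ph in enumerate(PHENOTYPE_ORDER)}
    for i, pm in enumerate(ovules):
        if pm == 0.0:
            continue
        for j, pf in enumerate(pollen):
            if pf == 0.0:
                continue
            zygote = PlantGenotype(HAPLOTYPES[i], HAPLOTYPES[j], mother.cytotype)
            probs[pheno_pos[classify_phenotype(zygote)]] += pm * pf
    return PhenotypeDistribution.from_array(probs)


# Canonical sire genotypes for the named single- and two-locus hypotheses.
# Sires are placed on the N cytotype so their own fertility never depends
# on restoration; the sire cytotype is not transmitted.
_NAMED_MODELS = {
    # hermaphrodite sire homozygous for the restorer at one locus
    "one_locus_hom": "RXr/RXr;N",
    # hermaphrodite/male sire heterozygous at a single restorer locus
    "one_locus_het": "RXr/rXr;N",
    # sire heterozygous at both restorer loci, loci unlinked
    "two_locus_unlinked_het_both": "RXR/rXr;N",
    # sire with one restorer allele at each locus in coupling, linked map
    "linked_coupled_sire": "RXR/rXr;N",
}


def expected_ratio_named_model(
    model: str,
    cross_type: CrossType,
    rmap: Optional[RecombinationMap] = None,
) -> PhenotypeDistribution:
    """Closed-form progeny distributions for the named genetic hypotheses.

    ``one_locus_hom`` / ``one_locus_het`` — a single restorer locus,
    homozygous or heterozygous in the sire; ``two_locus_unlinked_het_both``
    — two unlinked restorer loci both heterozygous in the sire;
    ``linked_coupled_sire`` — both restorers on one homolog under a linked
    map (requires ``rmap``). All delegate to :func:`progeny_distribution`
    with the canonical genotypes; maleness hypotheses substitute a Y for
    one X in the sire.
    """
    cross_type = CrossType(cross_type)
    if model not in _NAMED_MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(_NAMED_MODELS)}")
    if model == "linked_coupled_sire":
        if rmap is None:
            raise ValueError("linked_coupled_sire requires a recombination map")
        if rmap.mode is not SegregationMode.NO_DOUBLE_CROSSOVER:
            raise ValueError("linked_coupled_sire requires a linked (no-double-crossover) map")
    elif rmap is None:
        rmap = INDEPENDENT_MAP

    sire = PlantGenotype.from_string(_NAMED_MODELS[model])
    if cross_type is CrossType.HxH_self:
        # selfing a sterility-cytoplasm hermaphrodite; restored, so fertile
        herm = PlantGenotype(sire.hap_a, sire.hap_b, Cytotype.S)
        return progeny_distribution(herm, herm, rmap)
    if cross_type is CrossType.FxH:
        return progeny_distribution(CANONICAL_FEMALE, sire, rmap)
    # FxM: put the Y on the restorer-bearing homolog
    a, b = sire.hap_a, sire.hap_b
    y_on, x_on = (a, b) if a.n_restorers >= b.n_restorers else (b, a)
    male = PlantGenotype(
        Haplotype(y_on.r1, "Y", y_on.r2), Haplotype(x_on.r1, "X", x_on.r2), Cytotype.N
    )
    return progeny_distribution(CANONICAL_FEMALE, male, rmap)


def enumerate_sire_scenarios(
    cross_type: CrossType,
    rmap: RecombinationMap,
    collapse_tol: float = 1e-12,
) -> List[Tuple[SireScenario, PhenotypeDistribution]]:
    """Enumerate phase-distinct sire genotypes and their progeny
    distributions against the canonical female mother.

    For FxM the sire carries one Y homolog and one X homolog, each with
    any combination of R/r at the two restorer loci (16 phase
    configurations); for FxH both homologs are X (10 unordered
    configurations). Scenario genotypes are placed on the sterility
    cytoplasm (the sire cytotype is never transmitted) and must be
    pollen-fertile — MALE for FxM, HERMAPHRODITE for FxH — which
    excludes the wholly unrestored configurations. Scenarios whose
    distributions coincide within ``collapse_tol`` are merged, keeping
    the first label encountered.
    """
    cross_type = CrossType(cross_type)
    if cross_type not in (CrossType.FxM, CrossType.FxH):
        raise ValueError("scenario enumeration applies to FxM and FxH crosses")

    required = (
        Phenotype.MALE if cross_type is CrossType.FxM else Phenotype.HERMAPHRODITE
    )
    restorer_pairs = list(itertools.product("Rr", repeat=2))
    sires: List[PlantGenotype] = []
    if cross_type is CrossType.FxM:
        for (a1, a2), (b1, b2) in itertools.product(restorer_pairs, repeat=2):
            sires.append(
                PlantGenotype(Haplotype(a1, "Y", a2), Haplotype(b1, "X", b2), Cytotype.S)
            )
    else:
        for (a1, a2), (b1, b2) in itertools.combinations_with_replacement(
            restorer_pairs, 2
        ):
            sires.append(
                PlantGenotype(Haplotype(a1, "X", a2), Haplotype(b1, "X", b2), Cytotype.S)
            )
    sires = [s for s in sires if classify_phenotype(s) is required]

    seen: Dict[Tuple[int, ...], Tuple[SireScenario, PhenotypeDistribution]] = {}
    ndigits = max(0, int(round(-np.log10(collapse_tol))))
    for sire in dict.fromkeys(sires):  # unique genotypes, insertion order
        dist = progeny_distribution(CANONICAL_FEMALE, sire, rmap)
        key = tuple(np.round(dist.as_array(), ndigits))
        if key not in seen:
            haps = f"{sire.hap_a}/{sire.hap_b}"
            scenario = SireScenario(
                label=haps,
                genotype=sire,
                description=f"sire restorer phase {haps}",
            )
            seen[key] = (scenario, dist)
    return list(seen.values())
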