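"""Three-locus sex-chromosome model with a maternally inherited cytotype.

The model describes a sex chromosome carrying, in order, a dominant
male-fertility restorer locus (R1), the sex-determining locus (SDL, with
dominant male-determining allele Y), and a second restorer locus (R2).
A plant additionally carries one of two cytotypes: S (male-sterility
cytoplasm) or N (normal cytoplasm), inherited strictly through the mother.

Four sexual phenotypes arise from the interaction of the Y allele with
cytoplasmic male sterility and its nuclear restorers:

* ``MALE`` — carries Y; pollen-fertile (normal cytoplasm, or sterility
  cytoplasm restored by at least one dominant R allele at R1 or R2).
* ``STERILE_MALE`` — carries Y but expresses the sterility cytoplasm
  unrestored: male inflorescence architecture, no functional pollen.
* ``HERMAPHRODITE`` — no Y; pollen-fertile (monoecious).
* ``FEMALE`` — no Y; sterility cytoplasm, no restorer: functionally female.

Restoration is dominant and the two restorer loci are redundant — a single
R allele at either locus suffices.

Meiosis is modelled either with free recombination (``independent`` mode)
or with the two interval recombination fractions r12 (R1–SDL) and r23
(SDL–R2) under the assumption that double crossovers do not occur
(``no_double_crossover`` mode), so a gamete results from exactly one of
three mutually exclusive events: no crossover, a crossover in interval 1,
or a crossover in interval 2.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

__all__ = [
    "Cytotype",
    "Phenotype",
    "Haplotype",
    "PlantGenotype",
    "RecombinationMap",
    "HAPLOTYPES",
    "HAPLOTYPE_INDEX",
    "classify_phenotype",
    "gamete_distribution",
    "gamete_probs",
]

_RESTORER_ALLELES = ("R", "r")
_SDL_ALLELES = ("Y", "X")


class Cytotype(str, enum.Enum):
    """Cytoplasmic type: S = male-sterility cytoplasm, N = normal."""

    S = "S"
    N = "N"


class Phenotype(str, enum.Enum):
    MALE = "male"
    STERILE_MALE = "sterile_male"
    FEMALE = "female"
    HERMAPHRODITE = "hermaphrodite"


@dataclass(frozen=True, order=True)
class Haplotype:
    """Ordered three-locus haplotype: R1 allele, SDL allele, R2 allele."""

    r1: str
    sdl: str
    r2: str

    def __post_init__(self) -> None:
        if self.r1 not in _RESTORER_ALLELES or self.r2 not in _RESTORER_ALLELES:
            raise ValueError(f"restorer alleles must be in {_RESTORER_ALLELES}")
        if self.sdl not in _SDL_ALLELES:
            raise ValueError(f"SDL allele must be in {_SDL_ALLELES}")

    @property
    def has_y(self) -> bool:
        return self.sdl == "Y"

    @property
    def n_restorers(self) -> int:
        return (self.r1 == "R") + (self.r2 == "R")

    def __str__(self) -> str:
        return f"{self.r1}{self.sdl}{self.r2}"

    @classmethod
    def from_string(cls, s: str) -> "Haplotype":
        s = s.strip()
        if len(s) != 3:
            raise ValueError(f"haplotype string must have 3 characters: {s!r}")
        return cls(s[0], s[1], s[2])


#: The eight possible haplotypes, in a fixed canonical order.
HAPLOTYPES: Tuple[Haplotype, ...] = tuple(
    Haplotype(r1, sdl, r2)
    for r1 in _RESTORER_ALLELES
    for sdl in _SDL_ALLELES
    for r2 in _RESTORER_ALLELES
)

HAPLOTYPE_INDEX: Dict[Haplotype, int] = {h: i for i, h in enumerate(HAPLOTYPES)}


@dataclass(frozen=True)
class PlantGenotype:
    """Phase-resolved pair of haplotypes plus the maternal cytotype.

    Equality and hashing are invariant under swapping the two haplotypes:
    the pair is normalised to sorted order at construction.
    """

    hap_a: Haplotype
    hap_b: Haplotype
    cytotype: Cytotype

    def __post_init__(self) -> None:
        cyto = Cytotype(self.cytotype)
        a, b = sorted((self.hap_a, self.hap_b))
        object.__setattr__(self, "hap_a", a)
        object.__setattr__(self, "hap_b", b)
        object.__setattr__(self, "cytotype", cyto)

    @property
    def has_y(self) -> bool:
        return self.hap_a.has_y or self.hap_b.has_y

    @property
    def is_yy(self) -> bool:
        """YY genotypes are representable but never produced by model crosses
        (mothers are always non-Y)."""
        return self.hap_a.has_y and self.hap_b.has_y

    @property
    def n_restorer_alleles(self) -> int:
        return self.hap_a.n_restorers + self.hap_b.n_restorers

    @property
    def n_restored_loci(self) -> int:
        """Number of restorer loci (0–2) carrying at least one R allele."""
        r1 = self.hap_a.r1 == "R" or self.hap_b.r1 == "R"
        r2 = self.hap_a.r2 == "R" or self.hap_b.r2 == "R"
        return int(r1) + int(r2)

    @property
    def restored(self) -> bool:
        return self.n_restored_loci > 0

    def __str__(self) -> str:
        return f"{self.hap_a}/{self.hap_b};{self.cytotype.value}"

    @classmethod
    def from_string(cls, s: str) -> "PlantGenotype":
        """Parse compact genotype strings such as ``"RYR/rXr;S"``."""
        try:
            haps, cyto = s.strip().split(";")
            a, b = haps.split("/")
        except ValueError as exc:
            raise ValueError(f"malformed genotype string {s!r}") from exc
        return cls(Haplotype.from_string(a), Haplotype.from_string(b), Cytotype(cyto))


class SegregationMode(str, enum.Enum):
    NO_DOUBLE_CROSSOVER = "no_double_crossover"
    INDEPENDENT = "independent"


@dataclass(frozen=True)
class RecombinationMap:
    """Interval recombination fractions r12 (R1–SDL) and r23 (SDL–R2).

    In ``no_double_crossover`` mode a meiosis experiences exactly one of
    three events — no crossover (probability 1 − r12 − r23), a crossover
    in interval 1 (r12), or a crossover in interval 2 (r23) — so
    r12 + r23 must not exceed 1. In ``independent`` mode the three loci
    assort freely, which is the appropriate limit for unlinked loci.
    """

    r12: float = 0.0
    r23: float = 0.0
    mode: SegregationMode = SegregationMode.NO_DOUBLE_CROSSOVER

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", SegregationMode(self.mode))
        for name, r in (("r12", self.r12), ("r23", self.r23)):
            if not 0.0 <= r <= 0.5:
                raise ValueError(f"{name} must lie in [0, 0.5], got {r}")
        if self.mode is SegregationMode.NO_DOUBLE_CROSSOVER and self.r12 + self.r23 > 1.0:
            raise ValueError(
                "no_double_crossover mode requires r12 + r23 <= 1 "
                f"(got {self.r12} + {self.r23})"
            )


#: Free recombination among all three loci.
INDEPENDENT_MAP = RecombinationMap(0.5, 0.5, SegregationMode.INDEPENDENT)

#: The best-fit linked map inferred from crosses (r12 = 0.11, r23 = 0.26).
FITTED_MAP = RecombinationMap(0.11, 0.26, SegregationMode.NO_DOUBLE_CROSSOVER)


def classify_phenotype(genotype: PlantGenotype) -> Phenotype:
    """Assign the sexual phenotype implied by a genotype.

    The Y allele is dominant male-determining; the sterility cytoplasm S
    abolishes pollen production unless at least one dominant restorer
    allele is present at R1 or R2 (the loci are redundant). Total
    function — every genotype maps to exactly one phenotype.
    """
    fertile = genotype.cytotype is Cytotype.N or genotype.restored
    if genotype.has_y:
        return Phenotype.MALE if fertile else Phenotype.STERILE_MALE
    return Phenotype.HERMAPHRODITE if fertile else Phenotype.FEMALE


def gamete_probs(genotype: PlantGenotype, rmap: RecombinationMap) -> np.ndarray:
    """Gamete haplotype probabilities as a length-8 vector over HAPLOTYPES.

    ``no_double_crossover``: the two parental haplotypes appear with
    probability (1 − r12 − r23)/2 each, interval-1 recombinants with
    r12/2 each and interval-2 recombinants with r23/2 each.
    ``independent``: each locus transmits either homolog's allele with
    probability 1/2, independently of the other loci.
    """
    a, b = genotype.hap_a, genotype.hap_b
    out = np.zeros(len(HAPLOTYPES))
    if rmap.mode is SegregationMode.INDEPENDENT:
        for r1 in (a.r1, b.r1):
            for sdl in (a.sdl, b.sdl):
                for r2 in (a.r2, b.r2):
                    out[HAPLOTYPE_INDEX[Haplotype(r1, sdl, r2)]] += 0.125
        return out
    p_par = (1.0 - rmap.r12 - rmap.r23) / 2.0
    events = (
        (p_par, a),
        (p_par, b),
        # crossover in interval 1: R1 allele swaps homolog
        (rmap.r12 / 2.0, Haplotype(a.r1, b.sdl, b.r2)),
        (rmap.r12 / 2.0, Haplotype(b.r1, a.sdl, a.r2)),
        # crossover in interval 2: R2 allele swaps homolog
        (rmap.r23 / 2.0, Haplotype(a.r1, a.sdl, b.r2)),
        (rmap.r23 / 2.0, Haplotype(b.r1, b.sdl, a.r2)),
    )
    for p, hap in events:
        out[HAPLOTYPE_INDEX[hap]] += p
    return out


def gamete_distribution(
    genotype: PlantGenotype, rmap: RecombinationMap
) -> Dict[Haplotype, float]:
    """Gamete distribution as a dict restricted to positive-probability
    haplotypes; probabilities sum to 1."""
    probs = gamete_probs(genotype, rmap)
    return {h: p for h, p in zip(HAPLOTYPES, probs) if p > 0.0}
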