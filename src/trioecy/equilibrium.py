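"""Deterministic infinite-population recursion of genotype frequencies.

The state is the frequency vector over all 72 genotypes: 36 unordered
pairs of the 8 sex-chromosome haplotypes crossed with the 2 cytotypes.
Each generation:

1. every genotype contributes to the pollen pool in proportion to its
   frequency times its pollen output (males produce ``male_pollen_advantage``
   times the hermaphrodite output; females and sterile males produce
   none), discounted by the restoration cost;
2. ovule output is the female seed advantage for females, 1 for
   hermaphrodites, 0 otherwise, with the same cost discount;
3. hermaphrodites self-fertilise a fixed fraction *s* of their ovules
   with their own pollen (selfed zygotes survive with probability
   1 − *d*, the inbreeding depression); females, and the remaining
   hermaphrodite ovules, outcross to the population pollen pool;
4. offspring inherit the mother's cytotype; zygote frequencies are
   renormalised to sum to 1.

The restoration cost ρ multiplies both pollen and seed output by
(1 − ρ) for each restorer locus carrying at least one R allele,
combined multiplicatively across the two loci. By default the cost is
charged for carrying restorers regardless of cytoplasm: restorers are
then selected against whenever the sterility cytotype is rare, which
is what allows the cytotype and the restorers to be maintained jointly
(and females with them). The alternative convention — cost expressed
only on the sterility cytoplasm, restorers silent and neutral on N —
is available via ``cost_on_normal_cytotype=False``; under it the
sterility cytoplasm is purged and females are lost for any cost.

Convergence is declared when none of the four tracked allele
frequencies (R at R1, Y, R at R2, cytotype S) changes by more than the
tolerance over a trailing window of generations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .genetics import (
    HAPLOTYPES,
    Cytotype,
    Phenotype,
    PlantGenotype,
    RecombinationMap,
    classify_phenotype,
    gamete_probs,
)

__all__ = [
    "FitnessParams",
    "SimConfig",
    "PopulationState",
    "EquilibriumResult",
    "StateSpace",
    "step",
    "run_to_equilibrium",
    "sweep",
    "uniform_state",
]


@dataclass(frozen=True)
class FitnessParams:
    """Morph fitnesses and mating-system parameters.

    male_pollen_advantage
        Pollen output of a male relative to a fertile hermaphrodite
        (field estimates span roughly 6–15, point estimate ~12).
    female_seed_advantage
        Seed output of a female relative to a hermaphrodite (1.0–1.11).
    selfing_rate
        Fraction *s* of each hermaphrodite's ovules self-fertilised.
    inbreeding_depression
        Survival penalty *d* of selfed zygotes (weight 1 − d).
    restoration_cost
        Cost ρ per restored locus, on both pollen and seed output.
    cost_on_normal_cytotype
        Charge ρ for carrying restorers on the normal cytoplasm too
        (default True; see module docstring).
    cost_per_allele
        Charge ρ per restorer allele instead of per restored locus.
    """

    male_pollen_advantage: float = 12.0
    female_seed_advantage: float = 1.05
    selfing_rate: float = 0.0
    inbreeding_depression: float = 0.0
    restoration_cost: float = 0.0
    cost_on_normal_cytotype: bool = True
    cost_per_allele: bool = False

    def __post_init__(self) -> None:
        if self.male_pollen_advantage < 0 or self.female_seed_advantage < 0:
            raise ValueError("fitness ratios must be non-negative")
        for name in ("selfing_rate", "inbreeding_depression"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.restoration_cost < 1.0:
            raise ValueError("restoration_cost must lie in [0, 1)")


@dataclass(frozen=True)
class SimConfig:
    rmap: RecombinationMap = RecombinationMap(0.11, 0.26)
    tolerance: float = 1e-6
    window: int = 20
    max_generations: int = 50_000
    initial: Union[str, np.ndarray] = "uniform"

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.window < 1:
            raise ValueError("window must be >= 1")


class StateSpace:
    """Precomputed arrays over the 72 genotype states for one map.

    States are indexed by (unordered haplotype pair, cytotype); the
    collapse from ordered zygote pairs to unordered states and the
    per-genotype gamete distributions are cached here so a generation
    step reduces to a handful of small matrix operations.
    """

    def __init__(self, rmap: RecombinationMap):
        self.rmap = rmap
        pairs = list(itertools.combinations_with_replacement(range(len(HAPLOTYPES)), 2))
        self.pairs = pairs
        self.n_pairs = len(pairs)  # 36
        self.genotypes: List[PlantGenotype] = []
        for cyto in (Cytotype.S, Cytotype.N):
            for i, j in pairs:
                self.genotypes.append(
                    PlantGenotype(HAPLOTYPES[i], HAPLOTYPES[j], cyto)
                )
        self.n_states = len(self.genotypes)  # 72
        self.cyto_is_s = np.array(
            [g.cytotype is Cytotype.S for g in self.genotypes]
        )
        phenos = [classify_phenotype(g) for g in self.genotypes]
        self.phenotypes = phenos
        self.is_male = np.array([p is Phenotype.MALE for p in phenos])
        self.is_herm = np.array([p is Phenotype.HERMAPHRODITE for p in phenos])
        self.is_female = np.array([p is Phenotype.FEMALE for p in phenos])
        self.is_sterile = np.array([p is Phenotype.STERILE_MALE for p in phenos])
        self.n_restored_loci = np.array(
            [g.n_restored_loci for g in self.genotypes]
        )
        self.n_restorer_alleles = np.array(
            [g.n_restorer_alleles for g in self.genotypes]
        )
        # gamete distribution per state: (72, 8)
        self.gametes = np.array([gamete_probs(g, rmap) for g in self.genotypes])
        # ordered (8, 8) zygote pair -> unordered pair index (36)
        pair_index = np.zeros((8, 8), dtype=int)
        for k, (i, j) in enumerate(pairs):
            pair_index[i, j] = k
            pair_index[j, i] = k
        self.pair_index_flat = pair_index.ravel()
        # selfing: per state, distribution over unordered pairs (72, 36)
        outer = self.gametes[:, :, None] * self.gametes[:, None, :]
        self.self_pairs = np.apply_along_axis(
            lambda row: np.bincount(self.pair_index_flat, weights=row, minlength=self.n_pairs),
            1,
            outer.reshape(self.n_states, 64),
        )
        # allele dosage per state: columns (R at R1, Y, R at R2, cytotype S)
        dosage = np.zeros((self.n_states, 4))
        for k, g in enumerate(self.genotypes):
            dosage[k, 0] = ((g.hap_a.r1 == "R") + (g.hap_b.r1 == "R")) / 2.0
            dosage[k, 1] = (g.hap_a.has_y + g.hap_b.has_y) / 2.0
            dosage[k, 2] = ((g.hap_a.r2 == "R") + (g.hap_b.r2 == "R")) / 2.0
            dosage[k, 3] = float(g.cytotype is Cytotype.S)
        self.allele_dosage = dosage

    def collapse_cross(self, ovule_hap: np.ndarray, pollen_hap: np.ndarray) -> np.ndarray:
        """Unordered-pair distribution of zygotes from two haplotype pools."""
        outer = np.outer(ovule_hap, pollen_hap).ravel()
        return np.bincount(self.pair_index_flat, weights=outer, minlength=self.n_pairs)

    def state_index(self, genotype: PlantGenotype) -> int:
        return self.genotypes.index(genotype)


@dataclass
class PopulationState:
    """Frequency vector over the 72 genotype states plus a generation index."""

    frequencies: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 1:
            raise ValueError("frequencies must be a 1-D vector")
        if np.any(f < 0):
            raise ValueError("frequencies must be non-negative")
        total = f.sum()
        if total <= 0:
            raise ValueError("frequencies must have positive mass")
        self.frequencies = f / total

    def phenotype_frequencies(self, space: StateSpace) -> Dict[Phenotype, float]:
        f = self.frequencies
        return {
            Phenotype.MALE: float(f[space.is_male].sum()),
            Phenotype.STERILE_MALE: float(f[space.is_sterile].sum()),
            Phenotype.FEMALE: float(f[space.is_female].sum()),
            Phenotype.HERMAPHRODITE: float(f[space.is_herm].sum()),
        }

    def allele_frequencies(self, space: StateSpace) -> np.ndarray:
        """(R1-R, Y, R2-R, cytotype-S) frequencies."""
        return self.frequencies @ space.allele_dosage


@dataclass
class EquilibriumResult:
    state: PopulationState
    phenotype_frequencies: Dict[Phenotype, float]
    generations: int
    converged: bool
    max_drift: float  # largest |sum - 1| seen before renormalisation
    params: FitnessParams
    config: SimConfig

    @property
    def ternary_coordinates(self) -> Tuple[float, float]:
        """De Finetti coordinates of (female, male, hermaphrodite)
        renormalised over the three main morphs: x = h + m/2, y = (√3/2)·m."""
        ph = self.phenotype_frequencies
        f, m, h = (
            ph[Phenotype.FEMALE],
            ph[Phenotype.MALE],
            ph[Phenotype.HERMAPHRODITE],
        )
        total = f + m + h
        if total <= 0:
            return math.nan, math.nan
        f, m, h = f / total, m / total, h / total
        return h + m / 2.0, math.sqrt(3.0) / 2.0 * m


class ExtinctionError(RuntimeError):
    """The population cannot reproduce (no pollen for outcrossed ovules)."""


def uniform_state(
    space: StateSpace,
    cytotypes: Iterable[Cytotype] = (Cytotype.S, Cytotype.N),
    include_y: bool = True,
) -> PopulationState:
    """Equal frequency over the selected subset of genotype states."""
    cytoset = {Cytotype(c) for c in cytotypes}
    mask = np.array(
        [
            g.cytotype in cytoset and (include_y or not g.has_y)
            for g in space.genotypes
        ],
        dtype=float,
    )
    if mask.sum() == 0:
        raise ValueError("no states selected for the initial condition")
    return PopulationState(mask / mask.sum())


def _cost_factor(space: StateSpace, params: FitnessParams) -> np.ndarray:
    exponent = (
        space.n_restorer_alleles if params.cost_per_allele else space.n_restored_loci
    )
    factor = (1.0 - params.restoration_cost) ** exponent
    if not params.cost_on_normal_cytotype:
        factor = np.where(space.cyto_is_s, factor, 1.0)
    return factor


def step(
    state: PopulationState,
    params: FitnessParams,
    config: SimConfig,
    space: Optional[StateSpace] = None,
) -> Tuple[PopulationState, float]:
    """Advance one generation; returns the new state and the relative
    pre-normalisation drift of the zygote mass.

    The raw zygote vector is an expected-offspring measure that scales
    with fecundity, so conservation is checked against the ovule mass
    fed into pairing (each outcrossed ovule yields one zygote, each
    selfed ovule 1 − d): the pairing and unordered-pair collapse must
    preserve that mass to machine precision.
    """
    if space is None:
        space = StateSpace(config.rmap)
    f = state.frequencies
    cost = _cost_factor(space, params)
    pollen_out = f * cost * np.where(
        space.is_male, params.male_pollen_advantage, np.where(space.is_herm, 1.0, 0.0)
    )
    ovule_out = f * cost * np.where(
        space.is_female,
        params.female_seed_advantage,
        np.where(space.is_herm, 1.0, 0.0),
    )
    s = params.selfing_rate
    d = params.inbreeding_depression

    pollen_total = pollen_out.sum()
    outcross_w = ovule_out * np.where(space.is_herm, 1.0 - s, 1.0)
    if pollen_total <= 0.0:
        if outcross_w.sum() > 0.0:
            raise ExtinctionError(
                "no pollen produced while outcrossed ovules are present"
            )
        pollen_hap = np.zeros(len(HAPLOTYPES))
    else:
        pollen_hap = (pollen_out @ space.gametes) / pollen_total

    zygotes = np.zeros(space.n_states)
    half = space.n_pairs
    for cyto_is_s, offset in ((True, 0), (False, half)):
        mothers = space.cyto_is_s == cyto_is_s
        # selfed hermaphrodite ovules, discounted by inbreeding depression
        self_w = s * (1.0 - d) * ovule_out * (space.is_herm & mothers)
        pair_dist = self_w @ space.self_pairs
        # outcrossed ovules meet the population pollen pool
        ovule_hap = (outcross_w * mothers) @ space.gametes
        pair_dist = pair_dist + space.collapse_cross(ovule_hap, pollen_hap)
        zygotes[offset : offset + half] = pair_dist

    total = zygotes.sum()
    if total <= 0.0:
        raise ExtinctionError("no zygotes produced")
    # conservation check: pairing and pair-collapse must return exactly the
    # ovule mass fed in (selfed ovules carry the (1 - d) viability weight)
    expected_mass = float(
        (outcross_w.sum() if pollen_total > 0 else 0.0)
        + s * (1.0 - d) * ovule_out[space.is_herm].sum()
    )
    drift = abs(total - expected_mass) / max(expected_mass, 1e-300)
    return PopulationState(zygotes / total, state.generation + 1), drift


def run_to_equilibrium(
    params: FitnessParams,
    config: SimConfig = SimConfig(),
    space: Optional[StateSpace] = None,
) -> EquilibriumResult:
    """Iterate the recursion until the tracked allele frequencies change
    by less than the tolerance over the trailing window, or the
    generation cap is reached (``converged`` is False in that case)."""
    if space is None:
        space = StateSpace(config.rmap)
    if isinstance(config.initial, str):
        if config.initial != "uniform":
            raise ValueError(f"unknown initial preset {config.initial!r}")
        state = uniform_state(space)
    else:
        state = PopulationState(np.asarray(config.initial, dtype=float))

    history: List[np.ndarray] = [state.allele_frequencies(space)]
    max_drift = 0.0
    converged = False
    while state.generation < config.max_generations:
        state, drift = step(state, params, config, space)
        max_drift = max(max_drift, drift)
        history.append(state.allele_frequencies(space))
        if len(history) > config.window + 1:
            history.pop(0)
        if len(history) == config.window + 1:
            window = np.array(history)
            change = np.abs(window - window[-1]).max()
            if change < config.tolerance:
                converged = True
                break
    return EquilibriumResult(
        state=state,
        phenotype_frequencies=state.phenotype_frequencies(space),
        generations=state.generation,
        converged=converged,
        max_drift=max_drift,
        params=params,
        config=config,
    )


def sweep(
    param_grid: Sequence[FitnessParams],
    config: SimConfig = SimConfig(),
) -> pd.DataFrame:
    """Run :func:`run_to_equilibrium` for every parameter combination and
    return a tidy table (one row per combination) with equilibrium morph
    frequencies and De Finetti ternary coordinates."""
    space = StateSpace(config.rmap)
    rows = []
    for params in param_grid:
        res = run_to_equilibrium(params, config, space)
        ph = res.phenotype_frequencies
        x, y = res.ternary_coordinates
        rows.append(
            {
                "male_pollen_advantage": params.male_pollen_advantage,
                "female_seed_advantage": params.female_seed_advantage,
                "selfing_rate": params.selfing_rate,
                "inbreeding_depression": params.inbreeding_depression,
                "restoration_cost": params.restoration_cost,
                "freq_male": ph[Phenotype.MALE],
                "freq_sterile_male": ph[Phenotype.STERILE_MALE],
                "freq_female": ph[Phenotype.FEMALE],
                "freq_hermaphrodite": ph[Phenotype.HERMAPHRODITE],
                "ternary_x": x,
                "ternary_y": y,
                "generations": res.generations,
                "converged": res.converged,
            }
        )
    return pd.DataFrame(rows)
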