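"""Synthetic cross panels and population surveys.

Generators for data with the statistical structure the analyses assume:
cross progeny counts are multinomial draws from exact model-derived
phenotype distributions at a known (true) recombination map and sire
scenario mix; survey tables are multinomial draws from morph-frequency
archetypes spanning hermaphroditic to trioecious systems, or from
equilibria supplied by the deterministic simulator.

All generators are pure functions of their spec and seed; a panel's
hidden truth (which sire scenario generated each cross) is returned as
a separate table so recovery experiments cannot leak it into fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .crosses import (
    CANONICAL_FEMALE,
    CrossType,
    PhenotypeDistribution,
    progeny_distribution,
)
from .genetics import PlantGenotype, RecombinationMap
from .inference import CrossRecord
from .survey import PopulationRecord

__all__ = [
    "CrossPanelSpec",
    "SurveySpec",
    "SURVEY_ARCHETYPES",
    "simulate_cross",
    "simulate_cross_panel",
    "simulate_survey",
]

#: Default sire-scenario mix for FxM panels: the coupling configuration
#: (both restorers on the Y) predominates, as observed in real crosses,
#: with the remainder spread over single-locus and repulsion phases.
DEFAULT_SCENARIO_MIX: Dict[str, float] = {
    "RYR/rXr": 0.50,
    "RYr/rXr": 0.15,
    "rYR/rXr": 0.15,
    "RXR/rYr": 0.10,
    "RYr/rXR": 0.10,
}


@dataclass(frozen=True)
class CrossPanelSpec:
    """Specification of a synthetic FxM cross panel.

    Family sizes follow a shifted negative binomial: 20 + NB(r, p),
    truncated above at ``family_max``, so every family passes the
    minimum-size analysis filter. The default targets a mean family of
    about 60 offspring with moderate overdispersion.
    """

    true_map: RecombinationMap = RecombinationMap(0.11, 0.26)
    scenario_mix: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SCENARIO_MIX)
    )
    n_crosses: int = 40
    family_min: int = 20
    family_mean: float = 60.0
    family_max: int = 150
    family_dispersion: float = 4.0  # negative-binomial shape r
    seed: int = 0

    def __post_init__(self) -> None:
        weights = np.array(list(self.scenario_mix.values()), dtype=float)
        if np.any(weights < 0) or weights.sum() <= 0:
            raise ValueError("scenario_mix weights must be non-negative with positive sum")
        if self.family_min < 20:
            raise ValueError("family_min must be at least 20 (analysis filter)")
        if not self.family_min <= self.family_mean <= self.family_max:
            raise ValueError("family_mean must lie within [family_min, family_max]")


def simulate_cross(
    mother: PlantGenotype,
    father: PlantGenotype,
    rmap: RecombinationMap,
    n_offspring: int,
    seed: Optional[int] = None,
    cross_id: str = "cross",
    rng: Optional[np.random.Generator] = None,
) -> CrossRecord:
    """Multinomial progeny counts from the exact cross distribution."""
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    dist = progeny_distribution(mother, father, rmap)
    counts = rng.multinomial(n_offspring, dist.as_array())
    cross_type = CrossType.FxM if father.has_y else (
        CrossType.HxH_self if mother == father else CrossType.FxH
    )
    return CrossRecord(
        cross_id=cross_id,
        cross_type=cross_type,
        n_male=int(counts[0]),
        n_sterile_male=int(counts[1]),
        n_female=int(counts[2]),
        n_hermaphrodite=int(counts[3]),
    )


def _family_sizes(spec: CrossPanelSpec, rng: np.random.Generator) -> np.ndarray:
    r = spec.family_dispersion
    mean_excess = spec.family_mean - spec.family_min
    p = r / (r + mean_excess)
    sizes = spec.family_min + rng.negative_binomial(r, p, size=spec.n_crosses)
    return np.minimum(sizes, spec.family_max)


def simulate_cross_panel(
    spec: CrossPanelSpec,
) -> Tuple[List[CrossRecord], pd.DataFrame]:
    """Generate an FxM panel and the hidden truth table of sire scenarios.

    Mothers are the canonical female; sires are drawn from the scenario
    mix (genotype strings such as ``"RYR/rXr"``, placed on the N
    cytotype). Returns ``(records, truth)`` where the truth table maps
    each cross id to its generating sire genotype and family size.
    """
    rng = np.random.default_rng(spec.seed)
    labels = list(spec.scenario_mix)
    weights = np.array([spec.scenario_mix[k] for k in labels], dtype=float)
    weights = weights / weights.sum()
    sizes = _family_sizes(spec, rng)
    picks = rng.choice(len(labels), size=spec.n_crosses, p=weights)
    records: List[CrossRecord] = []
    truth_rows = []
    for idx, (size, pick) in enumerate(zip(sizes, picks), start=1):
        label = labels[pick]
        sire = PlantGenotype.from_string(f"{label};N")
        cross_id = f"synth_{idx:03d}"
        rec = simulate_cross(
            CANONICAL_FEMALE, sire, spec.true_map, int(size),
            cross_id=cross_id, rng=rng,
        )
        records.append(rec)
        truth_rows.append(
            {"cross_id": cross_id, "sire_genotype": str(sire), "n_offspring": int(size)}
        )
    return records, pd.DataFrame(truth_rows)


#: Morph-frequency archetypes (male, sterile_male, female, hermaphrodite)
#: spanning the four sexual systems; trioecious frequencies echo the
#: strongly polymorphic southern populations.
SURVEY_ARCHETYPES: Dict[str, Tuple[float, float, float, float]] = {
    "hermaphroditic": (0.0, 0.0, 0.0, 1.0),
    "androdioecious": (0.15, 0.0, 0.0, 0.85),
    "gynodioecious": (0.0, 0.0, 0.12, 0.88),
    "trioecious": (0.15, 0.005, 0.15, 0.695),
}


@dataclass(frozen=True)
class SurveySpec:
    """Specification of a synthetic population survey.

    Population morph frequencies are taken either from the named
    archetypes (optionally jittered by a Dirichlet draw concentrated on
    the archetype) or from an explicit list of frequency vectors, e.g.
    equilibria from the deterministic simulator.
    """

    n_populations: int = 20
    archetype_mix: Dict[str, float] = field(
        default_factory=lambda: {
            "hermaphroditic": 0.33,
            "androdioecious": 0.23,
            "gynodioecious": 0.11,
            "trioecious": 0.33,
        }
    )
    explicit_frequencies: Optional[Sequence[Sequence[float]]] = None
    sample_size: int = 200
    jitter_concentration: Optional[float] = None  # Dirichlet total mass
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")
        if self.explicit_frequencies is None:
            unknown = set(self.archetype_mix) - set(SURVEY_ARCHETYPES)
            if unknown:
                raise ValueError(f"unknown archetypes: {sorted(unknown)}")
            weights = np.array(list(self.archetype_mix.values()), dtype=float)
            if np.any(weights < 0) or weights.sum() <= 0:
                raise ValueError("archetype weights must be non-negative, positive sum")


def simulate_survey(
    spec: SurveySpec,
) -> Tuple[List[PopulationRecord], pd.DataFrame]:
    """Generate survey records and their hidden truth (source frequencies).

    Counts are Multinomial(sample_size, frequencies) per population.
    """
    rng = np.random.default_rng(spec.seed)
    freq_list: List[np.ndarray] = []
    source: List[str] = []
    if spec.explicit_frequencies is not None:
        pool = [np.asarray(f, dtype=float) for f in spec.explicit_frequencies]
        for f in pool:
            if f.shape != (4,) or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-6:
                raise ValueError("explicit frequencies must be 4-simplex points")
        idx = rng.integers(0, len(pool), size=spec.n_populations)
        freq_list = [pool[i] for i in idx]
        source = [f"explicit_{i}" for i in idx]
    else:
        labels = list(spec.archetype_mix)
        weights = np.array([spec.archetype_mix[k] for k in labels], dtype=float)
        weights = weights / weights.sum()
        picks = rng.choice(len(labels), size=spec.n_populations, p=weights)
        for pick in picks:
            base = np.array(SURVEY_ARCHETYPES[labels[pick]])
            if spec.jitter_concentration is not None:
                alpha = base * spec.jitter_concentration + 1e-3
                base = rng.dirichlet(alpha)
            freq_list.append(base)
            source.append(labels[pick])

    records: List[PopulationRecord] = []
    truth_rows = []
    for idx, (freqs, src) in enumerate(zip(freq_list, source), start=1):
        counts = rng.multinomial(spec.sample_size, freqs)
        pid = f"pop_{idx:03d}"
        records.append(
            PopulationRecord(
                population_id=pid,
                n_male=int(counts[0]),
                n_sterile_male=int(counts[1]),
                n_female=int(counts[2]),
                n_hermaphrodite=int(counts[3]),
            )
        )
        truth_rows.append(
            {
                "population_id": pid,
                "source": src,
                "freq_male": freqs[0],
                "freq_sterile_male": freqs[1],
                "freq_female": freqs[2],
                "freq_hermaphrodite": freqs[3],
            }
        )
    return records, pd.DataFrame(truth_rows)
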