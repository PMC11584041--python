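"""Sexual-system classification of population surveys.

A surveyed population is labelled by its morph frequencies with a fixed
low-frequency cutoff (default 2.5%): populations with both females and
males above the cutoff are trioecious; females only, gynodioecious;
males only, androdioecious; neither, hermaphroditic. Comparisons are
strict (a frequency exactly at the cutoff is not above it).
"""

from __future__ import annotations

import enum
import math
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PopulationRecord",
    "SexualSystem",
    "SurveySummary",
    "classify_sexual_system",
    "summarize_survey",
]

#: Default minimum sample for classification (survey protocol sampled at
#: least 100 individuals per population).
DEFAULT_MIN_SAMPLE = 100

DEFAULT_CUTOFF = 0.025


class SexualSystem(str, enum.Enum):
    HERMAPHRODITIC = "hermaphroditic"
    ANDRODIOECIOUS = "androdioecious"
    GYNODIOECIOUS = "gynodioecious"
    TRIOECIOUS = "trioecious"


@dataclass(frozen=True)
class PopulationRecord:
    """Morph counts of one surveyed population."""

    population_id: str
    n_male: int
    n_sterile_male: int
    n_female: int
    n_hermaphrodite: int
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    area: Optional[float] = None  # m^2
    region: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("n_male", "n_sterile_male", "n_female", "n_hermaphrodite"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(
                    f"{self.population_id}: {name} must be a non-negative integer"
                )
            object.__setattr__(self, name, int(v))

    @property
    def total_sampled(self) -> int:
        return self.n_male + self.n_sterile_male + self.n_female + self.n_hermaphrodite

    @property
    def density(self) -> Optional[float]:
        """Plants per square metre, when the surveyed area is known."""
        if self.area is None or self.area <= 0:
            return None
        return self.total_sampled / self.area

    def frequencies(self, sterile_males_as_male: bool = True) -> Dict[str, float]:
        n = self.total_sampled
        if n == 0:
            raise ValueError(f"{self.population_id}: zero individuals sampled")
        male = self.n_male + (self.n_sterile_male if sterile_males_as_male else 0)
        return {
            "male": male / n,
            "sterile_male": self.n_sterile_male / n,
            "female": self.n_female / n,
            "hermaphrodite": self.n_hermaphrodite / n,
        }


def classify_sexual_system(
    record: PopulationRecord,
    cutoff: float = DEFAULT_CUTOFF,
    sterile_males_as_male: bool = True,
    min_sample: int = 0,
) -> SexualSystem:
    """Label a population's sexual system from its morph frequencies.

    Sterile males are counted in the male class by default (they bear
    male morphology); exclude them with ``sterile_males_as_male=False``.
    Set ``min_sample`` to enforce a minimum sample size (the survey
    design used at least 100 individuals).
    """
    if record.total_sampled < max(min_sample, 1):
        raise ValueError(
            f"{record.population_id}: sample of {record.total_sampled} is below "
            f"the required minimum ({max(min_sample, 1)})"
        )
    freqs = record.frequencies(sterile_males_as_male)
    female_above = freqs["female"] > cutoff
    male_above = freqs["male"] > cutoff
    if female_above and male_above:
        return SexualSystem.TRIOECIOUS
    if female_above:
        return SexualSystem.GYNODIOECIOUS
    if male_above:
        return SexualSystem.ANDRODIOECIOUS
    return SexualSystem.HERMAPHRODITIC


@dataclass
class SurveySummary:
    pooled_frequencies: Dict[str, float]
    system_counts: Dict[SexualSystem, int]
    populations: pd.DataFrame
    by_region: Optional[pd.DataFrame] = None


def summarize_survey(
    records: Sequence[PopulationRecord],
    cutoff: float = DEFAULT_CUTOFF,
    sterile_males_as_male: bool = True,
    min_sample: int = 0,
) -> SurveySummary:
    """Pooled morph frequencies, per-system counts, and per-population
    frequencies with De Finetti coordinates.

    Pooled frequencies are individual-weighted (counts summed over all
    populations before dividing). Regional aggregates are produced when
    records carry a ``region``.
    """
    if not records:
        raise ValueError("at least one population record is required")
    pooled = np.zeros(4)
    rows = []
    counts: Counter = Counter({s: 0 for s in SexualSystem})
    for rec in records:
        pooled += [rec.n_male, rec.n_sterile_male, rec.n_female, rec.n_hermaphrodite]
        label = classify_sexual_system(rec, cutoff, sterile_males_as_male, min_sample)
        counts[label] += 1
        freqs = rec.frequencies(sterile_males_as_male)
        f, m, h = freqs["female"], freqs["male"], freqs["hermaphrodite"]
        tot = f + m + h
        x = y = math.nan
        if tot > 0:
            x = (h + m / 2.0) / tot
            y = math.sqrt(3.0) / 2.0 * m / tot
        rows.append(
            {
                "population_id": rec.population_id,
                "total_sampled": rec.total_sampled,
                "freq_male": freqs["male"],
                "freq_sterile_male": freqs["sterile_male"],
                "freq_female": freqs["female"],
                "freq_hermaphrodite": freqs["hermaphrodite"],
                "system": label.value,
                "ternary_x": x,
                "ternary_y": y,
                "region": rec.region,
                "density": rec.density,
            }
        )
    pooled_total = pooled.sum()
    pooled_freqs = {
        "male": pooled[0] / pooled_total,
        "sterile_male": pooled[1] / pooled_total,
        "female": pooled[2] / pooled_total,
        "hermaphrodite": pooled[3] / pooled_total,
    }
    table = pd.DataFrame(rows)
    by_region = None
    if table["region"].notna().any():
        by_region = (
            table.groupby("region", dropna=True)
            .agg(
                n_populations=("population_id", "size"),
                mean_freq_female=("freq_female", "mean"),
                mean_freq_male=("freq_male", "mean"),
                mean_freq_hermaphrodite=("freq_hermaphrodite", "mean"),
            )
            .reset_index()
        )
    return SurveySummary(
        pooled_frequencies=pooled_freqs,
        system_counts=dict(counts),
        populations=table,
        by_region=by_region,
    )
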