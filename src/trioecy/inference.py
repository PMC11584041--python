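"""Goodness-of-fit testing of cross progeny and recombination-map fitting.

Observed progeny counts are compared to model expectations with a χ²
goodness-of-fit statistic or an exact/Monte-Carlo multinomial
log-likelihood-ratio (LLR) test. The two interval recombination
fractions of the linked three-locus map are fitted by a grid search:
at each (r12, r23) on a regular grid every candidate sire scenario is
scored against every cross, each cross contributes its best-fitting
scenario's LLR (a profile likelihood over the discrete nuisance
scenarios), and the per-cross scores are combined into a single
criterion C_LLR whose grid maximum is the estimate.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .crosses import (
    CANONICAL_FEMALE,
    CrossType,
    PHENOTYPE_ORDER,
    PhenotypeDistribution,
    SireScenario,
    enumerate_sire_scenarios,
)
from .genetics import RecombinationMap, SegregationMode

__all__ = [
    "CrossRecord",
    "ScenarioFit",
    "MapFitResult",
    "chisq_gof",
    "multinomial_llr",
    "multinomial_llr_test",
    "acceptance_region",
    "bonferroni_alpha",
    "effective_recombination",
    "fit_recombination_map",
]

logger = logging.getLogger(__name__)

#: Minimum family size for a cross to enter the analyses.
MIN_FAMILY_SIZE = 20

#: Refuse exhaustive multinomial enumeration above this many outcomes.
EXHAUSTIVE_OUTCOME_GUARD = 2_000_000


@dataclass(frozen=True)
class CrossRecord:
    """Observed progeny counts of one cross family.

    Counts follow the phenotype order (male, sterile_male, female,
    hermaphrodite).
    """

    cross_id: str
    cross_type: CrossType
    n_male: int
    n_sterile_male: int
    n_female: int
    n_hermaphrodite: int
    mother_id: str = ""
    father_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "cross_type", CrossType(self.cross_type))
        for name in ("n_male", "n_sterile_male", "n_female", "n_hermaphrodite"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{self.cross_id}: {name} must be a non-negative integer")
            object.__setattr__(self, name, int(v))

    @property
    def counts(self) -> np.ndarray:
        return np.array(
            [self.n_male, self.n_sterile_male, self.n_female, self.n_hermaphrodite]
        )

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def eligible(self, min_n: int = MIN_FAMILY_SIZE) -> bool:
        return self.n >= min_n


@dataclass
class ScenarioFit:
    """Fit of one candidate sire scenario to one cross."""

    scenario: SireScenario
    expected: PhenotypeDistribution
    llr: float
    p_value: Optional[float] = None


@dataclass
class MapFitResult:
    """Result of the recombination-map grid search."""

    best_r12: float
    best_r23: float
    c_llr: float
    weight_mode: str
    r12_grid: np.ndarray
    r23_grid: np.ndarray
    c_llr_surface: np.ndarray  # shape (len(r12_grid), len(r23_grid))
    per_cross_best: Dict[str, ScenarioFit] = field(default_factory=dict)

    @property
    def best_map(self) -> RecombinationMap:
        return RecombinationMap(self.best_r12, self.best_r23)


def chisq_gof(
    counts: Sequence[int], expected_probs: Sequence[float]
) -> Tuple[float, int]:
    """Pearson χ² goodness-of-fit statistic against fixed class probabilities.

    Returns ``(chi2, df)`` with df = (number of positive-probability
    classes) − 1. An observation in a zero-probability class yields an
    infinite statistic (the model is impossible).
    """
    m = np.asarray(counts, dtype=float)
    p = np.asarray(expected_probs, dtype=float)
    if m.shape != p.shape or m.size < 2:
        raise ValueError("counts and expected_probs must have equal length >= 2")
    if np.any(m < 0) or np.any(p < 0):
        raise ValueError("counts and probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("expected probabilities must sum to 1")
    n = m.sum()
    if n < 1:
        raise ValueError("total count must be at least 1")
    pos = p > 0
    df = int(pos.sum()) - 1
    if np.any(m[~pos] > 0):
        return math.inf, df
    e = n * p[pos]
    chi2 = float(np.sum((m[pos] - e) ** 2 / e))
    return chi2, df


def multinomial_llr(counts: Sequence[int], expected_probs: Sequence[float]) -> float:
    """Log-likelihood ratio Σ_i m_i ln(n p_i / m_i), with 0·ln(·) = 0.

    Always ≤ 0, equal to 0 iff m_i = n p_i for all i; −inf when a
    zero-probability class was observed.
    """
    m = np.asarray(counts, dtype=float)
    p = np.asarray(expected_probs, dtype=float)
    n = m.sum()
    if np.any((p == 0) & (m > 0)):
        return -math.inf
    obs = m > 0
    return float(np.sum(m[obs] * np.log(n * p[obs] / m[obs])))


def _compositions(n: int, k: int) -> np.ndarray:
    """All length-k non-negative integer vectors summing to n (array rows)."""
    if k == 1:
        return np.array([[n]])
    rows = []
    for first in range(n + 1):
        rest = _compositions(n - first, k - 1)
        rows.append(
            np.column_stack([np.full(len(rest), first, dtype=int), rest])
        )
    return np.concatenate(rows)


def multinomial_llr_test(
    counts: Sequence[int],
    expected_probs: Sequence[float],
    method: str = "exhaustive",
    n_resample: int = 100_000,
    seed: Optional[int] = None,
    max_outcomes: int = EXHAUSTIVE_OUTCOME_GUARD,
) -> Tuple[float, float]:
    """Multinomial goodness-of-fit test on the log-likelihood ratio.

    Returns ``(llr, p_value)`` where the p-value is the probability,
    under Multinomial(n, p), of an outcome with LLR ≤ the observed LLR
    (outcomes at least as extreme). ``exhaustive`` enumerates every
    outcome exactly and is refused above ``max_outcomes``;
    ``montecarlo`` estimates the tail from ``n_resample`` multinomial
    draws and requires a seed for reproducibility.
    """
    m = np.asarray(counts, dtype=int)
    p = np.asarray(expected_probs, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("expected probabilities must sum to 1")
    n = int(m.sum())
    llr_obs = multinomial_llr(m, p)
    if llr_obs == -math.inf:
        return llr_obs, 0.0
    # restrict to positive-probability classes (zero classes have m=0 here)
    pos = p > 0
    p_pos = p[pos] / p[pos].sum()
    k = int(pos.sum())
    # tolerance for tie inclusion: outcomes with llr within rounding of
    # the observed value count as "at least as extreme"
    tol = 1e-9 * (1.0 + abs(llr_obs))

    if method == "exhaustive":
        n_outcomes = math.comb(n + k - 1, k - 1)
        if n_outcomes > max_outcomes:
            raise ValueError(
                f"exhaustive enumeration of {n_outcomes} outcomes exceeds the "
                f"guard ({max_outcomes}); use method='montecarlo'"
            )
        outcomes = _compositions(n, k)
        logpmf = stats.multinomial.logpmf(outcomes, n, p_pos)
        llrs = _llr_matrix(outcomes, n, p_pos)
        p_value = float(np.exp(logpmf[llrs <= llr_obs + tol]).sum())
        return llr_obs, min(p_value, 1.0)
    if method == "montecarlo":
        if n_resample < 1:
            raise ValueError("n_resample must be >= 1")
        rng = np.random.default_rng(seed)
        draws = rng.multinomial(n, p_pos, size=n_resample)
        llrs = _llr_matrix(draws, n, p_pos)
        p_value = float(np.mean(llrs <= llr_obs + tol))
        return llr_obs, p_value
    raise ValueError(f"unknown method {method!r}")


def _llr_matrix(counts: np.ndarray, n: int, p: np.ndarray) -> np.ndarray:
    """Vectorised LLR for an array of count rows against probabilities p."""
    m = counts.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = m * np.log(n * p[None, :] / m)
    terms[m == 0] = 0.0
    return terms.sum(axis=1)


def bonferroni_alpha(alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected significance level alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def acceptance_region(
    p0: float,
    n: int,
    alpha: float = 0.05,
    n_tests: int = 1,
    method: str = "chisq",
) -> Tuple[float, float]:
    """Bounds on the observed proportion that would NOT be rejected.

    ``chisq`` gives the analytical band p0 ± sqrt(χ²_crit(1) · p0(1−p0)/n)
    at the Bonferroni-corrected level; ``exact_binomial`` searches counts
    0..n for the smallest and largest proportions whose two-sided exact
    binomial test p-value is ≥ the corrected level (a stepwise band at
    integer/n positions).
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie strictly in (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    alpha_c = bonferroni_alpha(alpha, n_tests)
    if method == "chisq":
        crit = stats.chi2.ppf(1.0 - alpha_c, df=1)
        half = math.sqrt(crit * p0 * (1.0 - p0) / n)
        return max(0.0, p0 - half), min(1.0, p0 + half)
    if method == "exact_binomial":
        accepted = [
            k for k in range(n + 1)
            if stats.binomtest(k, n, p0).pvalue >= alpha_c
        ]
        if not accepted:  # pathological tiny n
            return p0, p0
        return accepted[0] / n, accepted[-1] / n
    raise ValueError(f"unknown method {method!r}")


def effective_recombination(rmap: RecombinationMap) -> float:
    """Recombination fraction between the two outer loci R1 and R2.

    With the sex-determining locus between them and double crossovers
    ignored, a gamete is R1–R2 recombinant after a crossover in either
    interval, so the fraction is r12 + r23 (capped at 1/2, the free
    recombination maximum). Under independent segregation the loci are
    unlinked and the fraction is 1/2 trivially.
    """
    if rmap.mode is SegregationMode.INDEPENDENT:
        return 0.5
    total = rmap.r12 + rmap.r23
    if total > 0.5:
        warnings.warn(
            f"r12 + r23 = {total:.3f} exceeds 0.5; capping the R1-R2 "
            "recombination fraction at 0.5",
            stacklevel=2,
        )
        return 0.5
    return total


_WEIGHT_MODES = ("sum", "n_weighted", "mean")


def fit_recombination_map(
    crosses: Sequence[CrossRecord],
    grid_step: float = 0.01,
    weight_mode: str = "sum",
    min_family_size: int = MIN_FAMILY_SIZE,
    exclude: Iterable[str] = (),
) -> MapFitResult:
    """Grid-search fit of (r12, r23) to FxM cross data by combined LLR.

    For each grid point the distinct sire scenarios are enumerated, each
    cross is scored by its best-fitting scenario's LLR, and the scores
    are combined per ``weight_mode``: ``sum`` adds the per-cross LLRs
    (family size already enters through the counts), ``n_weighted``
    multiplies each cross's LLR by its family size before adding, and
    ``mean`` divides by family size. The grid includes both endpoints
    0.0 and 0.5 in each interval; ties are broken toward smaller
    (r12, r23) lexicographically.
    """
    if weight_mode not in _WEIGHT_MODES:
        raise ValueError(f"weight_mode must be one of {_WEIGHT_MODES}")
    exclude = set(exclude)
    kept = [
        c for c in crosses
        if c.cross_id not in exclude and c.eligible(min_family_size)
    ]
    if not kept:
        raise ValueError("no eligible crosses to fit")
    bad = [c.cross_id for c in kept if c.cross_type is not CrossType.FxM]
    if bad:
        raise ValueError(f"map fitting requires FxM crosses; offending: {bad}")

    counts = np.array([c.counts for c in kept], dtype=float)  # (J, 4)
    totals = counts.sum(axis=1)  # (J,)
    # per-cross constant A_j = sum_i m_ji (ln n_j - ln m_ji)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_terms = counts * (np.log(totals)[:, None] - np.log(counts))
    a_terms[counts == 0] = 0.0
    a_const = a_terms.sum(axis=1)  # (J,)
    if weight_mode == "sum":
        weights = np.ones_like(totals)
    elif weight_mode == "n_weighted":
        weights = totals
    else:
        weights = 1.0 / totals

    n_steps = int(round(0.5 / grid_step))
    grid = np.linspace(0.0, 0.5, n_steps + 1)
    surface = np.full((grid.size, grid.size), -np.inf)

    best = (-math.inf, 0.0, 0.0)
    for i, r12 in enumerate(grid):
        for j, r23 in enumerate(grid):
            rmap = RecombinationMap(float(r12), float(r23))
            scen = enumerate_sire_scenarios(CrossType.FxM, rmap)
            probs = np.array([d.as_array() for _, d in scen])  # (S, 4)
            with np.errstate(divide="ignore"):
                logp = np.log(probs)
            logp[probs == 0.0] = -1e30  # impossible class => huge penalty
            llr_js = a_const[:, None] + counts @ logp.T  # (J, S)
            per_cross = llr_js.max(axis=1)
            c_llr = float(np.sum(weights * per_cross))
            surface[i, j] = c_llr
            if c_llr > best[0]:
                best = (c_llr, float(r12), float(r23))

    c_llr, best_r12, best_r23 = best
    # per-cross best scenarios at the optimum
    best_map = RecombinationMap(best_r12, best_r23)
    scen = enumerate_sire_scenarios(CrossType.FxM, best_map)
    per_cross_best: Dict[str, ScenarioFit] = {}
    for c in kept:
        fits = [
            ScenarioFit(s, d, multinomial_llr(c.counts, d.as_array()))
            for s, d in scen
        ]
        per_cross_best[c.cross_id] = max(fits, key=lambda f: f.llr)

    return MapFitResult(
        best_r12=best_r12,
        best_r23=best_r23,
        c_llr=c_llr,
        weight_mode=weight_mode,
        r12_grid=grid,
        r23_grid=grid,
        c_llr_surface=surface,
        per_cross_best=per_cross_best,
    )
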