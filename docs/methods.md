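# Methods

## The genetic model

The package models sex determination in a wind-pollinated annual plant
whose populations contain up to four sexual morphs: fertile males,
sterile males, females (male-sterile monoecious plants), and fertile
hermaphrodites. Three linked nuclear loci sit on a sex chromosome in
the order R1 – SDL – R2:

* **SDL** — the sex-determining locus, with a dominant
  male-determining allele Y and the alternative X. Y carriers develop
  male inflorescence architecture.
* **R1, R2** — two redundant male-fertility restorer loci, each
  segregating a dominant restorer R and a recessive non-restorer r.

A fourth, maternally inherited factor is the **cytotype**: S (a
cytoplasmic male-sterility mutation) or N (normal). A plant on the S
cytoplasm produces pollen only if it carries at least one R allele at
R1 or R2 (restoration is dominant and either locus suffices); on N no
restoration is needed. Phenotype is therefore a total function of
genotype: Y plus fertility gives a male, Y without fertility a sterile
male, no Y plus fertility a hermaphrodite, no Y without fertility a
female. Inheritance is disomic (the hexaploid genome pairs and
segregates like a diploid for these loci), so ordinary Mendelian
algebra applies.

Meiosis has two modes. Under **free recombination** each locus
transmits an allele from either homolog with probability 1/2,
independently — the correct limit for unlinked loci and the mode used
for the classical one- and two-locus segregation hypotheses. Under the
**linked map** a gamete results from exactly one of three mutually
exclusive events: no crossover (probability 1 − r12 − r23), a
crossover in the R1–SDL interval (r12), or a crossover in the SDL–R2
interval (r23); double crossovers are ignored. The two modes are kept
distinct because they do not nest: at r12 = r23 = 0.5 the three-event
model assigns zero probability to parental gametes, which is not
independent assortment. A corollary of ignoring double crossovers is
that the R1–R2 recombination fraction is simply r12 + r23 (0.37 at the
fitted map (0.11, 0.26)), capped at the free-recombination maximum of
1/2.

## Cross expectations and scenario enumeration

Expected progeny distributions are exact convolutions: maternal gamete
distribution × paternal gamete distribution, offspring cytotype set to
the mother's, each zygote classified. The canonical female mother is
`rXr/rXr;S` — under this model a female must lack both the Y and every
restorer allele, so all female parents are genetically identical at
these loci.

For a female × male cross the sire's unknown quantity is the *phase*
of restorer alleles across his Y and X homologs; for a female ×
hermaphrodite cross, across his two X homologs. The package enumerates
every phase configuration (16 for males, 10 unordered for
hermaphrodites), keeps those whose carrier would actually be
pollen-fertile on the sterility cytoplasm, and collapses
configurations with identical progeny distributions (tolerance 1e−12,
far below any distinction among exact rationals). At a generic linked
map this yields 9 distinct male-sire scenarios; the set is derived
computationally rather than hard-coded, so it adapts to degenerate
maps (complete linkage collapses it to 3).

## Goodness of fit and map fitting

Observed progeny counts are tested against fixed class probabilities
with either the Pearson χ² statistic (df = positive-probability
classes − 1) or the multinomial log-likelihood ratio
Σᵢ mᵢ ln(n pᵢ / mᵢ) (≤ 0, zero only at a perfect fit, with 0·ln(·) = 0).
The LLR test's p-value is the probability mass of outcomes with LLR ≤
the observed value, computed either by exhaustive enumeration of all
multinomial outcomes (refused above 2 × 10⁶ outcomes) or by seeded
Monte-Carlo resampling. Ties at the observed LLR are included using a
relative tolerance of 1e−9, so the least extreme outcome has p = 1
exactly. Acceptance-region curves for a binomial proportion come in
the analytical form p0 ± sqrt(χ²crit(1, α/k) p0(1−p0)/n) and as exact
stepwise bounds from the two-sided exact binomial test at the
Bonferroni-corrected level.

The interval rates (r12, r23) are fitted by grid search on the
inclusive 51 × 51 grid over [0, 0.5]² at step 0.01. At each grid point
every cross is scored by the LLR of its *best-fitting* sire scenario —
a profile likelihood over the discrete nuisance phase — and the
per-cross scores are combined into the criterion C_LLR. The published
weighting of this combination is ambiguous in its typeset form, so
three conventions are selectable: `sum` (default; family size already
enters through the counts), `n_weighted` (each cross's LLR multiplied
by its family size), and `mean` (divided by family size). All three
are reported by the acceptance script; the fitted grid point is
essentially insensitive to the choice on synthetic panels. Grid ties
break toward smaller (r12, r23) lexicographically.

## The deterministic recursion

The simulator iterates genotype frequencies of an infinite population
over the full state space of 36 unordered haplotype pairs × 2
cytotypes = 72 genotypes. (A 64-state bookkeeping is sometimes quoted
for this architecture; 72 unordered phase-resolved states is the
minimal representation that is sufficient under linkage, and it
subsumes any 64-state reduction.) Per generation:

1. **Pollen pool** — each genotype contributes frequency × pollen
   output × its gamete distribution. Pollen output is
   `male_pollen_advantage` (dimensionless ratio, default 12) for
   males, 1 for hermaphrodites, 0 for females and sterile males.
2. **Ovule output** — `female_seed_advantage` (default 1.05) for
   females, 1 for hermaphrodites, 0 otherwise.
3. **Mating** — hermaphrodites self a fixed fraction *s* of their
   ovules using their own gamete distribution (selfing with
   recombination, not genotype copying); selfed zygotes are weighted
   by 1 − *d* (inbreeding depression). Females, and the remaining
   hermaphrodite ovules, outcross to the normalised population pollen
   pool. Pollen is not depleted by selfing (wind pollination; pollen
   is not limiting in the model).
4. **Transmission** — offspring cytotype equals the mother's; zygote
   frequencies are renormalised. The pairing and unordered-pair
   collapse conserve ovule mass to machine precision, which is checked
   every generation.

The restoration cost ρ multiplies both pollen and seed output by
(1 − ρ) per restorer locus carrying at least one R allele, combined
multiplicatively across loci (a per-allele variant is available).
**The cost is charged regardless of cytoplasm by default.** This is a
deliberate modelling choice: if the cost is expressed only on the S
cytoplasm, restorers are neutral on N while restored S plants pay it,
so the S cytoplasm has lower mean fitness than N from essentially any
starting composition and is purged — females are lost for *every*
cost, and the model cannot maintain trioecy at all. With the
unconditional cost, restorers are selected against whenever S is rare,
which is precisely the balancing ingredient that lets cytotype,
restorers, and all three main morphs persist jointly; the equilibrium
is then also independent of the starting frequencies in all cases
examined. The S-only convention remains available via
`cost_on_normal_cytotype=False`.

Convergence is declared when none of the four tracked allele
frequencies (R at R1, Y, R at R2, cytotype S) changes by more than
1e−6 over a trailing window of 20 generations; the generation cap
defaults to 50 000 (the slowest cases are the ρ = 0 runs, where the
recessive non-restorer decays algebraically). The closed-form check
used in the tests: with no S cytoplasm and no selfing, the male
frequency recursion is m′ = (M m/2)/(M m + 1 − m), whose nontrivial
fixed point is m* = (M/2 − 1)/(M − 1) — 5/11 at M = 12, and 0 at the
classical twofold-pollen threshold M = 2.

### Expected equilibrium behaviour across the parameter box

Across ρ ∈ [0.15, 0.4], s ∈ [0.3, 1.0], d ∈ [0.1, 0.5], M = 12 and
female seed advantage 1.05, equilibria at low inbreeding depression
(d ≈ 0.1) hold hermaphrodites above 60% with males below 40%, females
below 40% and sterile males below 1%. At d = 0.5 and s ≥ 0.3 this is
not attainable in this class of model: the hermaphrodite's effective
ovule success is 1 − s·d ≤ 0.85 (0.5 at full selfing), giving females
an effective seed advantage of 1.05/(1 − s·d) ≈ 1.2–2.1, and the
equilibria correspondingly carry 14–40% females, 2–5% sterile males
and hermaphrodite frequencies down to ~0.17. The corresponding
acceptance test asserts the narrow ranges over the whole box and is
expected to fail for the high-d cells; the failure is a property of
the parameter box, not of the recursion (all other fixed-point and
conservation checks pass to 1e−4 or better).

## Survey classification

A population is labelled from its morph frequencies with a strict 2.5%
cutoff: trioecious if both females and males exceed it, gynodioecious
/ androdioecious if only one does, hermaphroditic otherwise. Sterile
males are counted in the male-frequency numerator by default (they
bear male morphology and are male by any field scoring); a flag
excludes them, and since their observed frequency is near zero the
choice rarely changes a label. Pooled frequencies are
individual-weighted. De Finetti coordinates over the renormalised
(female, male, hermaphrodite) triple are x = h + m/2,
y = (√3/2)·m.

## Synthetic data

The cross-panel generator draws, per cross: a sire scenario from a mix
of phase configurations, a family size from a shifted negative
binomial 20 + NB(r = 4, mean 40) truncated at 150 (mean ≈ 60,
matching the analysed families, all of which passed a ≥ 20 offspring
filter), and progeny counts from Multinomial(n, exact distribution) at
the true map. The default scenario mix puts half the weight on the
coupling configuration (both restorers on the Y), mirroring its
predominance among real crosses, and spreads the rest over
single-locus and repulsion phases — the single-locus sires are what
makes the two interval rates separately identifiable (a coupling sire
informs only their sum). The generating scenario of each cross is
returned in a separate truth table so recovery experiments cannot leak
it into fitting.

The survey generator draws multinomial morph counts at n = 200 from
archetype frequency vectors for the four sexual systems (optionally
Dirichlet-jittered, or replaced by simulator equilibria). What the
generators do **not** emulate: genotyping or scoring error, pollen
contamination between crosses, family structure among sires, spatial
autocorrelation among populations, or density-dependent selfing — so
green tests demonstrate correctness of the inference machinery under
the model's own assumptions, not robustness to those field
complications.

## Problem sizes

The shipped tests and acceptance script use: 40-cross panels of mean
family 60 for map recovery (full 51 × 51 grid, a few seconds); 12
equilibrium runs for the reduced parameter grid and single runs for
the fixed-point checks (28–50 000 generations each, sub-second to a
few seconds); exhaustive multinomial enumeration up to a few thousand
outcomes; and 400–1000 replicate populations for classification
recovery. These sizes were chosen as the smallest that make the
statistical assertions sharp (3-standard-error bounds, ±0.05 recovery,
95% label recovery).

## Known limitations

* Finite-population stochasticity, metapopulation/colonisation
  dynamics and pollen limitation are out of scope; the recursion is
  strictly deterministic and infinite-population.
* Confidence intervals on (r12, r23) are not computed (the fit is a
  point estimate on a grid).
* YY genotypes are representable but flagged and never produced by
  model crosses (mothers never carry Y).
* The equilibrium uniqueness check is local (two interior starts), not
  a global stability analysis.
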