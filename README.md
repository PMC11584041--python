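# trioecy

Population-genetic toolkit for **trioecy under cytoplasmic male
sterility (CMS) with XY sex determination** — the sexual system in
which males, females and hermaphrodites coexist as discrete morphs, as
found in hexaploid Iberian populations of the annual herb *Mercurialis
annua*.

The package is for researchers analysing controlled-cross and
population-survey data under this genetic architecture. It provides:

* **`trioecy.genetics`** — the three-locus sex chromosome
  (restorer R1 — sex-determining locus — restorer R2) plus maternally
  inherited cytotype (S = sterility cytoplasm, N = normal); phenotype
  classification and exact gamete distributions under free
  recombination or a linked map with double crossovers ignored.
* **`trioecy.crosses`** — exact progeny phenotype distributions for
  female × male, female × hermaphrodite and selfed-hermaphrodite
  crosses, the classical one-/two-locus segregation hypotheses
  (1:1:2 and 1:3:4 female : hermaphrodite : Y-carrier ratios), and
  enumeration of the distinct sire phase scenarios.
* **`trioecy.inference`** — χ² and exact/Monte-Carlo multinomial
  log-likelihood-ratio goodness-of-fit tests, Bonferroni-corrected
  acceptance regions, and grid-search fitting of the two interval
  recombination rates by combined LLR (C_LLR) with
  best-scenario-per-cross profiling.
* **`trioecy.equilibrium`** — deterministic infinite-population
  recursion over all 72 genotype states with selfing, inbreeding
  depression, restoration cost and morph-specific fitness; equilibrium
  detection and parameter sweeps with De Finetti (ternary)
  coordinates.
* **`trioecy.survey`** — sexual-system classification of surveyed
  populations (strict 2.5% morph-frequency cutoff) and survey
  summaries.
* **`trioecy.synthetic`** — seeded generators for cross panels and
  surveys with the exact statistical structure the analyses assume.
* **`trioecy.io` / `trioecy.cli`** — TSV/CSV table readers and
  writers, YAML/JSON configs, and a `trioecy` command with
  subcommands `fit-map`, `test-cross`, `equilibrate`, `sweep`,
  `classify-survey`, `simulate-crosses`, `simulate-survey`.

## The model in brief

A plant's phenotype is determined by its genotype at three linked loci
and its cytoplasm. Y is dominant male-determining. On the sterility
cytoplasm S, pollen production requires a dominant restorer allele R
at either of two redundant loci flanking the sex-determining locus:

| Y present | fertile (N, or S restored) | phenotype      |
|-----------|----------------------------|----------------|
| yes       | yes                        | male           |
| yes       | no                         | sterile male   |
| no        | yes                        | hermaphrodite  |
| no        | no                         | female         |

Gametes from the linked map (r12, r23) arise from one of three
mutually exclusive meiotic events (no crossover, interval-1 crossover,
interval-2 crossover), so the R1–R2 recombination fraction is
r12 + r23. Cross expectations are exact convolutions of parental
gamete distributions with maternal cytotype transmission. The
recombination rates are fitted by maximising
C_LLR = Σⱼ maxₛ Σᵢ mᵢⱼ ln(nⱼ pᵢₛ / mᵢⱼ) over a 0.01-step grid, where
the inner maximum profiles over the discrete sire phase scenarios *s*.

## Worked example

```python
>>> import trioecy as t

>>> # A female (rXr/rXr;S) crossed to a male carrying both restorers on
>>> # the Y, under the fitted map r12=0.11, r23=0.26:
>>> sire = t.PlantGenotype.from_string("RYR/rXr;N")
>>> t.progeny_distribution(t.CANONICAL_FEMALE, sire, t.FITTED_MAP)
PhenotypeDistribution(p_male=0.5, p_sterile_male=0.0, p_female=0.315, p_hermaphrodite=0.185)
```

Half the progeny carry the Y and are male (every Y gamete from this
sire carries at least one restorer); 31.5% inherit the unrecombined
restorer-free X and are female; the remaining 18.5% are recombinant
restored hermaphrodites. The implied R1–R2 recombination fraction:

```python
>>> t.effective_recombination(t.FITTED_MAP)
0.37
```

Fitting the map back from a synthetic panel generated at that truth:

```python
>>> panel, truth = t.simulate_cross_panel(t.CrossPanelSpec(seed=1))
>>> fit = t.fit_recombination_map(panel)
>>> (fit.best_r12, fit.best_r23)
(0.1, 0.26)
```

And a deterministic equilibrium with a restoration cost, showing a
maintained trioecious population:

```python
>>> params = t.FitnessParams(male_pollen_advantage=12, female_seed_advantage=1.05,
...                          selfing_rate=0.6, inbreeding_depression=0.5,
...                          restoration_cost=0.15)
>>> res = t.run_to_equilibrium(params)
>>> {k.value: round(v, 4) for k, v in res.phenotype_frequencies.items()}
{'male': 0.2822, 'sterile_male': 0.0195, 'female': 0.1423, 'hermaphrodite': 0.556}
```

Males, females and hermaphrodites all persist; without the cost
(`restoration_cost=0`) the restorers sweep and the female frequency
collapses below 1e−4.

See `docs/methods.md` for the model's assumptions, parameter
conventions (notably how the restoration cost is charged), numerical
choices, and limitations.

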