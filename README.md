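# gorillakin

Microsatellite kinship, parentage, and dispersal analysis for one-male
polygynous primate populations — built around the study design used for wild
western gorillas (*Gorilla gorilla*): a handful of habituated breeding groups
(one silverback, several adult females, their immatures) plus solitary males,
genotyped at ~10 autosomal microsatellite loci, spread across two regions tens
of kilometres apart, with behavioural proximity scans on the females.

The package answers the questions such a study asks:

* **Who is related to whom?**  Pairwise relatedness with the
  Queller–Goodnight (QG) and Lynch–Ritland (LR) method-of-moments estimators
  and the Loiselle kinship coefficient, with per-pair significance from
  allele-reshuffling permutations.  For reference individual *x* with alleles
  *a, b* against *y* with alleles *c, d*, QG accumulates per locus
  ½(δ<sub>ac</sub>+δ<sub>ad</sub>+δ<sub>bc</sub>+δ<sub>bd</sub>) − p<sub>a</sub> − p<sub>b</sub>
  over 1 + δ<sub>ab</sub> − p<sub>a</sub> − p<sub>b</sub>, multilocus as
  ratio of sums, symmetrised over the two reference orientations.
* **Who are the parents?**  Likelihood-based parentage: natural-log LOD
  scores under a genotyping-error model (a recorded genotype is an
  independent Hardy–Weinberg draw with probability *e*), joint parent-pair
  search with single-parent fallback, and confidence classes from the
  simulated Δ = LOD(top) − LOD(second) threshold procedure.  Pairwise
  relationship likelihood ratios (parent–offspring, full sib, half sib vs
  unrelated) via IBD-coefficient mixtures, significant above a ratio of 10.
* **Is there kin structure?**  Permutation tests: within-group mean
  relatedness against group-membership reshuffles, female-to-own-silverback
  relatedness against random male draws, and within-region tests by sex.
* **Is there spatial structure?**  R<sub>ST</sub> (allele-size variance
  components, the microsatellite analogue of F<sub>ST</sub>) with
  individual-permutation significance, and isolation by distance:
  R<sub>ST</sub>/(1−R<sub>ST</sub>) regressed on ln(km) with a
  location-permutation (Mantel-type) test.
* **Does kinship shape behaviour?**  Dyadic proximity indices (scans < 10 m
  per focal hour) correlated with relatedness by Spearman rank.

A forward simulator (`gorillakin.simdata`) generates the whole study system
with known truth — pedigrees, dispersal histories, stepwise-mutation
genotypes, typing error, proximity scans — so every estimator and test is
validated against ground truth.

## Worked example

The numbered scripts under `analysis/` run the full chain on the synthetic
study system (outputs land in `results/`):

```bash
python analysis/01_simulate_study_system.py --seed 0
python analysis/02_genetic_diversity.py
python analysis/03_relatedness_concordance.py
python analysis/04_parentage_assignment.py
python analysis/05_kin_structure_tests.py
python analysis/06_spatial_structure.py
python analysis/07_proximity_correlation.py
```

With seed 0 this prints, among other things:

```
mean alleles/locus 4.80, mean He 0.605, multilocus PID 6.318e-08

estimator_a estimator_b        r             p  n_pairs
         QG          LR 0.885797  2.396287e-93      276
         QG    LOISELLE 0.940084 4.616416e-130      276
         LR    LOISELLE 0.896122  1.151178e-98      276

32 immatures; 27 confident parent calls
confident calls matching the true pedigree: 27/27
extragroup paternities among confident calls: 4/4 recovered

Spearman rho = 0.134, p = 0.533, N = 24 within-group female dyads
```

Reading this: the three relatedness estimators agree strongly (Pearson r
0.89–0.94 over the 276 adult pairs), every confident parentage call matches
the true pedigree including the simulated extragroup sirings, and — as built
into the generator — female spatial proximity carries no kinship signal (the
Spearman correlation is small and non-significant).  The multilocus
probability of identity (~10⁻⁸) says the panel distinguishes individuals
essentially perfectly.

The same pipeline is scriptable end to end (`gorillakin pipeline config.yaml`)
or piecewise from the shell (`gorillakin simulate`, `gorillakin summarize`,
`gorillakin relatedness`); every run logs its seed and config hash and is
bit-reproducible.

## Layout

```
src/gorillakin/      the library: genodata, relatedness, parentage,
                     kin_structure, spatial, proximity, simdata, pipeline, cli
analysis/            numbered narrative drivers over the library
tests/               pytest suite (unit, property, whole-chain validation)
scripts/acceptance.py
docs/methods.md      models, assumptions, parameter choices, limitations
```
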