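# Methods

This note documents the statistical models implemented in `gorillakin`, the
design choices made where several defensible options existed, what the
synthetic-data generator does and does not emulate, and the numerical
conventions that matter for reproducing results.

## Genotype model and diversity summaries

Genotypes are unordered pairs of positive integer allele sizes at codominant
microsatellite loci; a locus either typed (two alleles, homozygotes repeated)
or missing.  Individuals carry sex, age class, social role (silverback, adult
female, immature, solitary male), group, and country.  The quality filter
keeps individuals typed at ≥ `min_valid_loci` loci (default 7 of a 10-locus
panel, i.e. "more than six").

Allele frequencies are observed counts over a reference subset, by default
all successfully typed individuals; an `reference_filter` predicate allows
e.g. adults-only references, since a sample heavy in offspring over-weights
parental alleles.  Expected heterozygosity defaults to Nei's unbiased form
*n*/(*n*−1)·(1−Σp²) with *n* the number of typed genes; the raw Gini–Simpson
form is selectable.  The probability of identity per locus is
Σᵢpᵢ⁴ + Σᵢ<ⱼ(2pᵢpⱼ)², multiplied across loci.

## Relatedness estimators

Three estimators over a shared frequency reference:

* **QG** (Queller–Goodnight): per-locus numerator
  ½(δ_ac+δ_ad+δ_bc+δ_bd) − p_a − p_b and denominator 1 + δ_ab − p_a − p_b for
  the reference orientation; multilocus value is the ratio of summed
  numerators to summed denominators (never a mean of per-locus ratios, which
  is unstable at near-zero denominators), then averaged over the two
  reference orientations so that value(x,y) = value(y,x) exactly.
* **LR** (Lynch–Ritland): locus estimate
  [p_a(δ_bc+δ_bd)+p_b(δ_ac+δ_ad)−4p_ap_b] / [(1+δ_ab)(p_a+p_b)−4p_ap_b]
  combined with the Lynch–Ritland locus weights (weight = locus denominator /
  2p_ap_b, so the multilocus value is again a ratio of sums), symmetrised the
  same way.
* **Loiselle** kinship: Σ_l Σ_a [(x_ia−p_a)(x_ja−p_a) + p_a(1−p_a)/(n_l−1)]
  over Σ_l Σ_a p_a(1−p_a), where x_ia is individual *i*'s dosage/2 of allele
  *a* and n_l the number of reference genes — the small-sample correction in
  the numerator removes the finite-reference bias.  Expectation is half the
  relatedness scale (0.25 for parent–offspring).

Loci where a pair's denominator vanishes (e.g. monomorphic, or an LR
heterozygote with both alleles at frequency ½) are skipped for that pair and
orientation.  Pairs sharing fewer than `min_shared_loci` typed loci (default
5, the study floor) are reported but flagged undefined.

Per-pair significance uses a frequency-resampling null: at every shared
locus, both individuals' alleles are redrawn with replacement from the
reference frequencies, the estimator recomputed, `n_perm` times; the
one-tailed p is the fraction of null values ≥ observed.  Resampling **with**
replacement was chosen for exchangeability with the frequency model that
defines the estimators (the alternative — permuting the finite sample's
alleles without replacement — conditions on the observed allele multiset and
answers a subtly different question).  Type-I calibration is verified in the
test suite: over simulated unrelated pairs the p-values are uniform and the
5% rejection rate holds.

## Parentage

**Error model.**  One parameter *e*: a recorded genotype is, with probability
*e*, an independent Hardy–Weinberg draw, else the true genotype.  Applied to
the offspring observation conditional on recorded parent genotypes:
P_e(g_o|parents) = (1−e)·T(g_o|parents) + e·P_HWE(g_o).  This keeps every
likelihood closed-form, sums to one over offspring genotypes for any parents
(property-tested), and recovers pure Mendelian transmission at e = 0.

**LOD scores.**  Natural-log ratios, summed over loci typed in every involved
individual.  Single-parent: ln P_e(g_o|g_c) − ln P_HWE(g_o).  With a known
other parent, both hypotheses condition on that parent: the candidate is
scored against "known parent + random second parent".  Mismatches are counted
ignoring error (loci where transmission is impossible).  At e = 0 an
incompatible locus yields −∞, retained as a sentinel.

**Confidence.**  The standard simulation procedure: simulate offspring from
frequency-drawn parents, build candidate pools of the analysis's actual size
(the true parent included with probability `prop_candidates_sampled`, default
0.5; typing error applied at `error_rate`, default 0.01), compute
Δ = LOD(top) − LOD(second), and return the smallest Δ* such that among
simulated assignments with Δ ≥ Δ* the fraction of correct top candidates
reaches the confidence level (0.80 relaxed, 0.95 strict).  Ties are broken
uniformly at random so an uninformative panel assigns at chance level and
produces +∞ thresholds with a warning.  The achieved confidence on a fresh
simulated test set matches the nominal level within 3% (tested).

**Assignment.**  Joint mother × father search first (exhaustive — candidate
sets are desk-scale); offspring whose best pair misses relaxed confidence
fall back to separate maternity and paternity analyses.  Exact LOD ties leave
the offspring unassigned.

**Relationship LRs.**  P(g_x,g_y|R) = Σ_m k_m(R)·P_m with
(k₀,k₁,k₂) = (0,1,0) PO, (¼,½,¼) FS, (½,½,0) HS, (1,0,0) U, where P₀ is the
product of HWE probabilities, P₁ chains a single-parent transmission, and P₂
requires genotype identity.  Error mixes each locus toward P₀.  LR(U) ≡ 1;
a relationship is flagged significant above LR = 10.

## Kin-structure permutation tests

All tests report the observed mean, the full null sample, and
p = (# null ≥ observed)/n_perm; a (b+1)/(n+1) variant that can never return
zero is available.  Undefined pairs are excluded from observed and null means
alike.  Group test: individuals are reshuffled among groups preserving group
sizes (a permutation, not a bootstrap — the classical group-relatedness
null).  Focal-male test: each female is independently paired with a uniform
draw from the male pool; the two-tailed companion p is 2·min(P(null ≥ obs),
P(null ≤ obs)) capped at 1.  Region tests reuse the group machinery on
country labels after sex filtering.

## Spatial structure

Geodesic distances use the haversine formula on the mean Earth radius
(6371.0088 km); a user-supplied distance matrix overrides coordinates — the
canonical path when printed field distances are to be reproduced exactly.

R_ST is computed by one-way ANOVA on allele sizes with populations as groups
and gene copies as observations: per locus, σ²_among = (MSB − MSW)/n₀ and
σ²_within = MSW; multilocus R_ST = Σσ²_among / Σ(σ²_among + σ²_within) across
loci.  Two populations fixed for different sizes give exactly 1; identical
compositions give a slightly negative value (−1/(n₀−1)), the familiar
behaviour of unbiased components — no estimator in this family returns an
exact 0 on fixed data.  The global test permutes individuals (keeping each
individual's full multilocus genotype intact) among populations.  Note the
single-stratum design: the individual level inside populations is not modeled
separately, which matters only when within-individual and within-population
components are to be reported separately — not for the differentiation and
IBD uses here (the toy cases requiring exact values are tested).

Isolation by distance: OLS of R_ST/(1−R_ST) on ln(distance km); pairs at
R_ST = 1 (infinite transform) are excluded with a warning.  Significance
permutes the location assignment of populations, recomputing the slope with
the genetic values fixed — equivalent to a Mantel test; one-tailed p for a
positive slope.  Natural log throughout (the base only rescales the slope);
output metadata records it.

## Proximity

Scan categories 0–5 m, 6–10 m, ≥10 m; an unrecorded distance is ≥10 m by the
field protocol.  "Near" pools 0–5 and 6–10 (i.e. <10 m).  The dyad index is
near scans per focal hour, pooled over both focal directions (direction-
specific counts are retained in the table output).  Spearman correlation uses
average-rank ties; the p-value is exact (full enumeration over rank
permutations) for n ≤ 8 and the large-sample approximation above that — at
n ≥ 9 the approximation is already accurate in the tails, and 9!+ grows
needlessly expensive.

## The synthetic study system

`simdata` emulates the *statistical* structure of the field system, not its
demography:

* 10 loci, 7 consecutive integer allele sizes per locus, founder frequencies
  Dirichlet(1) — expected heterozygosity exactly 0.75 and ~6–7 observed
  alleles per locus at the founding generation.
* Four groups in two regions (9.1 / 2.0 km within regions, ~57–66 km
  between), one silverback and four breeding females per group, four solitary
  males, two offspring per female per generation.
* Paternity: the group silverback, except with probability 2/27 a random
  outside male (other groups' silverbacks or solitaries) — the extragroup
  paternity rate of the emulated system.
* Dispersal: female natal dispersal is obligatory, 80% of its mass on the
  nearest group and the rest inverse-distance weighted; silverbacks recruit
  locally with probability 0.5, else from the nearest group, and solitary
  males are drawn from the global male surplus — so males move farther than
  females on average, via recruitment, extragroup paternity, and the
  solitary-male pathway.
* Mutation: strictly stepwise ±1 repeat with reflecting bounds at the edge of
  each locus's size range (rate 5×10⁻⁴ per allele copy per generation).
* Genotyping layer: per-genotype missingness, allelic dropout
  (heterozygote → random homozygote), and replacement error (HWE redraw),
  applied in that order as independent events; defaults 0 / 0 / 1%.
* Open-system founding: each region's founder frequencies are a
  Balding–Nichols (Dirichlet) perturbation of the global pool with
  differentiation parameter `region_fst` (default 0.08), followed by a short
  4-generation pedigree history.  A closed 4-group census cannot hold
  He = 0.75 over a long history — drift through tiny polygynous demes drains
  diversity far faster than any realistic mutation rate restores it — so deep
  structure is supplied at founding and the forward generations supply
  pedigree, dispersal, and mutation structure.  Consequence: final-census
  heterozygosity runs somewhat below the founder target (≈0.6–0.7), and
  regional R_ST lands in the 0.03–0.09 range across seeds, the order observed
  in real limited-dispersal systems at these sample sizes.

What the generator does **not** emulate: overlapping generations, interbirth
intervals, group formation and disintegration, age-structured dispersal
decisions, spatially explicit home ranges, and coalescent-scale deep history.
Passing tests therefore validate the estimators and tests under the stated
statistical structure; they say nothing about demographic realism beyond it.

A stepping-stone variant (`SimulationConfig.linear`) places demes on a line
for migration–drift validation.  The power scenario used in the whole-chain
tests is 10 demes 10 km apart, eight females per deme, females staying natal
with probability 0.7 (else nearest-biased dispersal), silverbacks recruited
locally with probability 0.7 (else adjacent), 30 generations, mutation 10⁻³,
no extragroup paternity — a strong-but-not-degenerate isolation-by-distance
regime: long-range paternity draws would erase the gradient, while much lower
migration drives demes toward fixation and makes the R_ST/(1−R_ST) transform
heavy-tailed and the Mantel test noise-dominated.

## Numerical conventions and degenerate inputs

* All randomness flows through `numpy.random.default_rng` seeds; every API
  taking randomness takes a seed, the pipeline derives per-stage seeds from
  the run seed, and reruns are bit-identical.
* Permutation p-values use the (# ≥ observed)/n_perm convention throughout.
* Denominator guards use an absolute tolerance of 10⁻¹²; LODs use −∞
  sentinels rather than clipping.
* Degenerate inputs fail loudly: empty subsets, single populations, missing
  focal hours, constant correlation vectors, monomorphic-in-size panels, and
  pairs below the shared-locus floor all raise typed errors; single-member
  groups are excluded from group tests with a warning.

## Problem sizes

The validation suite uses 10,000 dyads per relationship category for
estimator recovery, 1,000 replicates at 200 permutations each for the four
permutation-test calibrations, 1,000 simulated offspring for parentage
recovery, 1,000 pairs per class for relationship LRs, and 100 stepping-stone
replicates for spatial power — sizes at which Monte-Carlo error is well below
the asserted tolerances while the whole suite stays desk-scale.
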