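# Methods

This note records the statistical definitions, simulation model, numerical
choices and known limitations behind `introtrace`.

## Data model

Genotypes are codominant diploid calls at microsatellite loci, coded as
positive integer fragment lengths. A genotype is an unordered allele pair;
half-missing calls are not representable — a call is either complete or
missing (sentinel `-9` in STRUCTURE serialisation, empty cells in CSV).
All statistics are complete-case per locus: an individual missing at locus
*l* is excluded from locus-*l* computations only. Population labels are
opaque strings; text I/O is UTF-8. Three dialects are supported (tidy CSV;
STRUCTURE two-rows-per-individual; GenAlEx-style CSV) and round-trip
exactly.

## Diversity panel

- `H_E` uses the `2n/(2n-1)` small-sample correction; `H_O` is the
  observed heterozygote fraction. Per-locus `F_IS = 1 - H_O/H_E` is
  undefined at monomorphic loci and excluded from the population mean
  (unweighted over loci). A Weir–Cockerham-style multilocus `F_IS` was
  considered and deliberately not made the default: the per-locus ratio
  definition matches the diversity-panel convention the report mirrors.
- Rarefied allelic richness is evaluated through log-gamma; the default
  rarefaction size is `g = 2 × (smallest per-(population, locus)
  typed-genotype count)`, recomputed per dataset and recorded in the run
  metadata, since only "sample-size-corrected" is conventionally fixed.
- The Hardy–Weinberg exact test is a Monte-Carlo test conditional on
  allele counts (default 10,000 re-pairings of the observed gene copies;
  `(b+1)/(m+1)` correction). Full enumeration is infeasible for
  multi-allelic loci. The per-population column combines polymorphic loci
  by Fisher's method; monomorphic loci are flagged `p = 1` and excluded
  from the combination (including them would dilute the statistic with
  zero-information degrees of freedom).
- The linkage-equilibrium screen is the standardized index of association
  `r̄_d` over per-locus allele-mismatch distances, with a permutation null
  that shuffles genotypes among individuals independently per locus.
- `g2` is estimated as the pooled ratio of within-individual two-locus
  joint heterozygosity to its between-individual independence expectation,
  each term weighted by the typed locus-pair counts, minus one. With
  complete data this reduces to the classical identity-disequilibrium
  ratio; with missing data the per-pair weighting keeps the estimator
  unbiased toward zero under the null. Significance always comes from the
  permutation null (heterozygosity indicators shuffled among typed
  individuals within each locus), which is valid for any statistic of this
  family; the default 1,000 permutations match the reporting convention.

## Null alleles

Brookfield's estimator 1, `r = (H_E - H_O)/(1 + H_E)`, is reported per
(population, locus); negative values (heterozygote excess) are reported as
computed and flagged. Under the segregating-null model used by the
simulator (each gene copy independently null with probability *q*;
null/X scores homozygous X, null/null scores missing) the estimator's
expectation is `2qH/((1+q)(1+H))` with *H* the visible heterozygosity —
i.e., it recovers *q* well only at high diversity (*H* ≳ 0.85) and is
biased downward below that. This is a property of the estimator, not of
the implementation; the recovery tests therefore use high-diversity loci.

## Differentiation

Pairwise F_ST is Weir–Cockerham θ: per-allele variance components a, b, c
computed from the two populations' samples and summed over alleles and
loci before the ratio. Small negative estimates are reported as computed.
Pairwise Jost's D uses the unbiased two-population per-locus form
`D = (r/(r-1))(H_T - H_S)/(1 - H_S)` with Nei–Chesser-corrected `H_S`,
`H_T` (harmonic mean of sample sizes); `sample_correction=False` exposes
the parametric limit used by the closed-form oracles. Loci are combined by
a harmonic mean computed through the `1/(1 + 1/D)` reciprocal transform,
which stays defined at `D = 0` (a zero locus pulls the multilocus value
down without annihilating it); an arithmetic option is provided. Negative
multilocus D is clamped to 0 with a flag (D is a proportion); θ is never
clamped. Significance permutes individuals between the pair's populations.
The display rule marks cells ≥ 0.2.

## Iterative-reallocation clustering

Each run starts from a uniformly random k-partition and performs up to 20
sequential reassignment passes: individuals are visited in a fresh seeded
random order, scored against every group by the multilocus likelihood
(heterozygote `2 p_a p_b`, homozygote `p_a²`, log10), with leave-one-out
removal of the individual's own copies when scoring its current group, and
moved immediately. Alleles unseen in a group take the pseudo-frequency
`1/(2N + 1)` (N = the group's typed genotypes at the locus). Exact
likelihood ties break by a seeded jitter ≤ 1e-9 log10 units. Groups
emptied during a pass are respawned from the largest group's worst-fitting
member. Sequential (rather than simultaneous) reassignment was chosen
after simultaneous updates proved strongly contracting: on single
panmictic samples they funnelled most runs into one identical spurious
partition, which defeats plateau-based K estimation; sequential updates
with randomised order reproduce the expected behaviour (unique partitions
on unstructured data, unanimous convergence on real structure) and remain
deterministic under a fixed seed.

The plateau record per k sorts the 50 (default) runs by mean LLOD and
counts the consecutive identical canonical partitions from the top
(canonical form: group labels renumbered by first appearance). K is
estimated as the largest k whose plateau reaches 6; no qualifying k is
reported as K = 1, and two adjacent qualifying k with equal plateau
lengths are reported as undecided between them. The size of the largest
identical-partition set is also recorded. The threshold is configurable;
6 follows the cited software's guidance and its behaviour should be judged
per dataset — family structure from very recent, very tight bottlenecks is
real structure and is detected as such.

Mean LLOD is the average over individuals of `log10(L_best/L_second)`
(non-negative by construction). The LLOD significance test builds its null
by drawing pseudo-samples of the novel sample's size from the source's
empirical allele frequencies (random union of gametes) and comparing each
against the source profile the same way (leave-one-out self-profile versus
source profile). The null conditions on the observed source sample: it is
exact when the novel sample is itself a draw from that pool and mildly
anti-conservative for two fully independent samples of one parametric
population.

## Source search

Candidates are narrowed by repeated k = 2 allocation runs. Co-allocation
of a candidate with the novel sample is the overlap of their cluster
distributions (sum over clusters of the smaller fraction) normalised by
the novel's largest cluster fraction: it reduces to the shared-majority-
cluster fraction when the novel is concentrated, and a parent aligned with
either half of a 50/50-split novel (the admixture signature) scores 1.
Candidates below the threshold (default 0.5) are discarded one per round
(the worst; batch discard optional). Termination: one candidate left
(single source), none discardable with several left (multiple sources —
ambiguity flag set), or all discarded (untested source). Ambiguous traces
may be complemented by a DAPC fitted on the novel plus the survivors; the
nearest-centroid ordering is advisory and never auto-discards. The DAPC
itself is PCA on the centred/scaled allele-dosage matrix (missing dosages
imputed by group means) followed by linear discriminant analysis;
`n_pca='auto'` keeps the smallest set of components explaining 90% of
variance, capped at n/3. Self-assignment accuracy is computed on the
training data and is optimistically biased at large retained-PC counts.

## Hybrid calls

An individual is scored per species panel by the number of loci with at
least one scored allele. Calls require at least two amplifying loci on
each panel; the minor-panel amplification fraction then grades the call:
F1 candidate at ≥ 0.6, backcross candidate in [0.2, 0.6), non-hybrid
below. The thresholds interpolate the canonical exemplars (100%/80% → F1;
100%/30–40% → backcross) and are always recorded with the call. Limitation:
with 10-locus panels, per-locus cross-amplification artifact rates above
roughly 1% make two coincident artifacts non-negligible
(`P[Bin(10, q) ≥ 2]`), so the false-positive rate of the two-locus rule
degrades with noisy scoring; the band cannot be widened without un-calling
the 30–40% backcross exemplar. Prevalence estimation is deliberately not
offered (collections of morphologically ambiguous individuals are biased
samples).

## Synthetic data

The simulator is a discrete-generation Wright–Fisher model per population:
offspring draw two parents uniformly with replacement and inherit one
random allele from each; mutation is strictly stepwise (±1 repeat unit,
symmetric; default rate 5e-4 per copy per generation — a standard
microsatellite order of magnitude). Populations recover to the configured
effective size (default 200) one generation after founding (instant
growth). A documented ledger replays as: burn-in of the native population
(default 200 generations), events in year order — a founder event samples
the propagule without replacement (propagules larger than the source are
capped at the source size); several same-year shipments into one
destination merge with founder numbers proportional to propagule sizes; a
later shipment into an existing population admixes at proportion
`propagule/(propagule + N_current)` — with two generations per year of
drift between event years (a weevil-voltinism approximation), a
configurable post-history growth period, and finally per-population
sampling without replacement (default 25 individuals). Genotyping noise
adds independent whole-genotype dropout and a segregating null allele per
locus (each copy null with probability q).

What the generator emulates: serial bottlenecks, admixture, drift, SMM
mutation, missingness, null alleles, at the data shape of a worldwide
microsatellite survey (8–10 loci, 2–10 alleles/locus, 6–33 individuals per
site, 8–11 sites). What it does not: selection, sex structure, overlapping
generations, linkage, spatial dispersal, allele-size homoplasy beyond the
SMM ladder, and scoring artifacts other than nulls/dropout. Passing tests
on simulated data therefore validate the statistical machinery under the
stated demographic model, not the wet-lab scoring pipeline.

## Determinism and problem sizes

Every stochastic routine takes an explicit seed; the pipeline derives
per-stage seeds from one global seed via a stage-name hash, and reruns
with an identical configuration are bit-identical. Test and acceptance
experiments run at desk scale chosen to keep each property sharp: 20
seeded datasets for K-recovery and source-search recovery, 200 replicates
for type-I calibrations, 100 replicates for null-allele recovery, 100,000
subsamples for the rarefaction Monte-Carlo oracle. Permutation p-values
always use the `(b+1)/(m+1)` correction and respect its lower bound.
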