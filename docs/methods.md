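# Methods

`pearsnp` implements a marker-panel workflow for clonally propagated crops,
exercised end to end on a synthetic pear-like germplasm collection: locus
filtering, marker informativeness statistics, population differentiation and
diversity, core-panel selection with nested subsets, and genotype-profile
variety identification.

## Genotype model and conventions

Genotypes are biallelic diploid calls coded as ALT-allele dosage 0/1/2 with
−1 for missing, held in a `GenotypeMatrix` (accessions × loci, optional
per-call read depth). Coordinates are 1-based; chromosome labels are
normalized by stripping a `chr` prefix. Allele orientation is taken from the
input; a table cell whose alleles are not the locus's REF/ALT is a
validation error, never silently recoded, because strand flips would corrupt
identification results.

## Synthetic collection

The generator draws structured genotypes under the Balding–Nichols model.
Per locus an ancestral ALT frequency `p` is drawn by sampling a minor-allele
frequency uniformly from (0.10, 0.50) and mirroring it to `1−p` with
probability 1/2. Population `k` with drift parameter `F_k` draws its
frequency from `Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k)`; each diploid
genotype is `Binomial(2, q_k)`. The defaults are the study conditions the
pipeline is designed for:

| parameter | default | rationale |
|---|---|---|
| populations | 5 (P. pyrifolia, P. ussuriensis, P. bretschneideri, P. communis, hybrids) | the four cultivated species plus interspecific hybrids |
| sizes | (86, 27, 19, 26, 26) | unequal sample sizes of a real collection; 184 accessions |
| drift `F` | (0.02, 0.20, 0.25, 0.75, 0.05) | pairwise differentiation spanning ≈0.03–0.49 and within-population He spanning ≈0.10–0.38, i.e. weakly drifted Asian pears vs. a narrow, strongly diverged European pool |
| loci | 900 on 17 chromosomes | enough that the MAF/missing filter and the PIC/het gate (≈33% pass rate) leave a 232-marker core panel feasible, mirroring a realistic discovery funnel |
| chromosome spans | ≈480 Mb total, per-chromosome proportions of a pear assembly | uniform locus placement weighted by length, positions unique and sorted |
| missing rate | 0.03 | >90% call rates for most accessions |
| depth | Poisson(20) per call | mean mapped depth of ~20× |
| clones | 8 pairs, each differing at Uniform{0,1,2} loci | somatic/bud mutants; 184 + 8 = 192 accessions |

For the Hudson-style estimand the expected pairwise differentiation is
approximately the mean of the two drift parameters; the generator records
the realized per-population frequencies (`TrueParameters`) so estimator
recovery is testable: expected heterozygosity in closed form
(`mean 2q(1−q)`) and a ratio-of-sums Hudson Fst from true frequencies.

What the generator does *not* emulate: linkage disequilibrium (loci are
independent), admixed individuals (hybrids are a drifted population of
their own unless the frequency-averaging flag is used), genotyping error,
locus-specific missingness, and correlated drift between populations (a
star phylogeny, so two "similar" populations cannot both be close to each
other and far from a third). Passing tests therefore demonstrate
correctness of the estimators and the workflow's logic, not calibration
against any real collection.

## Marker statistics and filters

* **Allele frequencies** by gene counting over non-missing diploid calls;
  a locus with zero called genotypes returns a NaN sentinel.
* **PIC** `= 1 − Σp_i² − Σ_{i<j} 2p_i²p_j²`; for biallelic loci bounded by
  0.375 at MAF 0.5 and strictly increasing in MAF.
* **Expected heterozygosity** uses the sample-size-corrected (unbiased)
  form `He = 2n/(2n−1)(1 − Σp_i²)`, consistent with the
  "corrected for sample size" convention used for the distance matrix.
* **Allelic richness** is rarefaction-based (El Mousadik & Petit): per
  locus `A = Σ_i [1 − C(2N−N_i, g)/C(2N, g)]`, averaged over loci. The
  rarefaction size `g` defaults to twice the smallest per-population,
  per-locus called sample and is shared across all rows of the diversity
  table, including the pooled "Total" row, which is computed over all
  non-excluded accessions as one sample (pooling, not averaging — the
  alternative convention is noted because published tables rarely say
  which they use). Binomial ratios are evaluated in log space.
* **Locus filter**: calls with depth below 3× are first set missing (a
  warned no-op when no depth is recorded); loci are then dropped when
  missing rate ≥ 0.15, otherwise when MAF ≤ 0.05. Keep-side inequalities
  are strict, ties are excluded, attribution is to the first failing rule,
  and the filter is idempotent. The missing-rate default is 0.15; the
  looser 0.30 sometimes quoted for comparable workflows is available as a
  parameter.
* **Core-candidate gate**: PIC > 0.25 and heterozygosity rate < 0.35
  (strict). The heterozygosity ceiling guards against paralog-collapse
  artifacts, which present as excess heterozygosity.

## Differentiation statistics

* **Fst** is Weir & Cockerham's (1984) θ for two populations, combined
  over loci as a ratio of sums of the variance components
  (`Σa / Σ(a+b+c)`). Loci with no called genotype in either population
  (or fewer than three pooled) are skipped. Negative multi-locus θ is
  reported as computed. Note the estimator's small-sample correction makes
  θ for two copies of the same sample slightly *negative* (order 1/n),
  not zero; zero is its expectation under no differentiation.
* **Nei's distance** is the 1978 unbiased form: within-population
  identities `Ĵ_X = mean_l (2n Σx² − 1)/(2n − 1)`, between-identity
  `J_XY = mean_l Σ x_i y_i`, `D = −ln(J_XY/√(Ĵ_X Ĵ_Y))`, clipped at 0
  (the unbiased correction can push the ratio above 1, e.g. for
  self-comparisons) and `+inf` when the populations share no alleles.
* **Significance**: the permutation null reassigns whole multilocus
  genotypes (accessions) between the pair, preserving within-individual
  structure, with θ recomputed each time. The add-one estimator
  `p = (1 + #{θ* ≥ θ})/(1 + n_perm)` avoids p = 0; the Bonferroni factor
  is the number of pairs tested (10 for five populations). The permutation
  engine evaluates assignments in vectorized blocks, so 10,000
  permutations across all ten pairs take seconds.

Which exact Fst variant legacy microsatellite software computes for SNP
data is often undocumented; Weir–Cockerham is adopted here as the field
default and recorded in output metadata.

## Clustering

PCA encodes calls as dosages, imputes missing calls to the locus mean,
centers columns, and takes the SVD; explained fractions are relative to
total variance. Distances are pairwise-complete Euclidean over dosages
with `L/L_shared` rescaling and a minimum shared-locus fraction (default
0.5) guarding degenerate pairs. UPGMA is implemented directly with a
deterministic tie-break (merge the pair whose representative leaf labels
sort first); heights are half the merge distance so cophenetic distances
equal merge distances, and trees serialize to Newick with branch lengths
as height differences.

## Panel design

Candidates passing the gate are allocated per-chromosome quotas: one base
seat per candidate-bearing chromosome when the target allows, the
remainder apportioned to chromosomes proportionally to the physical span
of their candidates with largest-remainder rounding. Within a chromosome
candidates are taken in descending PIC (ties by position, then id),
skipping any closer than 500 kb (default) to a selected marker. Shortfalls
are redistributed across chromosomes by the same rule; only when no
spacing-respecting candidate remains anywhere is spacing relaxed, and each
relaxation is recorded on the panel. No published allocation algorithm
exists for this step, so this transparent deterministic procedure is the
package's own; quotas and spacing are parameters. Nested subsets re-run
the procedure restricted to the parent's markers, making each subset a
true subset by construction (an independent, non-nested mode is simply
selection from the full candidate table).

## Identification

Two accessions are indistinguishable when they share at least
`min_shared` called loci (default: half the panel, rounded up) and agree
at every shared locus; missing-vs-called comparisons are not differences.
Groups are connected components of this relation — reported as components
because missing-data patterns can break transitivity — and distinguished
accessions are exactly the singleton components. Pairs below the sharing
floor are flagged uncallable, never merged. The zero-difference criterion
(rather than a distance threshold) matches how somatic mutants behave: a
clone differing at no assayed marker is undistinguishable by definition,
and one differing at any panel marker is separated.

## Problem sizes and reproducibility

The test suite runs the statistical checks at reduced but sufficient
sizes: type-I-error calibration of the permutation test uses 200 replicate
null datasets of 300 loci and 20+20 accessions at 499 permutations
(rejection rate at α = 0.05 within [0.03, 0.07]); parameter recovery uses
two populations of 80 at 1,000 loci (θ within 25% of the truth-derived
value); workflow-shape properties use 50 replicates of a 55-accession,
300-locus collection. `scripts/acceptance.py` runs the full study-size
conditions (192 accessions, 900 loci, 10,000 permutations) in well under a
minute. All randomness flows from a single integer seed through
`numpy.random.SeedSequence`, and a rerun with the same seed reproduces
every output byte for byte.

## Known limitations

* The Balding–Nichols star phylogeny cannot reproduce *correlated*
  population structure (e.g. two sister populations jointly diverged from
  the rest); simulated pairwise divergences are approximately additive in
  the drift parameters.
* Identification treats genotyping as error-free; a single miscalled
  marker would split a true clone pair. A tolerance threshold would
  require an error model, which is out of scope.
* Imputation beyond locus-mean (for PCA) is not provided; haplotype-based
  imputation belongs to external tooling.
* Model-based ancestry clustering (admixture proportions) is out of
  scope; PCA and UPGMA are the provided structure summaries.
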