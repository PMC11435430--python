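# pearsnp

SNP core-panel design, population-genetic summaries, and genotype-profile
variety identification for cultivated pear (*Pyrus* spp.) germplasm
collections — and for any clonally propagated crop with a modest biallelic
marker set.

Pear cultivars are hard to tell apart morphologically, yet variety
protection (DUS testing) requires distinctness to be demonstrable. A small,
well-chosen SNP panel can fingerprint a collection cheaply: filter
discovery-stage SNPs on minor allele frequency, missing rate and depth;
keep informative, artifact-free markers (polymorphic information content
PIC > 0.25, heterozygosity rate < 35%); spread them across the 17 pear
chromosomes; and score how many accessions carry a unique multilocus
profile. This package implements that workflow as a tested library with a
CLI, plus a synthetic-data generator so every stage is verifiable without
access to any proprietary collection.

## Core statistics

For allele frequencies `p_i` at a biallelic locus:

- `PIC = 1 − Σ p_i² − Σ_{i<j} 2 p_i² p_j²` (max 0.375 at MAF 0.5)
- unbiased expected heterozygosity `He = 2n/(2n−1) · (1 − Σ p_i²)`
- rarefaction allelic richness `A = Σ_i [1 − C(2N−N_i, g)/C(2N, g)]`
- Weir–Cockerham `θ` (two-population, ratio of summed variance
  components) with permutation p-values (whole genotypes permuted,
  add-one estimator, Bonferroni over pairs)
- Nei's (1978) unbiased standard genetic distance
  `D = −ln(J_XY / √(Ĵ_X Ĵ_Y))`
- pairwise-complete Euclidean genotype distances, UPGMA dendrograms, PCA

The synthetic generator draws structured genotypes under the
Balding–Nichols model (`Beta`-distributed population frequencies around an
ancestral frequency with drift `F`), records the true frequencies, and
appends clone/bud-mutant pairs differing at 0–2 loci.

## Worked example

```bash
pearsnp simulate --outdir results/dataset --seed 1
pearsnp all --vcf results/dataset/genotypes.vcf \
            --metadata results/dataset/populations.csv \
            --outdir results/run --seed 1
```

or, as a library / via the numbered analysis drivers
(`analysis/01_simulate_collection.py` … `05_identify_varieties.py`):

```text
$ python analysis/01_simulate_collection.py
simulated 192 accessions (184 base + 8 clones) x 900 SNPs

$ python analysis/03_population_structure.py
pairwise matrix (Fst upper triangle, Nei D lower triangle):
                      P. pyrifolia  P. ussuriensis  P. bretschneideri  P. communis  interspecific hybrid
P. pyrifolia                   NaN           0.100              0.129        0.307                 0.033
P. ussuriensis               0.063             NaN              0.225        0.467                 0.132
P. bretschneideri            0.086           0.134                NaN        0.495                 0.158
P. communis                  0.196           0.258              0.249          NaN                 0.380
interspecific hybrid         0.021           0.080              0.099        0.200                   NaN
10/10 pairs significant at p < 0.001 (Bonferroni, 10000 permutations)
PCA: PC1 explains 15.5%, PC2 5.2% of total variance

$ python analysis/05_identify_varieties.py
identification rates along the nested chain:
   panel_232: 180/192 (93.8%), 6 indistinguishable groups
   panel_192: 178/192 (92.7%), 7 indistinguishable groups
    panel_96: 176/192 (91.7%), 8 indistinguishable groups
    panel_48: 167/192 (87.0%), 9 indistinguishable groups
    panel_24: 153/192 (79.7%), 10 indistinguishable groups
```

Reading: the European population (*P. communis*, strongly drifted and
genetically narrow) is sharply differentiated from the Asian species
(θ up to 0.50) while hybrids sit closest to *P. pyrifolia* (θ = 0.033);
the 232-marker core panel distinguishes 93.8% of accessions — the
residual groups are exactly the simulated zero-mutation clone pairs — and
identification degrades gracefully as the nested panels shrink to 24
SNPs, which still resolve ~80%.

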