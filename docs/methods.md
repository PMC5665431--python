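# Methods

This note records the models, estimators, numerical choices and known
limitations behind each module, and what the synthetic data do and do
not establish about behaviour on real cohorts.

## Synthetic cohorts (`simdata`)

The generator produces the statistical structure the downstream stages
assume, not coalescent realism.

- **Allele frequencies.** Ancestral frequencies are Uniform(0.05, 0.95)
  per SNP. Cluster frequencies follow the Balding–Nichols model:
  Beta with mean `p` and variance `F·p(1−p)`, i.e.
  `Beta(p(1−F)/F, (1−p)(1−F)/F)`; `F = 0` returns `p` exactly. `F` is
  the per-cluster drift parameter (dimensionless, in [0, 1); default
  0.03 in the analysis drivers — a within-region level of
  differentiation at which haplotype sharing still dominates plain
  genotype sharing).
- **Haplotype sharing.** Each cluster has a founder pool
  (`n_founders = 30`) drawn site-wise from the cluster frequencies;
  sample haplotypes are mosaics of founder segments with geometric
  lengths (mean 20 SNPs, the order of magnitude of chunk sizes seen
  when painting dense array data). Mosaic copying makes within-cluster
  sharing exceed between-cluster sharing, which is exactly the signal
  the painter measures. Admixed clusters draw each segment's source
  cluster from their mixture row.
- **Sweep implantation.** "Concordant" mode drives each affected
  cluster to near-fixation (carrier fraction 0.95) for a *distinct*
  4-SNP haplotype, raising local differentiation; "discordant" fixes
  the *same* haplotype in all affected clusters, collapsing local
  differentiation (the Weir–Cockerham numerator then goes non-positive).
- **Coordinates.** bp positions are uniformly spaced; the genetic map
  defaults to 1 cM/Mb. Alleles are strictly biallelic 0/1.
- **Direct coancestry generator.** For profile-recovery studies,
  `simulate_coancestry` skips haplotypes entirely: each recipient's row
  is Multinomial over donor individuals with expected share
  `β_g / n_g`; donor-cluster members donate uniformly to the rest of
  their own cluster (self-copying excluded), which makes the
  donor-cluster characteristic rows exactly uniform in expectation and
  the profile identifiable.

What the generator does **not** emulate: recombination-map and LD
realism, admixture-LD decay over generations (so no weighted-LD dating
on synthetic data), mutation, multi-allelic sites, and genotyping
error. Passing tests therefore establish correctness of the estimators
and their calibration under the stated models, not performance on the
messier frequency spectra and LD of real arrays.

## Painter (`painting`)

The painter minimises
`mismatch_cost · #mismatches + switch_cost · #switches` over donor-label
sequences by dynamic programming, exactly; ties break toward the lowest
donor index and then the earlier switch, so output is deterministic.
This is a deliberate simplification of the Li–Stephens HMM: it keeps the
chunk-count/chunk-length semantics the downstream statistics need while
being oracle-testable (exhaustive search on small instances), but it is
*not* numerically equivalent to ChromoPainter — no recombination-rate
scaling, no mutation-rate estimation, and hard rather than posterior
chunk boundaries. Both haplotypes of each recipient are painted against
both haplotypes of every other individual (self excluded); chunks are
attributed to donor individuals. Default costs are
`switch_cost = mismatch_cost = 1`: a switch is worth one mismatch,
which keeps chunks at the tens-of-SNPs scale of the simulated segments.

Chunk cM lengths place chunk boundaries at midpoints between flanking
SNPs, so each recipient haplotype's chunk lengths partition the
chromosome's total cM span exactly — the conservation property the
chunk-length matrices rely on.

The within-population submatrix scaling (used when one population's
within-population donation is inflated, e.g. by imputed genotypes)
regresses within-population average donation on sample size across the
unaffected populations and multiplies the affected block by
predicted/observed. The regression predictor is a design choice; sample
size is the natural candidate because within-population donation grows
with the number of available same-population donors.

## Ancestry profiles (`ancestry_profile`)

The simplex-constrained least squares `min ‖Y − Xβ‖₂` s.t. `β ≥ 0`,
`Σβ = 1` is solved by augmenting the system with a penalty row
`λ·(1,…,1) ↦ λ`, `λ = 10⁴·max|X|`, running non-negative least squares,
and renormalising exactly. At this penalty weight the solution matches a
projected-gradient solver to ~1e-6 in objective while avoiding a bespoke
active-set implementation.

The chromosome-block bootstrap resamples, independently per chromosome,
each target individual's coancestry row from the same-cluster pool
(with replacement), sums the chromosome matrices, recomputes `Y` and
refits with **fixed** donor rows — donor clusters are treated as
reference signatures, not as a source of sampling noise. Intervals are
per-coordinate percentile intervals (linear interpolation).

The difference test centres the bootstrap differences at the observed
difference, `x⁽ⁱ⁾ = (β⁽ⁱ⁾ − γ⁽ⁱ⁾) − (β − γ)`, counts the one-tailed
proportion of `x⁽ⁱ⁾` at least as extreme as `β − γ` in the direction of
its sign, doubles and caps at 1. An absolute-value ("two-tailed before
doubling") convention exists; the signed convention is used because it
reduces to the familiar percentile test under symmetry. A reporting
flag can floor zero counts at `2/B`; by default a zero count reports 0.
Calibration: under a true null the test rejects at the 0.05 level in
5% ± 3% of 200 simulation runs (checked in the test suite at B = 200).

Profiles default to chunk-length matrices (chunk counts are accepted);
lengths weight sharing by genome span rather than by recombination
breakpoints, which is the more stable signal when chunk sizes differ
between donor clusters.

## Cluster separability (`cluster_eval`)

Reassignment probabilities follow the overlap rule
`P(A_i | B) = |A_i ∩ B| / Σ_j |A_j ∩ B|`, averaged over sampled
iterations; every vector sums to 1 by construction. Probability ties
break toward the individual's original cluster (conservative: an exact
tie never reports a separation failure), then lexicographically.
Separability summaries report mean and sample SD (n − 1) of reassigned
counts per ordered cluster pair over alternative runs. Partition
samples are read as one iteration per line, comma-separated labels in
individual order; sampled cluster names carry no meaning beyond the
partition they induce.

`binary_dendrogram_counts` constructs a rooted binary dendrogram over
`n` leaves by successive pairwise merges and counts its parts: `n − 1`
internal nodes and `2n − 2` edges (3198 for the study-scale 1600
individuals).

## Differentiation scan (`differentiation`)

Windows are consecutive, non-overlapping blocks of 4 SNPs per
chromosome; trailing SNPs are dropped. Window length outliers (beyond
3 SD of log bp or log cM span, statistics from the pre-filter table in
a single pass) are removed; zero-length spans are removed and excluded
from the log statistics; a zero SD removes nothing in that scale.
Re-running the filter can remove more windows — the contract is
single-pass, and the tests document it.

Per window, distinct 4-SNP haplotypes are the alleles of one
multi-allelic haploid locus. With `r` populations of `n_i` haplotypes
and allele frequencies `p_iu`:

```
n_c   = (n − Σn_i²/n) / (r − 1)
MSP_u = Σ_i n_i (p_iu − p̄_u)² / (r − 1)
MSG_u = Σ_i n_i p_iu (1 − p_iu) / Σ(n_i − 1)
num   = Σ_u (MSP_u − MSG_u) / n_c
den   = Σ_u (MSP_u + (n_c − 1)·MSG_u) / n_c
```

The per-window HF_ST is `num/den` (can be ≤ 0; undefined when
`den = 0`, i.e. the window is monomorphic everywhere — such windows are
excluded from binning and from population-level HF_ST). The components
are exposed so an alternative estimator can be swapped without touching
the ratio-of-averages aggregation. Population HF_ST is `Σnum / Σden`
over retained windows — the ratio-of-averages estimator, which is not
the mean of per-window ratios.

A calibration fact, verified empirically in the test suite: on haploid
samples drawn directly from the Balding–Nichols model the SNP-level
ratio-of-averages recovers the drift parameter `F` almost exactly,
while the 4-SNP haplotype-allele version sits well below `F` when sites
drift independently (each haplotype allele's frequency is a product of
semi-independently drifting site frequencies, which dilutes per-allele
differentiation). Windowed HF_ST values are therefore comparable
between analyses with the same window scheme but are not on the same
scale as SNP-level F_ST.

Binning sorts valid windows ascending by HF_ST (stable sort, ties keep
genomic order) into 20 contiguous equal-count groups (first `remainder`
bins take the extra window); bin 1 is least, bin 20 most
differentiated. Enrichment per bin uses a one-sided Fisher exact test
of {in-bin vs out} × {selected vs not} at the multiplicity-adjusted
threshold `0.01/20 = 5×10⁻⁴`. Selected-vs-rest location shifts use the
Mann-Whitney test (exact enumeration when both groups ≤ 20, else the
tie-corrected normal approximation); rank correlations are Spearman
with average ranks. Loci spanning several windows report the bin of the
maximum-HF_ST overlapping window. BED inputs are 0-based half-open, VCF
1-based; window spans run from first to last SNP inclusive. Known
highly-selected regions (e.g. extended HLA) are excluded via a
user-supplied BED, never hard-coded. The scan defaults to clusters of
at least 42 individuals (configurable), below which window-level
haplotype frequencies are too noisy.

Neighbor joining is the standard Saitou–Nei agglomeration with the
usual Q-matrix; ties break toward the lexicographically smallest taxon
pair, negative branch lengths are reported as computed, and additive
distances are recovered exactly (verified against an independent NJ
implementation).

## Stratification (`stratification`)

The Cochran–Armitage trend test uses scores (0, 1, 2); a zero-variance
genotype distribution scores 0. `λ_GC = median(χ²)/0.4549`, the 1-df
χ² median hard-coded to 4 decimals for reproducibility; the median uses
the midpoint rule for even counts. The case/control design is cluster
membership itself — no phenotype model — and SNPs below 1% combined
minor allele frequency are excluded (a conventional GWAS floor; the
threshold is a parameter).

## Admixture-date meta-analysis (`admix_meta`)

Fixed-effect only: inverse-variance weights, combined SE
`(Σw)^{-1/2}`, Cochran's `Q` against χ²(k−1). Smallest-SE selection
breaks ties toward the smaller estimate, then the lexicographically
smaller reference. Year conversions are **years before present** at 25
years/generation; no calendar-date arithmetic is attempted. The bundled
`data/table1.csv` holds the per-cluster dates (generations ± SE and
admixture P-values) that the meta-analysis and selection operate on.
The reference-multiplicity correction multiplies raw P-values by the
effective number of reference populations (default 12) and caps at 1.

## Problem sizes

The analysis drivers and tests run cohorts of 30–200 individuals per
cluster, 4 chromosomes and 600–5,000 SNPs each (≈ 20,000 SNPs for the
λ_GC studies), bootstrap sizes 200–1,000, and 100–200 replicate runs
for calibration/coverage studies. These sizes were chosen so each
estimator operates in the regime its asymptotics assume (dozens of
haplotypes per population per window, thousands of SNPs per λ_GC
median) while the whole suite stays desk-scale.

## Known limitations

- The painter is not ChromoPainter; absolute chunk counts are not
  comparable with Li–Stephens output, only their relative structure.
- Percentile bootstrap intervals undercover slightly for target
  clusters of ≲20 individuals (the coverage study uses 30).
- Haplotypic F_ST values depend on the window scheme and are not on
  the SNP-level F_ST scale (see above).
- MCMC partition samples are consumed, never produced: there is no
  clustering likelihood or convergence diagnostic here.
- Profiles quantify present-day haplotype sharing; they are not, by
  themselves, a migration history.
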