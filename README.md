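# hapfine

Haplotype-based fine-scale population structure analysis: coancestry
painting, ancestry-profile decomposition with bootstrap inference,
cluster separability, windowed haplotypic F_ST and its relation to
positive selection, genomic-control stratification checks, and
meta-analysis of admixture dates.

## Who this is for

Population geneticists working with dense, phased SNP data from closely
related populations — the regime where classical PCA on genotype
sharing stops resolving structure but haplotype sharing still does.
The package implements the statistical core of such a study as a tested,
reusable library plus a sequence of analysis drivers, exercised
end-to-end on synthetic cohorts so that every stage is verifiable
without access to restricted genotype data.

## The statistics

**Coancestry painting.** Each phased haplotype of a recipient
individual is reconstructed as a mosaic of donor haplotype chunks by
minimising `mismatch_cost · (allele mismatches) + switch_cost ·
(donor switches)` exactly via dynamic programming. The coancestry
matrix `a_ij` counts chunks (or sums their cM lengths) that recipient
*i* copies from donor *j* — a natural summary of haplotype sharing.
(This deterministic min-cost painter preserves chunk semantics but is
intentionally simpler than the Li–Stephens HMM used by ChromoPainter.)

**Ancestry profiles.** A target cluster's mean coancestry row `Y` over
external donors is decomposed as `Y ≈ β₁X₁ + … + β_G X_G` with
`β_g ≥ 0`, `Σβ_g = 1`, where `X_g` are donor-cluster mean rows; solved
by penalty-row NNLS with exact renormalisation. Confidence intervals
come from a chromosome-block bootstrap (per chromosome, each target
individual's row is replaced by a re-drawn same-cluster row; donor rows
stay fixed); differences of contributions are tested by centring the
bootstrap differences at the observed difference and doubling the
one-tailed tail proportion.

**Cluster separability.** Given the original clustering `{A_i}` and
alternative MCMC partition samples, an individual in sampled cluster
`B` is reassigned to `A_i` with probability `|A_i ∩ B| / Σ_j |A_j ∩ B|`,
averaged over iterations; counting individuals whose most probable
cluster changes quantifies separability.

**Haplotypic F_ST.** The genome is cut into 4-SNP windows; distinct
window haplotypes are treated as alleles of one multi-allelic locus and
Weir–Cockerham-style haploid variance components give a per-window
numerator and denominator. The population-level HF_ST is the ratio of
averages `Σnum / Σden` (never the mean of ratios). Windows are ranked
into 20 equal-count bins; per-bin enrichment of positively-selected
windows is tested one-sided by Fisher's exact test at `P < 0.01/20`.
NJ trees on pairwise HF_ST summarise between-cluster distances.

**Stratification.** Two clusters are cast as GWAS cases and controls;
the genomic-control factor `λ_GC = median(χ²_trend) / 0.4549` measures
the genome-wide inflation that structure alone produces.

**Admixture-date meta-analysis.** Per-cluster dates (generations ± SE)
are combined by inverse-variance fixed effects; Cochran's
`Q = Σ w_i (x_i − x̄)²` with `k − 1` df tests heterogeneity; dates
convert to years before present at 25 years/generation.

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on a
simulated cohort (four clusters of 30, drift F = 0.03, one cluster an
admixed 30/70 mosaic of the first two) and write tables under
`results/`:

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_paint_coancestry.py
python analysis/03_ancestry_profiles.py --seed 1
...
```

`03_ancestry_profiles.py` prints:

```
ancestry profile of pop3 (chunk-length coancestry, donors pop0-2):
  pop0: beta = 0.282 [0.260, 0.305]  (truth 0.30)
  pop1: beta = 0.718 [0.695, 0.740]  (truth 0.70)
  pop2: beta = 0.000 [0.000, 0.000]  (truth 0.00)
```

— the NNLS profile recovers the designed 30/70 mixture, with bootstrap
95% intervals covering the truth and no spurious contribution from the
unrelated cluster. `05_differentiation_scan.py` shows the direction
reversal between selection that is concordant vs discordant with
drift:

```
concordant: significant bins [20] (Fisher P < 0.01/20); selected windows' HF_ST higher
discordant: significant bins [1, 2] (Fisher P < 0.01/20); selected windows' HF_ST lower
```

and `07_admixture_dating_meta.py` reproduces the admixture-dating
conclusions from the bundled per-cluster table: dates are heterogeneous
across all nine clusters (Cochran P = 0.034 and 0.0082 for the two Han
Chinese references) but homogeneous within the Hondo and Ryukyu island
groups, with smallest-SE dates 49.9 generations (~1250 years BP) for
Hondo and 39.3 generations (~975 years BP) for Ryukyu.

The same stages are scriptable through the `hapfine` CLI
(`simulate`, `paint`, `profile`, `separability`, `diff-scan`, `strat`,
`meta`, `run`).

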