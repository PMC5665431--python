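"""Impact of population structure on association testing.

Two clusters are compared as GWAS cases and controls with no phenotype
model: any systematic allele-frequency difference between them inflates
the Cochran–Armitage trend statistic genome-wide. The genomic-control
inflation factor lambda_GC is the median trend chi-square divided by
0.4549, the median of the 1-df chi-square null; lambda_GC > 1 indicates
stratification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cluster_eval import ClusterModel
from .simdata import HaplotypeDataset

__all__ = ["GwasSimResult", "trend_test", "lambda_gc", "simulate_gwas_pair",
           "CHI2_1DF_MEDIAN"]

# median of the chi-square distribution with 1 df, to 4 decimals
CHI2_1DF_MEDIAN = 0.4549


@dataclass
class GwasSimResult:
    chi2: np.ndarray
    lambda_gc: float
    n_snps: int
    case_cluster: str
    control_cluster: str


def trend_test(genotype_counts) -> float:
    """Cochran–Armitage trend chi-square (1 df), scores (0, 1, 2).

    ``genotype_counts``: 2x3 table, rows (cases, controls), columns
    copies of the alternate allele. A zero-variance genotype
    distribution gives 0.
    """
    tab = np.asarray(genotype_counts, dtype=float)
    if tab.shape != (2, 3):
        raise ValueError("expected a 2x3 {case,control} x {0,1,2} table")
    if np.any(tab.sum(axis=1) <= 0):
        raise ValueError("row totals must be positive")
    return float(_trend_chi2(tab[None, 0, :], tab[None, 1, :])[0])


def _trend_chi2(case_counts: np.ndarray, control_counts: np.ndarray) -> np.ndarray:
    """Vectorised trend chi-square over SNPs; rows are (S, 3) tables."""
    scores = np.array([0.0, 1.0, 2.0])
    r = case_counts.sum(axis=1)  # cases per SNP
    n_gt = case_counts + control_counts
    n = n_gt.sum(axis=1)
    t_num = n * (case_counts @ scores) - r * (n_gt @ scores)
    var_term = r * (n - r) * (n * (n_gt @ scores**2) - (n_gt @ scores) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(var_term > 0, n * t_num**2 / var_term, 0.0)
    return chi2


def lambda_gc(chi2) -> float:
    """Genomic-control inflation factor: median(chi2) / 0.4549.

    The median uses the midpoint rule for even n (numpy default).
    """
    chi2 = np.asarray(chi2, dtype=float)
    if chi2.size == 0:
        raise ValueError("empty chi-square vector")
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)


def _genotypes(dataset: HaplotypeDataset, individuals: np.ndarray) -> np.ndarray:
    """(n_ind, total_snps) diploid dosage matrix from phased haplotypes."""
    mats = []
    for c in range(dataset.n_chrom):
        h = dataset.haplotypes[c]
        mats.append(h[2 * individuals] + h[2 * individuals + 1])
    return np.concatenate(mats, axis=1)


def simulate_gwas_pair(
    dataset: HaplotypeDataset,
    clusters: ClusterModel,
    cluster_a: str,
    cluster_b: str,
    min_maf: float = 0.01,
) -> GwasSimResult:
    """Case-control GWAS of cluster membership; returns per-SNP trend
    chi-square and lambda_GC.

    Cases are cluster_a members, controls cluster_b members; SNPs with
    combined minor allele frequency below ``min_maf`` are excluded.
    """
    ids = dataset.individual_ids
    idx = {i: k for k, i in enumerate(ids)}
    a_members = [idx[i] for i in clusters.members(cluster_a) if i in idx]
    b_members = [idx[i] for i in clusters.members(cluster_b) if i in idx]
    if not a_members or not b_members:
        raise ValueError("both clusters must be non-empty within the dataset")
    if set(a_members) & set(b_members):
        raise ValueError("clusters overlap")
    g_case = _genotypes(dataset, np.asarray(a_members))
    g_ctrl = _genotypes(dataset, np.asarray(b_members))
    combined = np.concatenate([g_case, g_ctrl], axis=0)
    af = combined.mean(axis=0) / 2
    keep = np.minimum(af, 1 - af) >= min_maf
    case_counts = np.stack([(g_case[:, keep] == k).sum(axis=0) for k in (0, 1, 2)], axis=1)
    ctrl_counts = np.stack([(g_ctrl[:, keep] == k).sum(axis=0) for k in (0, 1, 2)], axis=1)
    chi2 = _trend_chi2(case_counts.astype(float), ctrl_counts.astype(float))
    return GwasSimResult(chi2, lambda_gc(chi2), int(keep.sum()), cluster_a, cluster_b)
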