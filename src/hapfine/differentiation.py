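"""Windowed haplotypic F_ST and the selection–differentiation scan.

The genome is partitioned into consecutive windows of four SNPs. Within
a window, each distinct 4-SNP haplotype is treated as one allele of a
multi-allelic locus and each phased haplotype as a haploid observation;
Weir–Cockerham-style variance components for haploid data give a
per-window numerator (among-population component) and denominator
(total). The population-level HF_ST is the ratio of averages: summed
numerators over summed denominators across windows — not the mean of
the per-window ratios. Windows are ranked into equal-count HF_ST bins
and the proportion overlapping positively-selected regions is compared
per bin against the genome-wide average with one-sided Fisher tests
(threshold 0.01 / n_bins).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import HaplotypeDataset

__all__ = [
    "WindowTable",
    "HfstResult",
    "make_windows",
    "filter_outlier_windows",
    "window_hfst",
    "window_hfst_table",
    "population_hfst",
    "pairwise_hfst_matrix",
    "neighbor_joining",
    "bin_windows",
    "enrichment_by_bin",
    "selected_vs_nonselected_test",
    "rank_correlation",
    "annotate_loci",
    "mark_selected_windows",
]

WINDOW_SIZE = 4


@dataclass
class WindowTable:
    """Per-window table: coordinates, HF_ST components, flags and bins."""

    table: pd.DataFrame

    def __getattr__(self, name):
        return getattr(self.table, name)

    def __len__(self) -> int:
        return len(self.table)

    def valid(self) -> pd.DataFrame:
        """Windows retained after filtering and with a defined HF_ST."""
        t = self.table
        mask = ~t["removed"]
        if "monomorphic" in t:
            mask &= ~t["monomorphic"]
        return t[mask]


@dataclass
class HfstResult:
    """Ratio-of-averages population HF_ST over retained windows."""

    hfst: float
    numerator_sum: float
    denominator_sum: float
    n_windows: int


def make_windows(dataset: HaplotypeDataset) -> WindowTable:
    """Partition every chromosome into consecutive 4-SNP windows.

    Trailing SNPs that do not fill a window are dropped. bp and cM spans
    run from the first to the last SNP of the window, inclusive.
    """
    rows = []
    for c in range(dataset.n_chrom):
        s = dataset.haplotypes[c].shape[1]
        n_win = s // WINDOW_SIZE
        if n_win == 0:
            continue
        bp = dataset.positions_bp[c]
        cm = dataset.positions_cm[c]
        for w in range(n_win):
            a, b = w * WINDOW_SIZE, (w + 1) * WINDOW_SIZE - 1
            rows.append((dataset.chromosomes[c], c, w, a, b,
                         int(bp[a]), int(bp[b]),
                         int(bp[b]) - int(bp[a]), float(cm[b] - cm[a])))
    table = pd.DataFrame(rows, columns=[
        "chromosome", "chrom_index", "window", "snp_start", "snp_end",
        "bp_start", "bp_end", "bp_span", "cm_span",
    ])
    table["removed"] = False
    return WindowTable(table)


def filter_outlier_windows(windows: WindowTable, n_sd: float = 3.0) -> WindowTable:
    """Remove windows whose log(bp) or log(cM) span is an outlier.

    A window is removed when its log-span deviates from the mean by more
    than ``n_sd`` standard deviations in EITHER scale. Statistics are
    computed once on the pre-filter table (single pass; re-applying can
    remove more). Zero-length spans are excluded from the log statistics
    and removed. With zero SD in a scale, no window is removed on that
    scale.
    """
    t = windows.table.copy()
    if len(t) < 2:
        raise ValueError("need at least two windows")
    removed = t["removed"].to_numpy().copy()
    for col in ("bp_span", "cm_span"):
        span = t[col].to_numpy(dtype=float)
        positive = span > 0
        removed |= ~positive
        logs = np.log(span[positive])
        mu, sd = logs.mean(), logs.std(ddof=0)
        if sd > 0:
            z = np.zeros(len(t))
            z[positive] = np.abs(np.log(span[positive]) - mu) / sd
            removed |= z > n_sd
    t["removed"] = removed
    return WindowTable(t)


def _haploid_variance_components(counts: np.ndarray) -> tuple:
    """Weir–Cockerham-style haploid variance components.

    ``counts``: (r populations, ..., u alleles) haplotype counts. Returns
    (numerator, denominator) summed over alleles, broadcast over any
    middle axes. With r populations of n_i haplotypes:

        n_c    = (n - Σn_i²/n) / (r - 1)
        MSP_u  = Σ_i n_i (p_iu - p̄_u)² / (r - 1)
        MSG_u  = Σ_i n_i p_iu (1 - p_iu) / Σ(n_i - 1)
        num    = Σ_u (MSP_u - MSG_u) / n_c
        den    = Σ_u (MSP_u + (n_c - 1) MSG_u) / n_c
    """
    counts = np.asarray(counts, dtype=float)
    r = counts.shape[0]
    n_i = counts.sum(axis=-1)  # (r, ...)
    if np.any(n_i < 2):
        raise ValueError("every population needs at least 2 haplotypes")
    n = n_i.sum(axis=0)
    n_c = (n - (n_i**2).sum(axis=0) / n) / (r - 1)
    p = counts / n_i[..., None]
    p_bar = (n_i[..., None] * p).sum(axis=0) / n[..., None]
    msp = (n_i[..., None] * (p - p_bar[None]) ** 2).sum(axis=0) / (r - 1)
    msg = (n_i[..., None] * p * (1 - p)).sum(axis=0) / (n_i - 1).sum(axis=0)[..., None]
    num = ((msp - msg) / n_c[..., None]).sum(axis=-1)
    den = ((msp + (n_c[..., None] - 1) * msg) / n_c[..., None]).sum(axis=-1)
    return num, den


def window_hfst(pop_haplotype_counts) -> tuple:
    """(numerator, denominator) for one window from per-population counts.

    ``pop_haplotype_counts``: (r, u) array of counts of each distinct
    window haplotype ("allele") per population. HF_ST = num / den; a zero
    denominator (window monomorphic across all populations) leaves HF_ST
    undefined.
    """
    counts = np.atleast_2d(np.asarray(pop_haplotype_counts, dtype=float))
    if counts.shape[0] < 2:
        raise ValueError("need at least 2 populations")
    num, den = _haploid_variance_components(counts)
    return float(num), float(den)


def _window_allele_codes(haps: np.ndarray, snp_start: np.ndarray) -> np.ndarray:
    """Encode each 4-SNP window haplotype as an integer allele 0..15."""
    weights = 1 << np.arange(WINDOW_SIZE - 1, -1, -1)
    idx = snp_start[:, None] + np.arange(WINDOW_SIZE)[None, :]  # (W, 4)
    return np.einsum("hwk,k->hw", haps[:, idx], weights)  # (H, W)


def window_hfst_table(
    dataset: HaplotypeDataset,
    populations: list,
    windows: WindowTable | None = None,
) -> WindowTable:
    """Per-window HF_ST components between the given population labels.

    Vectorised over windows: window haplotypes are encoded as 4-bit
    alleles, counted per population, and the haploid variance components
    evaluated for all windows at once. Adds ``numerator``,
    ``denominator``, ``hfst`` and ``monomorphic`` columns.
    """
    if windows is None:
        windows = make_windows(dataset)
    t = windows.table.copy()
    labels = np.asarray(dataset.population_labels)
    hap_labels = np.repeat(labels, 2)
    masks = []
    for pop in populations:
        m = hap_labels == pop
        if m.sum() < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 haplotypes")
        masks.append(m)

    num = np.full(len(t), np.nan)
    den = np.full(len(t), np.nan)
    for c in sorted(t["chrom_index"].unique()):
        sel = t["chrom_index"] == c
        starts = t.loc[sel, "snp_start"].to_numpy()
        codes = _window_allele_codes(dataset.haplotypes[c], starts)  # (H, W)
        n_win = len(starts)
        counts = np.zeros((len(populations), n_win, 1 << WINDOW_SIZE))
        offsets = np.arange(n_win) * (1 << WINDOW_SIZE)
        for k, m in enumerate(masks):
            flat = (codes[m] + offsets[None, :]).ravel()
            counts[k] = np.bincount(flat, minlength=n_win * (1 << WINDOW_SIZE)
                                    ).reshape(n_win, 1 << WINDOW_SIZE)
        num[sel], den[sel] = _haploid_variance_components(counts)

    t["numerator"] = num
    t["denominator"] = den
    t["monomorphic"] = den == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        t["hfst"] = np.where(den != 0, num / den, np.nan)
    return WindowTable(t)


def population_hfst(windows: WindowTable) -> HfstResult:
    """Ratio-of-averages HF_ST over retained, non-monomorphic windows."""
    v = windows.valid()
    if "numerator" not in v:
        raise ValueError("windows carry no HF_ST components")
    den_sum = float(v["denominator"].sum())
    if len(v) == 0 or den_sum <= 0:
        raise ValueError("no valid windows with positive total denominator")
    num_sum = float(v["numerator"].sum())
    return HfstResult(num_sum / den_sum, num_sum, den_sum, len(v))


def pairwise_hfst_matrix(
    dataset: HaplotypeDataset,
    populations: list | None = None,
    min_cluster_size: int = 1,
    filter_outliers: bool = True,
) -> pd.DataFrame:
    """Symmetric matrix of pairwise population HF_ST.

    ``min_cluster_size`` drops populations with fewer individuals (the
    scan default elsewhere is 42 individuals; here the caller chooses).
    """
    labels = pd.Series(dataset.population_labels)
    if populations is None:
        populations = sorted(labels.unique())
    populations = [p for p in populations if (labels == p).sum() >= min_cluster_size]
    mat = pd.DataFrame(0.0, index=populations, columns=populations)
    base = make_windows(dataset)
    if filter_outliers:
        base = filter_outlier_windows(base)
    for i, a in enumerate(populations):
        for b in populations[i + 1:]:
            wt = window_hfst_table(dataset, [a, b], base)
            h = population_hfst(wt).hfst
            mat.loc[a, b] = mat.loc[b, a] = h
    return mat


def neighbor_joining(dist: pd.DataFrame) -> str:
    """Saitou–Nei neighbor joining on a pairwise distance matrix.

    Returns an unrooted tree in Newick format. Negative branch lengths
    are retained as computed. Ties in the Q matrix are broken toward the
    lexicographically smallest taxon pair, making the output
    deterministic under taxon permutation.
    """
    d = dist.copy().astype(float)
    if np.isnan(d.values).any():
        raise ValueError("NaN distances")
    if not np.allclose(d.values, d.values.T):
        raise ValueError("distance matrix must be symmetric")
    if len(d) < 3:
        raise ValueError("need at least 3 taxa")
    nodes = {t: str(t) for t in d.index}

    while len(d) > 3:
        taxa = list(d.index)
        n = len(taxa)
        total = d.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d.iloc[i, j] - total.iloc[i] - total.iloc[j]
                key = (q, *sorted((str(taxa[i]), str(taxa[j]))))
                if best is None or key < best[0]:
                    best = (key, taxa[i], taxa[j])
        _, a, b = best
        dab = d.loc[a, b]
        la = 0.5 * dab + (total[a] - total[b]) / (2 * (n - 2))
        lb = dab - la
        new = f"__{a}__{b}"
        nodes[new] = f"({nodes[a]}:{la:.10g},{nodes[b]}:{lb:.10g})"
        rest = [t for t in taxa if t not in (a, b)]
        new_d = 0.5 * (d.loc[rest, a] + d.loc[rest, b] - dab)
        d = d.loc[rest, rest]
        d[new] = new_d
        d.loc[new] = new_d.reindex(d.index).fillna(0.0)
        d.loc[new, new] = 0.0
        del nodes[a], nodes[b]

    (a, b, c) = list(d.index)
    # three-point formulas for the final star
    la = 0.5 * (d.loc[a, b] + d.loc[a, c] - d.loc[b, c])
    lb = 0.5 * (d.loc[a, b] + d.loc[b, c] - d.loc[a, c])
    lc = 0.5 * (d.loc[a, c] + d.loc[b, c] - d.loc[a, b])
    return f"({nodes[a]}:{la:.10g},{nodes[b]}:{lb:.10g},{nodes[c]}:{lc:.10g});"


def bin_windows(windows: WindowTable, n_bins: int = 20) -> WindowTable:
    """Sort valid windows by HF_ST into equal-count bins.

    Stable ascending sort (ties keep genomic order); the windows are
    split into ``n_bins`` contiguous groups whose sizes differ by at
    most one, the first ``remainder`` bins getting the extra window.
    Bin 1 holds the lowest HF_ST, bin ``n_bins`` the highest. Removed
    and monomorphic windows get no bin.
    """
    t = windows.table.copy()
    valid_idx = windows.valid().index
    n_valid = len(valid_idx)
    if n_valid < n_bins:
        raise ValueError(f"fewer valid windows ({n_valid}) than bins ({n_bins})")
    order = valid_idx[np.argsort(t.loc[valid_idx, "hfst"].to_numpy(), kind="stable")]
    base, rem = divmod(n_valid, n_bins)
    sizes = np.full(n_bins, base)
    sizes[:rem] += 1
    bins = np.repeat(np.arange(1, n_bins + 1), sizes)
    t["bin"] = pd.Series(pd.NA, index=t.index, dtype="Int64")
    t.loc[order, "bin"] = bins
    return WindowTable(t)


def mark_selected_windows(windows: WindowTable, regions: pd.DataFrame) -> WindowTable:
    """Flag windows overlapping positively-selected regions.

    ``regions`` is a BED-style frame with columns chromosome/start/end
    (0-based half-open). A window overlaps when its [bp_start-1, bp_end)
    interval intersects a region on the same chromosome.
    """
    t = windows.table.copy()
    sel = np.zeros(len(t), dtype=bool)
    for _, reg in regions.iterrows():
        same = t["chromosome"] == reg.iloc[0]
        # window as 0-based half-open: [bp_start - 1, bp_end)
        overlap = (t["bp_start"] - 1 < int(reg.iloc[2])) & (t["bp_end"] > int(reg.iloc[1]))
        sel |= (same & overlap).to_numpy()
    t["selected"] = sel
    return WindowTable(t)


def enrichment_by_bin(windows: WindowTable, alpha: float = 0.01) -> pd.DataFrame:
    """Per-bin selected-window proportion with one-sided Fisher tests.

    For each bin, the 2x2 table {in-bin vs out-of-bin} x {selected vs
    not} over valid binned windows is tested for enrichment (one-sided,
    'greater'); the significance flag uses the multiplicity-adjusted
    threshold ``alpha / n_bins`` (default 0.01/20 = 5e-4). The
    genome-wide average proportion is included on every row.
    """
    v = windows.valid()
    if "bin" not in v or v["bin"].isna().all():
        raise ValueError("windows are not binned")
    v = v[v["bin"].notna()]
    selected = v["selected"].to_numpy(dtype=bool)
    bins = v["bin"].to_numpy(dtype=int)
    n_bins = bins.max()
    genome_prop = selected.mean()
    threshold = alpha / n_bins
    rows = []
    for b in range(1, n_bins + 1):
        in_bin = bins == b
        a11 = int(np.sum(in_bin & selected))
        a12 = int(np.sum(in_bin & ~selected))
        a21 = int(np.sum(~in_bin & selected))
        a22 = int(np.sum(~in_bin & ~selected))
        if selected.any():
            _, p = stats.fisher_exact([[a11, a12], [a21, a22]], alternative="greater")
        else:
            p = 1.0
        rows.append((b, in_bin.sum(), a11, a11 / in_bin.sum(), p, p < threshold))
    out = pd.DataFrame(rows, columns=[
        "bin", "n_windows", "n_selected", "prop_selected", "p_fisher", "significant",
    ])
    out["genome_prop"] = genome_prop
    out["threshold"] = threshold
    return out


def selected_vs_nonselected_test(hfst: np.ndarray, selected: np.ndarray) -> tuple:
    """Mann-Whitney two-sided p and direction for HF_ST by selection status.

    Exact enumeration for small groups (both <= 20), tie-corrected
    normal approximation otherwise. Direction is the sign of the median
    difference (selected minus non-selected).
    """
    hfst = np.asarray(hfst, dtype=float)
    selected = np.asarray(selected, dtype=bool)
    a, b = hfst[selected], hfst[~selected]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if max(len(a), len(b)) <= 20 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    direction = int(np.sign(np.median(a) - np.median(b)))
    return float(res.pvalue), direction


def rank_correlation(hfst_a: np.ndarray, hfst_b: np.ndarray) -> tuple:
    """Spearman rho (average ranks for ties) and t-approximation p."""
    a = np.asarray(hfst_a, dtype=float)
    b = np.asarray(hfst_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two aligned vectors of >= 3 windows")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant vector")
    res = stats.spearmanr(a, b)
    return float(res.statistic), float(res.pvalue)


def annotate_loci(windows: WindowTable, loci: pd.DataFrame) -> pd.DataFrame:
    """Map named loci (BED-style: chrom, start, end, name) to HF_ST bins.

    A locus overlapping several windows reports the bin of the
    maximum-HF_ST overlapping window; loci on uncovered chromosomes are
    reported as unmapped (bin <NA>), not an error.
    """
    if loci.shape[1] < 4:
        raise ValueError("loci need 4 BED columns: chrom, start, end, name")
    t = windows.table
    rows = []
    for _, reg in loci.iterrows():
        chrom, start, end, name = reg.iloc[0], int(reg.iloc[1]), int(reg.iloc[2]), reg.iloc[3]
        hit = t[(t["chromosome"] == chrom)
                & (t["bp_start"] - 1 < end) & (t["bp_end"] > start)
                & t["bin"].notna()] if "bin" in t else t.iloc[0:0]
        if len(hit) == 0:
            rows.append((name, chrom, pd.NA, np.nan))
        else:
            best = hit.loc[hit["hfst"].idxmax()]
            rows.append((name, chrom, int(best["bin"]), float(best["hfst"])))
    return pd.DataFrame(rows, columns=["name", "chromosome", "bin", "hfst"])
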