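"""Synthetic phased-haplotype and coancestry generators.

The generators emulate the statistical structure the downstream stages
assume: clusters of individuals whose allele frequencies have drifted
apart from a common ancestral pool (Balding–Nichols), haplotype sharing
induced by mosaic copying from per-cluster founder pools, admixed target
clusters whose mosaic segments are drawn from a designated mixture over
donor clusters, and implanted low-diversity (sweep-like) windows that
are either concordant or discordant with between-cluster differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimConfig",
    "HaplotypeDataset",
    "SweepRecord",
    "SimulatedCoancestry",
    "simulate_haplotypes",
    "implant_sweep",
    "simulate_coancestry",
    "draw_cluster_frequencies",
]


@dataclass
class SimConfig:
    """Parameters of the haplotype simulator.

    Parameters
    ----------
    n_clusters : int
        Number of clusters (named ``pop0``, ``pop1``, ...).
    n_per_cluster : list of int
        Diploid individuals per cluster.
    n_chrom : int
        Number of chromosomes.
    snps_per_chrom : int
        SNPs per chromosome (>= 8).
    drift_f : list of float
        Per-cluster Balding–Nichols drift parameter F in [0, 1).
    mixture : dict, optional
        Maps a target cluster index to a length-``n_clusters`` row of
        ancestry weights over donor clusters (non-negative, sums to 1).
        Clusters without a row copy only from their own founder pool.
    sweep_windows : list of tuple, optional
        ``(chromosome index, window index, affected cluster indices)``
        specs consumed by :func:`implant_sweep`.
    seed : int
        Seed for all randomness.
    n_founders : int
        Founder haplotypes per cluster in the mosaic copying pool.
    mean_segment_snps : float
        Mean (geometric) mosaic segment length in SNPs. Default 20,
        the order of magnitude of chunk sizes seen in dense-array
        painting (tens of SNPs per chunk).
    snp_spacing_bp : int
        Uniform physical spacing between SNPs.
    """

    n_clusters: int
    n_per_cluster: list
    n_chrom: int
    snps_per_chrom: int
    drift_f: list
    mixture: dict | None = None
    sweep_windows: list = field(default_factory=list)
    seed: int = 0
    n_founders: int = 30
    mean_segment_snps: float = 20.0
    snp_spacing_bp: int = 5000

    def __post_init__(self) -> None:
        if len(self.n_per_cluster) != self.n_clusters:
            raise ValueError("n_per_cluster length must equal n_clusters")
        if len(self.drift_f) != self.n_clusters:
            raise ValueError("drift_f length must equal n_clusters")
        if any(n <= 0 for n in self.n_per_cluster):
            raise ValueError("all cluster sizes must be positive")
        if self.n_chrom <= 0 or self.snps_per_chrom <= 0:
            raise ValueError("counts must be positive")
        if self.snps_per_chrom < 8:
            raise ValueError("snps_per_chrom must be >= 8")
        if any(not (0.0 <= f < 1.0) for f in self.drift_f):
            raise ValueError("drift_f must lie in [0, 1)")
        if self.mixture is not None:
            for k, row in self.mixture.items():
                row = np.asarray(row, dtype=float)
                if not (0 <= k < self.n_clusters):
                    raise ValueError(f"mixture refers to unknown cluster {k}")
                if row.shape != (self.n_clusters,):
                    raise ValueError("mixture rows must have one weight per cluster")
                if (row < 0).any():
                    raise ValueError("mixture weights must be non-negative")
                if abs(row.sum() - 1.0) > 1e-12:
                    raise ValueError("mixture rows must sum to 1")


@dataclass
class HaplotypeDataset:
    """Phased diploid haplotypes with per-chromosome SNP coordinates.

    ``haplotypes[c]`` is a ``(2N, S_c)`` 0/1 matrix; rows ``2k`` and
    ``2k + 1`` are the two haplotypes of individual ``k``.
    """

    haplotypes: list  # per-chromosome (2N, S) uint8 arrays
    positions_bp: list  # per-chromosome strictly increasing int arrays
    positions_cm: list  # per-chromosome non-decreasing float arrays
    individual_ids: list
    population_labels: list
    chromosomes: list = None  # chromosome names
    cluster_frequencies: list = None  # per-chromosome (K, S) latent freqs

    def __post_init__(self) -> None:
        if self.chromosomes is None:
            self.chromosomes = [f"chr{i + 1}" for i in range(len(self.haplotypes))]
        n = len(self.individual_ids)
        for h in self.haplotypes:
            if h.shape[0] != 2 * n:
                raise ValueError("haplotype row count must be 2 x n_individuals")
        for bp in self.positions_bp:
            if np.any(np.diff(bp) <= 0):
                raise ValueError("bp positions must be strictly increasing")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_chrom(self) -> int:
        return len(self.haplotypes)

    def copy(self) -> "HaplotypeDataset":
        return HaplotypeDataset(
            [h.copy() for h in self.haplotypes],
            [p.copy() for p in self.positions_bp],
            [p.copy() for p in self.positions_cm],
            list(self.individual_ids),
            list(self.population_labels),
            list(self.chromosomes),
            None if self.cluster_frequencies is None
            else [f.copy() for f in self.cluster_frequencies],
        )


@dataclass
class SweepRecord:
    """BED-style record of an implanted sweep region (0-based half-open)."""

    chromosome: str
    start_bp: int
    end_bp: int
    name: str


def draw_cluster_frequencies(p: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """Balding–Nichols cluster allele frequencies.

    Drawn from a Beta with mean ``p`` and variance ``f * p * (1 - p)``,
    i.e. Beta(p (1-f)/f, (1-p)(1-f)/f). ``f = 0`` returns ``p`` itself.
    """
    if f == 0.0:
        return p.copy()
    scale = (1.0 - f) / f
    return rng.beta(p * scale, (1.0 - p) * scale)


def _segment_lengths(total: int, mean_len: float, rng: np.random.Generator) -> np.ndarray:
    """Geometric mosaic segment lengths covering exactly ``total`` SNPs."""
    n_guess = max(8, int(2 * total / mean_len) + 8)
    lens = rng.geometric(1.0 / mean_len, size=n_guess)
    while lens.sum() < total:
        lens = np.concatenate([lens, rng.geometric(1.0 / mean_len, size=n_guess)])
    cut = np.searchsorted(np.cumsum(lens), total) + 1
    lens = lens[:cut]
    lens[-1] -= lens.sum() - total
    return lens


def simulate_haplotypes(config: SimConfig) -> HaplotypeDataset:
    """Simulate phased haplotypes for drifted, optionally admixed clusters.

    Ancestral frequencies are Uniform(0.05, 0.95); each cluster's
    frequencies are Balding–Nichols draws around them; per cluster a
    founder pool of ``n_founders`` haplotypes is drawn site-wise from the
    cluster frequencies; each sample haplotype is a mosaic of founder
    segments (geometric lengths) whose source cluster is the own cluster,
    or — for clusters with a mixture row — drawn from that row. The
    construction makes within-cluster haplotype sharing exceed
    between-cluster sharing, which is what painting then measures.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_clusters
    n_ind = int(np.sum(config.n_per_cluster))
    labels = []
    for c, n in enumerate(config.n_per_cluster):
        labels.extend([f"pop{c}"] * n)
    ids = [f"ind{i:04d}" for i in range(n_ind)]
    cluster_of_ind = np.repeat(np.arange(k), config.n_per_cluster)

    haplos, bps, cms, freqs = [], [], [], []
    s = config.snps_per_chrom
    for _c in range(config.n_chrom):
        p = rng.uniform(0.05, 0.95, size=s)
        q = np.stack([draw_cluster_frequencies(p, config.drift_f[g], rng) for g in range(k)])
        founders = (rng.random((k, config.n_founders, s)) < q[:, None, :]).astype(np.uint8)
        haps = np.empty((2 * n_ind, s), dtype=np.uint8)
        for i in range(n_ind):
            g = cluster_of_ind[i]
            mix = None
            if config.mixture is not None and g in config.mixture:
                mix = np.asarray(config.mixture[g], dtype=float)
            for h in range(2):
                lens = _segment_lengths(s, config.mean_segment_snps, rng)
                if mix is None:
                    src_cluster = np.full(len(lens), g)
                else:
                    src_cluster = rng.choice(k, size=len(lens), p=mix)
                src_founder = rng.integers(0, config.n_founders, size=len(lens))
                src_c = np.repeat(src_cluster, lens)
                src_f = np.repeat(src_founder, lens)
                haps[2 * i + h] = founders[src_c, src_f, np.arange(s)]
        bp = (np.arange(s) + 1) * config.snp_spacing_bp
        haplos.append(haps)
        bps.append(bp)
        cms.append(bp * 1e-6)  # 1 cM/Mb default map
        freqs.append(q)

    return HaplotypeDataset(haplos, bps, cms, ids, labels, None, freqs)


def implant_sweep(
    dataset: HaplotypeDataset,
    windows: list,
    mode: str = "concordant",
    window_size: int = 4,
    carrier_fraction: float = 0.95,
    seed: int = 0,
) -> tuple:
    """Implant sweep-like low-diversity windows; returns (dataset, BED records).

    ``windows`` is a list of ``(chrom_index, window_index, affected cluster
    labels)``; the window covers SNPs ``[w * window_size, (w+1) * window_size)``.
    In ``"concordant"`` mode each affected cluster is driven to (near)
    fixation for a distinct haplotype, raising local differentiation; in
    ``"discordant"`` mode all affected clusters are fixed for the SAME
    haplotype, removing local differentiation. ``carrier_fraction`` of the
    haplotypes in each affected cluster carry the sweep haplotype.
    """
    if mode not in ("concordant", "discordant"):
        raise ValueError(f"unknown mode {mode!r}")
    out = dataset.copy()
    rng = np.random.default_rng(seed)
    pops = np.asarray(out.population_labels)
    records = []
    for chrom_idx, win_idx, clusters in windows:
        if chrom_idx >= out.n_chrom:
            raise ValueError(f"chromosome index {chrom_idx} out of range")
        haps = out.haplotypes[chrom_idx]
        s0, s1 = win_idx * window_size, (win_idx + 1) * window_size
        if s1 > haps.shape[1]:
            raise ValueError(f"window index {win_idx} out of range")
        if isinstance(clusters, str):
            clusters = [clusters]
        # distinct sweep haplotypes per cluster in concordant mode; one shared
        # haplotype in discordant mode
        shared = rng.integers(0, 2, size=window_size).astype(np.uint8)
        for ci, cl in enumerate(clusters):
            if cl not in pops:
                raise ValueError(f"unknown cluster {cl!r}")
            if mode == "concordant":
                sweep_hap = np.zeros(window_size, dtype=np.uint8)
                sweep_hap[ci % window_size] = 1  # distinct per cluster
            else:
                sweep_hap = shared
            ind_mask = pops == cl
            hap_rows = np.repeat(ind_mask, 2)
            rows = np.flatnonzero(hap_rows)
            n_carrier = int(round(carrier_fraction * len(rows)))
            carriers = rng.choice(rows, size=n_carrier, replace=False)
            haps[np.ix_(carriers, np.arange(s0, s1))] = sweep_hap
        bp = out.positions_bp[chrom_idx]
        records.append(
            SweepRecord(out.chromosomes[chrom_idx], int(bp[s0]) - 1, int(bp[s1 - 1]),
                        f"sweep_{mode}_{chrom_idx}_{win_idx}")
        )
    return out, records


@dataclass
class SimulatedCoancestry:
    """Direct multinomial generator output for profile-recovery tests.

    Rows: donor-cluster recipients first, then target recipients; columns:
    donor individuals. ``truth`` holds the generating profile rows.
    """

    values: np.ndarray
    per_chromosome: list
    recipient_ids: list
    donor_ids: list
    assignment: dict  # recipient id -> cluster label
    donor_assignment: dict  # donor id -> donor cluster label
    truth: np.ndarray  # (n_targets, G)
    target_labels: list
    donor_labels: list


def simulate_coancestry(
    n_per_cluster: list,
    profile_matrix,
    chunks_per_recipient: int,
    noise_seed: int = 0,
    n_per_target: int = 30,
    n_chrom: int = 1,
) -> SimulatedCoancestry:
    """Draw coancestry rows directly from known ancestry profiles.

    Each recipient's row over donor individuals is Multinomial with
    expected share ``beta_g / n_g`` to each member of donor cluster ``g``.
    Donor-cluster members are themselves recipients whose chunks go
    uniformly to the *other* members of their own cluster (self-copying
    forbidden), so per-cluster characteristic rows have exactly the
    uniform ``1 / n_g`` column expectation. With ``n_chrom > 1`` chunks
    are split evenly over chromosomes (for chromosome-block bootstrap).
    """
    if chunks_per_recipient < 1:
        raise ValueError("chunks_per_recipient must be >= 1")
    profile = np.atleast_2d(np.asarray(profile_matrix, dtype=float))
    g = len(n_per_cluster)
    if profile.shape[1] != g:
        raise ValueError("profile rows must have one weight per donor cluster")
    if (profile < 0).any() or np.any(np.abs(profile.sum(axis=1) - 1) > 1e-9):
        raise ValueError("profile rows must be non-negative and sum to 1")
    rng = np.random.default_rng(noise_seed)

    donor_labels = [f"D{j}" for j in range(g)]
    target_labels = [f"T{t}" for t in range(profile.shape[0])]
    donor_ids, donor_assignment = [], {}
    for j, n in enumerate(n_per_cluster):
        for m in range(n):
            did = f"d{j}_{m}"
            donor_ids.append(did)
            donor_assignment[did] = donor_labels[j]
    n_donors = len(donor_ids)
    donor_cluster_idx = np.repeat(np.arange(g), n_per_cluster)

    rows, recipient_ids, assignment = [], [], {}
    # donor-cluster recipients: uniform over own cluster minus self
    for i, did in enumerate(donor_ids):
        j = donor_cluster_idx[i]
        prob = np.zeros(n_donors)
        own = donor_cluster_idx == j
        prob[own] = 1.0 / (n_per_cluster[j] - 1) if n_per_cluster[j] > 1 else 0.0
        prob[i] = 0.0
        if prob.sum() == 0:  # singleton donor cluster: spread uniformly elsewhere
            prob[~own] = 1.0
        prob /= prob.sum()
        rows.append(prob)
        recipient_ids.append(did)
        assignment[did] = donor_labels[j]
    # target recipients
    for t, beta in enumerate(profile):
        share = beta[donor_cluster_idx] / np.asarray(n_per_cluster, dtype=float)[donor_cluster_idx]
        share /= share.sum()
        for m in range(n_per_target):
            rid = f"t{t}_{m}"
            rows.append(share)
            recipient_ids.append(rid)
            assignment[rid] = target_labels[t]

    probs = np.asarray(rows)
    chunks_per_chrom = np.full(n_chrom, chunks_per_recipient // n_chrom)
    chunks_per_chrom[: chunks_per_recipient % n_chrom] += 1
    per_chrom = []
    for c in range(n_chrom):
        mat = np.empty_like(probs)
        for r in range(probs.shape[0]):
            mat[r] = rng.multinomial(chunks_per_chrom[c], probs[r])
        per_chrom.append(mat)
    values = np.sum(per_chrom, axis=0)
    return SimulatedCoancestry(
        values, per_chrom, recipient_ids, donor_ids, assignment,
        donor_assignment, profile, target_labels, donor_labels,
    )
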