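"""Haplotype painting and coancestry matrices.

A recipient haplotype is "painted" as a patchwork of donor haplotype
chunks: the segmentation minimising

    mismatch_cost * (allele mismatches) + switch_cost * (donor switches)

computed exactly by dynamic programming. Chunk counts (or summed cM
chunk lengths) aggregated over recipients and donors give the coancestry
matrix a_ij: the amount of genome recipient i copies from donor j, a
natural summary of haplotype sharing. This deterministic min-cost
segmentation preserves the chunk semantics the downstream statistics
need; it is intentionally simpler than (and not equivalent to) the
Li–Stephens HMM used by ChromoPainter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simdata import HaplotypeDataset

__all__ = [
    "PaintingParams",
    "CoancestryMatrix",
    "Chunk",
    "paint_chromosome",
    "build_coancestry",
    "read_chunk_matrix",
    "write_chunk_matrix",
    "apply_submatrix_scaling",
    "estimate_submatrix_scaling",
]


@dataclass
class PaintingParams:
    """Costs of the min-cost segmentation painter.

    switch_cost : cost of switching donor between adjacent SNPs.
    mismatch_cost : cost per allele mismatch against the copied donor.
    donor_set : optional list of individual ids allowed as donors.
    """

    switch_cost: float = 1.0
    mismatch_cost: float = 1.0
    donor_set: list | None = None

    def __post_init__(self) -> None:
        if self.switch_cost <= 0 or self.mismatch_cost <= 0:
            raise ValueError("costs must be positive")


@dataclass
class Chunk:
    donor: int  # donor row index in the donor matrix
    start: int  # first SNP index (inclusive)
    end: int  # last SNP index (inclusive)


@dataclass
class CoancestryMatrix:
    """Chunk counts (or summed cM lengths) donated from j to recipient i.

    Square in the usual all-vs-all painting (zero diagonal, self-copying
    forbidden); rectangular when recipients and donors differ (e.g. a
    target population painted against external donors only).
    """

    values: np.ndarray
    recipient_ids: list
    donor_ids: list = None
    mode: str = "chunk_counts"
    per_chromosome: list = None
    chromosomes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.donor_ids is None:
            self.donor_ids = list(self.recipient_ids)
        if self.values.shape != (len(self.recipient_ids), len(self.donor_ids)):
            raise ValueError("values shape does not match id lists")
        if self.mode not in ("chunk_counts", "chunk_lengths_cM"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if (self.values < 0).any():
            raise ValueError("coancestry values must be non-negative")
        if self.is_square:
            same = [i for i, r in enumerate(self.recipient_ids) if r == self.donor_ids[i]]
            if same and np.any(np.abs(np.diag(self.values)[same]) > 0):
                raise ValueError("diagonal must be zero (self-copying forbidden)")
        if self.per_chromosome is not None:
            total = np.sum(self.per_chromosome, axis=0)
            if not np.allclose(total, self.values, atol=1e-9):
                raise ValueError("per-chromosome matrices must sum to the total")

    @property
    def is_square(self) -> bool:
        return list(self.recipient_ids) == list(self.donor_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.recipient_ids, columns=self.donor_ids)


def _mismatch_matrix(recipient: np.ndarray, donors: np.ndarray) -> np.ndarray:
    return (donors != recipient[None, :]).astype(float)


def paint_chromosome(
    recipient_hap: np.ndarray, donor_haps: np.ndarray, params: PaintingParams
) -> list:
    """Min-cost segmentation of a recipient against donor haplotypes.

    Returns the list of :class:`Chunk` of the segmentation minimising
    ``mismatch_cost * mismatches + switch_cost * switches``, computed by
    dynamic programming over (site, donor) states. Ties are broken toward
    the lowest donor index, then toward the earlier switch point.
    Adjacent chunks copied from the same donor row are merged.
    """
    recipient = np.asarray(recipient_hap)
    donors = np.atleast_2d(np.asarray(donor_haps))
    if donors.shape[0] == 0:
        raise ValueError("empty donor set")
    if donors.shape[1] != recipient.shape[0]:
        raise ValueError("donor haplotypes must match recipient length")
    s = recipient.shape[0]
    mis = params.mismatch_cost * _mismatch_matrix(recipient, donors)

    # forward DP: cost[d] = best cost of a path ending at site t copying d
    cost = mis[:, 0].copy()
    # came_from[t, d]: donor at t-1 on the best path into (t, d); -1 = stay
    came_from = np.full((s, donors.shape[0]), -1, dtype=np.int64)
    for t in range(1, s):
        best_prev = np.argmin(cost)  # argmin returns lowest index on ties
        switch_cost_t = cost[best_prev] + params.switch_cost
        stay = cost
        # strict '<' keeps 'stay' on ties -> pushes switches earlier
        switch_better = switch_cost_t < stay
        came_from[t, switch_better] = best_prev
        cost = np.where(switch_better, switch_cost_t, stay) + mis[:, t]

    d = int(np.argmin(cost))
    chunks: list[Chunk] = []
    end = s - 1
    for t in range(s - 1, 0, -1):
        prev = came_from[t, d]
        if prev >= 0:
            chunks.append(Chunk(d, t, end))
            end = t - 1
            d = int(prev)
    chunks.append(Chunk(d, 0, end))
    chunks.reverse()
    # merge adjacent chunks copied from the same donor
    merged: list[Chunk] = []
    for ch in chunks:
        if merged and merged[-1].donor == ch.donor:
            merged[-1].end = ch.end
        else:
            merged.append(ch)
    return merged


def painting_cost(recipient_hap, donor_haps, chunks, params: PaintingParams) -> float:
    """Total cost of a given segmentation (used by tests as a cross-check)."""
    recipient = np.asarray(recipient_hap)
    donors = np.atleast_2d(np.asarray(donor_haps))
    cost = params.switch_cost * (len(chunks) - 1)
    for ch in chunks:
        seg = slice(ch.start, ch.end + 1)
        cost += params.mismatch_cost * np.sum(donors[ch.donor, seg] != recipient[seg])
    return float(cost)


def _chunk_cm_lengths(chunks: list, cm: np.ndarray) -> np.ndarray:
    """cM length per chunk; chunk boundaries at midpoints between SNPs.

    The lengths partition the chromosome's total cM span exactly.
    """
    bounds = np.empty(len(chunks) + 1)
    bounds[0] = cm[0]
    bounds[-1] = cm[-1]
    for i in range(1, len(chunks)):
        left_end = chunks[i - 1].end
        right_start = chunks[i].start
        bounds[i] = 0.5 * (cm[left_end] + cm[right_start])
    return np.diff(bounds)


def build_coancestry(
    dataset: HaplotypeDataset,
    params: PaintingParams | None = None,
    mode: str = "chunk_counts",
) -> CoancestryMatrix:
    """Paint every individual against all others; aggregate chunks to a_ij.

    Both haplotypes of each recipient are painted against both haplotypes
    of every donor individual (excluding the recipient itself, and
    restricted to ``params.donor_set`` if given). ``a_ij`` is the number
    of chunks copied from either haplotype of ``j`` (``chunk_counts``) or
    their summed cM length (``chunk_lengths_cM``). Per-chromosome
    matrices are retained and sum to the total.
    """
    if params is None:
        params = PaintingParams()
    if mode not in ("chunk_counts", "chunk_lengths_cM"):
        raise ValueError(f"unknown mode {mode!r}")
    n = dataset.n_individuals
    ids = dataset.individual_ids
    donor_pool = set(params.donor_set) if params.donor_set is not None else set(ids)
    per_chrom = []
    for c in range(dataset.n_chrom):
        haps = dataset.haplotypes[c]
        cm = dataset.positions_cm[c]
        mat = np.zeros((n, n))
        for i in range(n):
            donor_inds = [j for j in range(n) if j != i and ids[j] in donor_pool]
            if not donor_inds:
                raise ValueError("empty donor set for recipient " + ids[i])
            donor_rows = np.array([[2 * j, 2 * j + 1] for j in donor_inds]).ravel()
            donors = haps[donor_rows]
            row_to_ind = np.repeat(donor_inds, 2)
            for h in range(2):
                chunks = paint_chromosome(haps[2 * i + h], donors, params)
                if mode == "chunk_counts":
                    for ch in chunks:
                        mat[i, row_to_ind[ch.donor]] += 1
                else:
                    lens = _chunk_cm_lengths(chunks, cm)
                    for ch, ln in zip(chunks, lens):
                        mat[i, row_to_ind[ch.donor]] += ln
        per_chrom.append(mat)
    total = np.sum(per_chrom, axis=0)
    return CoancestryMatrix(total, list(ids), list(ids), mode, per_chrom,
                            list(dataset.chromosomes))


def write_chunk_matrix(matrix: CoancestryMatrix, path) -> None:
    """Write a ChromoPainter-style chunkcounts/chunklengths TSV."""
    with open(path, "w") as fh:
        fh.write("Recipient " + " ".join(matrix.donor_ids) + "\n")
        for i, rid in enumerate(matrix.recipient_ids):
            vals = " ".join(repr(float(v)) for v in matrix.values[i])
            fh.write(f"{rid} {vals}\n")


def read_chunk_matrix(path, dialect: str = "chunkcounts") -> CoancestryMatrix:
    """Read a ChromoPainter-style matrix file.

    Expects a header row ``Recipient <donor ids...>`` and one numeric row
    per recipient. A missing self column is treated as zero donation.
    """
    if dialect not in ("chunkcounts", "chunklengths"):
        raise ValueError(f"unknown dialect {dialect!r}")
    mode = "chunk_counts" if dialect == "chunkcounts" else "chunk_lengths_cM"
    with open(path) as fh:
        header = fh.readline().split()
        if not header or header[0].lower() not in ("recipient", "#recipient"):
            raise ValueError("expected header starting with 'Recipient'")
        donor_ids = header[1:]
        if len(set(donor_ids)) != len(donor_ids):
            raise ValueError("duplicated donor IDs in header")
        recipients, rows = [], []
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            rid = parts[0]
            entries = parts[1:]
            if len(entries) != len(donor_ids):
                raise ValueError(
                    f"row for recipient {rid!r} has {len(entries)} entries, "
                    f"expected {len(donor_ids)}"
                )
            try:
                rows.append([float(x) for x in entries])
            except ValueError as exc:
                raise ValueError(f"non-numeric entry in row for {rid!r}") from exc
            recipients.append(rid)
        if len(set(recipients)) != len(recipients):
            raise ValueError("duplicated recipient IDs")
    return CoancestryMatrix(np.asarray(rows), recipients, donor_ids, mode)


def apply_submatrix_scaling(
    matrix: CoancestryMatrix, population: list, factor: float
) -> CoancestryMatrix:
    """Scale the within-population block of the coancestry matrix.

    Entries whose recipient AND donor both belong to ``population`` are
    multiplied by ``factor``; all other entries are unchanged. This is
    the correction applied when one population's within-population
    donation is inflated (e.g. by genotype imputation) relative to the
    trend of the other populations.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    members = set(population)
    unknown = members - set(matrix.recipient_ids) - set(matrix.donor_ids)
    if unknown:
        raise ValueError(f"unknown individuals: {sorted(unknown)}")
    rmask = np.array([r in members for r in matrix.recipient_ids])
    cmask = np.array([d in members for d in matrix.donor_ids])
    scale = np.ones_like(matrix.values)
    scale[np.ix_(rmask, cmask)] = factor
    per_chrom = None
    if matrix.per_chromosome is not None:
        per_chrom = [m * scale for m in matrix.per_chromosome]
    return CoancestryMatrix(
        matrix.values * scale, list(matrix.recipient_ids), list(matrix.donor_ids),
        matrix.mode, per_chrom, list(matrix.chromosomes),
    )


def estimate_submatrix_scaling(
    within_pop_averages: dict, sample_sizes: dict, target: str
) -> float:
    """Correction factor for one population's inflated within-pop donation.

    Fits a least-squares line of within-population average donation
    against sample size over the non-target populations, and returns
    predicted/observed for the target. Requires >= 3 reference
    populations and non-degenerate x values.
    """
    refs = [p for p in within_pop_averages if p != target]
    if target not in within_pop_averages:
        raise ValueError(f"target {target!r} not among populations")
    if len(refs) < 3:
        raise ValueError("need at least 3 non-target populations")
    x = np.array([sample_sizes[p] for p in refs], dtype=float)
    y = np.array([within_pop_averages[p] for p in refs], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: all sample sizes equal")
    slope, intercept = np.polyfit(x, y, 1)
    predicted = slope * sample_sizes[target] + intercept
    observed = within_pop_averages[target]
    if observed <= 0:
        raise ValueError("target within-population average must be positive")
    return max(float(predicted / observed), np.finfo(float).tiny)
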