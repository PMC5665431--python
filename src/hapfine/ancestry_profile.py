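"""Ancestry profiles: simplex-constrained mixture decomposition of
coancestry rows, with chromosome-block bootstrap inference.

A cluster's characteristic row Y (the mean coancestry row over its
recipients, indexed by donor individuals) is approximated as a mixture
of donor-cluster characteristic rows X_g:

    Y ≈ β₁X₁ + ... + β_G X_G,   β_g ≥ 0,  Σβ_g = 1.

β is the cluster's ancestry profile. Confidence intervals come from a
chromosome-block bootstrap: per chromosome, each target individual's
coancestry row is replaced by that of a uniformly re-drawn same-cluster
individual, the per-chromosome matrices re-summed and the profile
re-fitted (donor rows X stay fixed). Differences of contributions
between two clusters are tested by centring the bootstrap differences
at the observed difference and doubling the one-tailed tail proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .cluster_eval import ClusterModel

__all__ = [
    "CharacteristicRow",
    "AncestryProfile",
    "BootstrapProfiles",
    "cluster_mean_row",
    "fit_profile",
    "bootstrap_profiles",
    "profile_difference_test",
    "profile_ci",
]


@dataclass
class CharacteristicRow:
    """Mean coancestry row of a cluster's recipients over donor columns."""

    values: np.ndarray
    donor_ids: list
    cluster: str
    n_recipients: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.donor_ids),):
            raise ValueError("row length must match donor ids")
        if (self.values < 0).any():
            raise ValueError("coancestry entries must be non-negative")


@dataclass
class AncestryProfile:
    """Simplex mixture weights over donor clusters."""

    beta: np.ndarray
    donor_clusters: list
    target: str
    objective: float = np.nan

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if (self.beta < -1e-12).any():
            raise ValueError("beta must be non-negative")
        if abs(self.beta.sum() - 1.0) > 1e-9:
            raise ValueError("beta must sum to 1")


@dataclass
class BootstrapProfiles:
    """B bootstrap replicates of a profile (rows on the simplex)."""

    samples: np.ndarray  # (B, G)
    donor_clusters: list
    target: str
    seed: int

    @property
    def n_boot(self) -> int:
        return self.samples.shape[0]


def _rows_for(matrix, ids: list) -> np.ndarray:
    index = {r: i for i, r in enumerate(matrix.recipient_ids)}
    missing = [i for i in ids if i not in index]
    if missing:
        raise ValueError(f"recipients not in matrix: {missing}")
    return matrix.values[[index[i] for i in ids]]


def cluster_mean_row(
    matrix, clusters: ClusterModel, cluster: str, donor_ids: list | None = None
) -> CharacteristicRow:
    """Arithmetic mean of a cluster's coancestry rows over donor columns.

    ``donor_ids`` restricts the columns (e.g. to external donors,
    excluding the target cluster's own members); by default all matrix
    columns are kept.
    """
    members = clusters.members(cluster)
    if not members:
        raise ValueError(f"empty cluster {cluster!r}")
    rows = _rows_for(matrix, members)
    mean = rows.mean(axis=0)
    cols = list(matrix.donor_ids)
    if donor_ids is not None:
        col_index = {d: i for i, d in enumerate(cols)}
        missing = [d for d in donor_ids if d not in col_index]
        if missing:
            raise ValueError(f"donor columns not in matrix: {missing}")
        mean = mean[[col_index[d] for d in donor_ids]]
        cols = list(donor_ids)
    return CharacteristicRow(mean, cols, cluster, len(members))


def fit_profile(y: CharacteristicRow, xs: list) -> AncestryProfile:
    """Non-negative, sum-to-one least-squares mixture fit of Y on X_g's.

    Solved as unconstrained-sum NNLS on the system augmented with a
    heavy penalty row lam * (1, ..., 1) -> lam (lam = 1e4 * max|X|),
    followed by exact renormalisation onto the simplex.
    """
    if not xs:
        raise ValueError("need at least one donor cluster row")
    a = np.column_stack([x.values for x in xs])
    if a.shape[0] != y.values.shape[0]:
        raise ValueError("all rows must have the same donor columns")
    if a.shape[0] == 0:
        raise ValueError("zero-length characteristic rows")
    if not np.any(a):
        raise ValueError("all donor rows are zero")
    lam = 1e4 * np.abs(a).max()
    a_aug = np.vstack([a, lam * np.ones(a.shape[1])])
    y_aug = np.concatenate([y.values, [lam]])
    beta, _ = nnls(a_aug, y_aug)
    total = beta.sum()
    if total == 0:
        raise ValueError("degenerate fit: all coefficients zero")
    beta = beta / total
    resid = y.values - a @ beta
    return AncestryProfile(beta, [x.cluster for x in xs], y.cluster,
                           float(np.dot(resid, resid)))


def bootstrap_profiles(
    per_chrom: list,
    clusters: ClusterModel,
    target: str,
    donors_x: list,
    n_boot: int = 1000,
    seed: int = 0,
) -> BootstrapProfiles:
    """Chromosome-block bootstrap of a cluster's ancestry profile.

    ``per_chrom`` is a list of CoancestryMatrix (one per chromosome)
    sharing recipient/donor ids. For each replicate, for every target
    individual and chromosome independently, the individual's
    per-chromosome row is replaced by the same-chromosome row of a
    uniformly drawn same-cluster individual (with replacement); the
    matrices are summed, Y recomputed and the profile re-fitted against
    the FIXED donor rows ``donors_x``.
    """
    members = clusters.members(target)
    if not members:
        raise ValueError(f"empty target cluster {target!r}")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    donor_cols = donors_x[0].donor_ids
    # stack the target rows per chromosome once: (C, n_members, n_donor_cols)
    col_index = {d: i for i, d in enumerate(per_chrom[0].donor_ids)}
    cols = [col_index[d] for d in donor_cols]
    stacks = np.stack([_rows_for(m, members)[:, cols] for m in per_chrom])
    n_c, n_m, _ = stacks.shape
    samples = np.empty((n_boot, len(donors_x)))
    for b in range(n_boot):
        pick = rng.integers(0, n_m, size=(n_c, n_m))
        resampled = stacks[np.arange(n_c)[:, None], pick]  # (C, n_members, D)
        y = resampled.sum(axis=0).mean(axis=0)
        prof = fit_profile(CharacteristicRow(y, donor_cols, target, n_m), donors_x)
        samples[b] = prof.beta
    return BootstrapProfiles(samples, [x.cluster for x in donors_x], target, seed)


def profile_difference_test(
    beta_obs: float,
    gamma_obs: float,
    boot_beta: np.ndarray,
    boot_gamma: np.ndarray,
    floor: bool = False,
) -> float:
    """Two-sided bootstrap p for a difference of contributions.

    Null samples are the bootstrap differences centred at the observed
    difference, x_i = (β_i − γ_i) − (β − γ). The one-tailed proportion of
    x_i at least as extreme as the observed difference β − γ, in the
    direction of its sign, is doubled and capped at 1. With ``floor``
    a zero count reports 2/B instead of 0. Contributions may be sums
    over several donor clusters. Bootstrap vectors must be independent
    (or jointly drawn and paired by index).
    """
    boot_beta = np.asarray(boot_beta, dtype=float)
    boot_gamma = np.asarray(boot_gamma, dtype=float)
    if boot_beta.shape != boot_gamma.shape or boot_beta.ndim != 1:
        raise ValueError("bootstrap vectors must be 1-D and of equal length")
    n_boot = boot_beta.shape[0]
    if n_boot == 0:
        raise ValueError("empty bootstrap")
    d = beta_obs - gamma_obs
    x = (boot_beta - boot_gamma) - d
    count = int(np.sum(x >= d) if d >= 0 else np.sum(x <= d))
    if count == 0 and floor:
        count = 1
    return min(1.0, 2.0 * count / n_boot)


def profile_ci(boot: BootstrapProfiles, level: float = 0.95) -> np.ndarray:
    """Per-cluster percentile interval, shape (G, 2), linear interpolation."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if boot.n_boot < 20:
        raise ValueError("need at least 20 bootstrap replicates")
    alpha = (1 - level) / 2
    lo = np.quantile(boot.samples, alpha, axis=0)
    hi = np.quantile(boot.samples, 1 - alpha, axis=0)
    return np.column_stack([lo, hi])
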