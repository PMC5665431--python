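"""Cluster separability from MCMC partition samples.

Given an original clustering {A_i} and sampled partitions from an
alternative clustering run, an individual sitting in sampled cluster B
is reassigned to original cluster A_i with probability

    |A_i ∩ B| / sum_j |A_j ∩ B|,

averaged over sampled iterations. Individuals whose most probable
cluster differs from their original one are "intermediate"; counting
them per cluster pair quantifies how separable the clusters are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ClusterModel",
    "PartitionSamples",
    "reassignment_probability",
    "reassign_all",
    "separability_summary",
    "pairwise_coincidence",
    "read_partition_samples",
    "binary_dendrogram_counts",
]


@dataclass
class ClusterModel:
    """A partition of individuals into named clusters."""

    assignment: dict  # individual id -> cluster label

    def __post_init__(self) -> None:
        if not self.assignment:
            raise ValueError("empty clustering")

    @property
    def individuals(self) -> list:
        return list(self.assignment)

    @property
    def labels(self) -> list:
        return sorted(set(self.assignment.values()))

    @property
    def sizes(self) -> dict:
        out: dict = {}
        for lab in self.assignment.values():
            out[lab] = out.get(lab, 0) + 1
        return out

    def members(self, label: str) -> list:
        return [i for i, l in self.assignment.items() if l == label]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ClusterModel":
        return cls(dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str))))


@dataclass
class PartitionSamples:
    """Sampled partitions: one label per individual per iteration."""

    individuals: list
    iterations: list  # list of label arrays, one per iteration
    run_id: str = "run"

    def __post_init__(self) -> None:
        n = len(self.individuals)
        for it in self.iterations:
            if len(it) != n:
                raise ValueError("each iteration must cover all individuals")


def read_partition_samples(path, individuals: list, run_id: str | None = None) -> PartitionSamples:
    """Read one sampled partition per line, comma-separated labels in
    individual order."""
    iterations = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            iterations.append(np.array(line.split(",")))
    return PartitionSamples(list(individuals), iterations, run_id or str(path))


def _check_universe(original: ClusterModel, samples: PartitionSamples) -> None:
    if set(samples.individuals) != set(original.individuals):
        raise ValueError("partition samples cover a different set of individuals")


def reassignment_probability(
    original: ClusterModel, samples: PartitionSamples, individual: str
) -> pd.Series:
    """Probability of reassignment to each original cluster, averaged
    over sampled iterations; sums to 1."""
    _check_universe(original, samples)
    if individual not in original.assignment:
        raise ValueError(f"unknown individual {individual!r}")
    labels = original.labels
    orig = np.array([original.assignment[i] for i in samples.individuals])
    idx = samples.individuals.index(individual)
    acc = np.zeros(len(labels))
    for it in samples.iterations:
        in_b = np.asarray(it) == it[idx]
        counts = np.array([np.sum(in_b & (orig == lab)) for lab in labels], dtype=float)
        total = counts.sum()
        if total == 0:
            raise ValueError("sampled cluster disjoint from all original clusters")
        acc += counts / total
    return pd.Series(acc / len(samples.iterations), index=labels)


def reassign_all(original: ClusterModel, samples: PartitionSamples) -> pd.DataFrame:
    """Most probable original cluster per individual.

    Returns a frame indexed by individual with columns ``original``,
    ``reassigned`` and ``moved``. Probability ties are broken toward the
    individual's original cluster, then by lexicographic label order.
    """
    _check_universe(original, samples)
    labels = original.labels
    orig_arr = np.array([original.assignment[i] for i in samples.individuals])
    lab_index = {lab: k for k, lab in enumerate(labels)}
    probs = np.zeros((len(samples.individuals), len(labels)))
    for it in samples.iterations:
        it = np.asarray(it)
        # for each sampled cluster B, the overlap counts with all A_j
        for b in np.unique(it):
            in_b = it == b
            counts = np.array([np.sum(in_b & (orig_arr == lab)) for lab in labels], dtype=float)
            total = counts.sum()
            if total == 0:
                raise ValueError("sampled cluster disjoint from all original clusters")
            probs[in_b] += counts / total
    probs /= len(samples.iterations)
    rows = []
    for i, ind in enumerate(samples.individuals):
        own = lab_index[orig_arr[i]]
        best = np.flatnonzero(probs[i] == probs[i].max())
        chosen = own if own in best else int(best[0])  # labels sorted: ties lexicographic
        rows.append((ind, orig_arr[i], labels[chosen], labels[chosen] != orig_arr[i]))
    return pd.DataFrame(rows, columns=["individual", "original", "reassigned", "moved"]
                        ).set_index("individual")


def reassignment_counts(original: ClusterModel, samples: PartitionSamples) -> pd.DataFrame:
    """Counts of individuals moved per ordered (from, to) cluster pair."""
    res = reassign_all(original, samples)
    labels = original.labels
    mat = pd.DataFrame(0, index=labels, columns=labels)
    for _, row in res[res["moved"]].iterrows():
        mat.loc[row["original"], row["reassigned"]] += 1
    return mat


def separability_summary(original: ClusterModel, runs: list) -> tuple:
    """Mean and sample SD (n-1) of reassigned counts per ordered cluster
    pair, over alternative runs."""
    if len(runs) < 1:
        raise ValueError("need at least one run")
    counts = [reassignment_counts(original, r).to_numpy(dtype=float) for r in runs]
    labels = original.labels
    arr = np.stack(counts)
    mean = pd.DataFrame(arr.mean(axis=0), index=labels, columns=labels)
    sd = pd.DataFrame(
        arr.std(axis=0, ddof=1) if len(runs) > 1 else np.zeros_like(arr[0]),
        index=labels, columns=labels,
    )
    return mean, sd


def pairwise_coincidence(samples: PartitionSamples) -> pd.DataFrame:
    """Posterior co-clustering probability matrix.

    Entry (i, j) is the fraction of sampled iterations in which i and j
    share a cluster: symmetric, unit diagonal, values in [0, 1].
    """
    if not samples.iterations:
        raise ValueError("need at least one iteration")
    n = len(samples.individuals)
    acc = np.zeros((n, n))
    for it in samples.iterations:
        it = np.asarray(it)
        acc += (it[:, None] == it[None, :])
    acc /= len(samples.iterations)
    return pd.DataFrame(acc, index=samples.individuals, columns=samples.individuals)


def binary_dendrogram_counts(n_tips: int, seed: int | None = None) -> dict:
    """Build a rooted binary dendrogram over ``n_tips`` leaves and count
    its nodes and edges.

    The tree is built by successive pairwise merges (random merge order
    if a seed is given, deterministic left-to-right otherwise), the way a
    hierarchical clustering of individuals produces its dendrogram; the
    counts are then read off the constructed tree: n_tips leaves,
    n_tips - 1 internal nodes and one edge per non-root node.
    """
    if n_tips < 2:
        raise ValueError("need at least two tips")
    rng = np.random.default_rng(seed) if seed is not None else None
    # each active entry is (node_id); edges collected as (parent, child)
    active = list(range(n_tips))
    next_id = n_tips
    edges = []
    while len(active) > 1:
        if rng is not None:
            i, j = sorted(rng.choice(len(active), size=2, replace=False))
        else:
            i, j = 0, 1
        b = active.pop(j)
        a = active.pop(i)
        edges.append((next_id, a))
        edges.append((next_id, b))
        active.append(next_id)
        next_id += 1
    n_internal = next_id - n_tips
    return {
        "n_tips": n_tips,
        "n_internal": n_internal,
        "n_nodes": n_tips + n_internal,
        "n_edges": len(edges),
    }
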