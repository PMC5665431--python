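"""Cluster separability from alternative-run partition samples.

Builds nine synthetic alternative MCMC runs over the cohort: most
iterations reproduce the true clustering (with arbitrary sampled-cluster
names), but a handful of 'intermediate' pop0 individuals co-cluster
with pop1 in part of the iterations. Reports the reassignment summary
per ordered cluster pair, the co-clustering coincidence, and the binary
dendrogram arithmetic at the full study size.
"""

import argparse
from pathlib import Path

import numpy as np

from hapfine import io
from hapfine.cluster_eval import (PartitionSamples, binary_dendrogram_counts,
                                  pairwise_coincidence, separability_summary)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--scratch", type=Path, default=Path("scratch/analysis"))
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

original = io.read_clusters(args.scratch / "clusters.tsv")
inds = original.individuals
true_labels = np.array([original.assignment[i] for i in inds])
rng = np.random.default_rng(args.seed)

intermediates = [i for i, lab in enumerate(true_labels) if lab == "pop0"][:3]
runs = []
for r in range(9):
    names = {lab: f"B{k}_{r}" for k, lab in enumerate(sorted(set(true_labels)))}
    iterations = []
    for _ in range(50):
        it = np.array([names[lab] for lab in true_labels], dtype=object)
        for idx in intermediates:
            if rng.random() < 0.7:  # intermediate individuals drift to pop1
                it[idx] = names["pop1"]
        iterations.append(it.astype(str))
    runs.append(PartitionSamples(list(inds), iterations, run_id=f"run{r}"))

mean, sd = separability_summary(original, runs)
long = mean.stack().rename("mean_reassigned").to_frame()
long["sd_reassigned"] = sd.stack()
long.index.names = ["from_cluster", "to_cluster"]
io.write_table(long.reset_index(), args.results / "04_separability.tsv",
               seed=args.seed, runs=9)

coin = pairwise_coincidence(runs[0])
counts = binary_dendrogram_counts(1600, seed=args.seed)

print("mean reassigned individuals per ordered cluster pair (9 runs):")
print(mean.round(2).to_string())
print(f"\npop0 -> pop1 reassignments: mean {mean.loc['pop0', 'pop1']:.2f} "
      f"(the 3 implanted intermediates), SD {sd.loc['pop0', 'pop1']:.2f}")
print(f"all other ordered pairs: 0 (well separated)")
within = coin.to_numpy()[np.ix_(true_labels == 'pop2', true_labels == 'pop2')]
print(f"co-clustering posterior within pop2: {within.mean():.3f}")
print(f"binary dendrogram at study size: {counts['n_tips']} tips, "
      f"{counts['n_internal']} internal nodes, {counts['n_edges']} edges")
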