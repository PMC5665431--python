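"""Windowed HF_ST scan: sweeps concordant vs discordant with drift.

Implants 30 sweep windows into the cohort in each mode, computes 4-SNP
window HF_ST between pop0 and pop1, sorts windows into 20 equal-count
bins and tests each bin for enrichment of selected windows. Concordant
sweeps (distinct haplotype fixed per cluster) should load the top bin;
discordant sweeps (same haplotype in both clusters) the bottom bins —
the direction reversal between 'distant' and 'close' population
comparisons. Also writes the NJ tree of pairwise HF_ST.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from hapfine import differentiation as diff
from hapfine import io, simdata

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--scratch", type=Path, default=Path("scratch/analysis"))
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

clusters = io.read_clusters(args.scratch / "clusters.tsv")
ds = io.read_vcf(args.scratch / "cohort.vcf")
ds.population_labels = [clusters.assignment[i] for i in ds.individual_ids]

rng = np.random.default_rng(args.seed)
n_win = ds.haplotypes[0].shape[1] // 4
picks = [(c, int(w), ["pop0", "pop1"]) for c in range(ds.n_chrom)
         for w in rng.choice(n_win, size=8, replace=False)]

all_bins = []
for mode in ("concordant", "discordant"):
    swept, records = simdata.implant_sweep(ds, picks, mode, seed=args.seed)
    io.write_bed(records, args.scratch / f"sweeps_{mode}.bed", seed=args.seed)
    wt = diff.window_hfst_table(swept, ["pop0", "pop1"])
    wt = diff.filter_outlier_windows(wt)
    wt = diff.bin_windows(wt, 20)
    bed = pd.DataFrame([[r.chromosome, r.start_bp, r.end_bp, r.name]
                        for r in records])
    wt = diff.mark_selected_windows(wt, bed)
    enr = diff.enrichment_by_bin(wt)
    enr.insert(0, "mode", mode)
    all_bins.append(enr)
    sig = enr.loc[enr["significant"], "bin"].tolist()
    v = wt.valid()
    p_mw, direction = diff.selected_vs_nonselected_test(
        v["hfst"].to_numpy(), v["selected"].to_numpy())
    word = "higher" if direction > 0 else "lower"
    print(f"{mode}: significant bins {sig} "
          f"(Fisher P < 0.01/20); selected windows' HF_ST {word} "
          f"(Mann-Whitney P = {p_mw:.3g})")

io.write_table(pd.concat(all_bins), args.results / "05_enrichment_bins.tsv",
               seed=args.seed, bins=20)

dist = diff.pairwise_hfst_matrix(ds)
tree = diff.neighbor_joining(dist)
(args.results / "05_hfst_nj.nwk").write_text(tree + "\n")
print("\npairwise population HF_ST (ratio of averages):")
print(dist.round(4).to_string())
print(f"NJ tree: {tree}")
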