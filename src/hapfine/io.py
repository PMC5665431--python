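"""Format plumbing: phased VCF, cluster TSV, BED and result writers.

Formats interoperate with the standard haplotype-analysis toolchain:
phased VCF with '|'-separated GT, ChromoPainter-style chunk matrices
(see :mod:`hapfine.painting`), cluster assignment TSV (id<TAB>cluster),
BED 0-based half-open, Newick and JSON. Every table writer stamps a
provenance header (version, seed, parameters) as '#'-comment lines.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from . import __version__
from .cluster_eval import ClusterModel
from .simdata import HaplotypeDataset, SweepRecord

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_bed",
    "read_bed",
    "write_clusters",
    "read_clusters",
    "provenance_header",
    "write_table",
    "write_json",
]


def provenance_header(seed=None, **params) -> str:
    parts = [f"hapfine v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    parts.extend(f"{k}={v}" for k, v in params.items())
    return "# " + " ".join(parts)


def write_vcf(dataset: HaplotypeDataset, path, seed=None) -> None:
    """Write phased haplotypes as a combined multi-chromosome VCF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=hapfine_v{__version__}")
        if seed is not None:
            fh.write(f"_seed{seed}")
        fh.write("\n")
        for c, name in enumerate(dataset.chromosomes):
            length = int(dataset.positions_bp[c][-1]) + 1
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = "\t".join(dataset.individual_ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        n = dataset.n_individuals
        for c, name in enumerate(dataset.chromosomes):
            haps = dataset.haplotypes[c]
            for s, pos in enumerate(dataset.positions_bp[c]):
                gts = "\t".join(
                    f"{haps[2 * k, s]}|{haps[2 * k + 1, s]}" for k in range(n)
                )
                fh.write(f"{name}\t{pos}\tsnp_{name}_{s}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path, population_labels=None) -> HaplotypeDataset:
    """Read a phased VCF into a HaplotypeDataset (cyvcf2 backend).

    Unphased genotypes (a '/' separator) are rejected. Genetic-map
    positions default to 1 cM/Mb.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    by_chrom: dict = {}
    for v in vcf:
        alleles = []
        for g in v.genotypes:
            if len(g) < 3 or not g[2]:
                raise ValueError(f"unphased genotype at {v.CHROM}:{v.POS}")
            alleles.extend([g[0], g[1]])
        by_chrom.setdefault(v.CHROM, ([], []))
        by_chrom[v.CHROM][0].append(v.POS)
        by_chrom[v.CHROM][1].append(alleles)
    chroms = list(by_chrom)
    haplos, bps, cms = [], [], []
    for c in chroms:
        pos, rows = by_chrom[c]
        haplos.append(np.asarray(rows, dtype=np.uint8).T.copy())
        bp = np.asarray(pos, dtype=np.int64)
        bps.append(bp)
        cms.append(bp * 1e-6)
    if population_labels is None:
        population_labels = ["unknown"] * len(ids)
    return HaplotypeDataset(haplos, bps, cms, ids, list(population_labels), chroms)


def write_bed(records: list, path, seed=None) -> None:
    """Write sweep/region records as BED (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed) + "\n")
        for r in records:
            if isinstance(r, SweepRecord):
                fh.write(f"{r.chromosome}\t{r.start_bp}\t{r.end_bp}\t{r.name}\n")
            else:
                fh.write("\t".join(str(x) for x in r) + "\n")


def read_bed(path) -> pd.DataFrame:
    """Read a BED file (>= 3 columns, 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] < 3:
        raise ValueError("BED needs at least chrom/start/end columns")
    names = ["chromosome", "start", "end"] + [f"col{i}" for i in range(3, df.shape[1])]
    if df.shape[1] >= 4:
        names[3] = "name"
    df.columns = names
    if not (df["end"] > df["start"]).all():
        raise ValueError("malformed BED: end must exceed start")
    return df


def write_clusters(clusters: ClusterModel, path) -> None:
    with open(path, "w") as fh:
        for ind, lab in clusters.assignment.items():
            fh.write(f"{ind}\t{lab}\n")


def read_clusters(path) -> ClusterModel:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["individual", "cluster"])
    return ClusterModel.from_frame(df)


def write_table(df: pd.DataFrame, path, seed=None, **params) -> None:
    """TSV writer with provenance header."""
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed, **params) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def write_json(obj, path, seed=None, **params) -> None:
    payload = {"provenance": provenance_header(seed=seed, **params)[2:], **obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")
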