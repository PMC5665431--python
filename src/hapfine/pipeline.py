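"""Pipeline configuration and the end-to-end demo run.

Binds the stages simulate -> paint -> profile -> diff-scan -> strat ->
meta into one call over a validated config. Every output table carries
a provenance header with version, seed and parameters; each stage logs
row counts at INFO.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from . import admix_meta, ancestry_profile, differentiation, io, painting, simdata
from . import stratification
from .cluster_eval import ClusterModel

logger = logging.getLogger("hapfine")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated pipeline parameters; unknown keys are rejected.

    Defaults give a small two-stage demo that runs in minutes on one
    CPU: a 3-cluster simulation with one admixed target, painting in
    both modes, profile fit with bootstrap, a differentiation scan with
    implanted sweeps, a stratification check and the meta-analysis of
    the bundled admixture-date table.
    """

    out_dir: str = "hapfine_out"
    seed: int = 1
    n_clusters: int = 3
    n_per_cluster: list = field(default_factory=lambda: [25, 25, 25])
    n_chrom: int = 3
    snps_per_chrom: int = 400
    drift_f: list = field(default_factory=lambda: [0.03, 0.03, 0.03])
    mixture: dict | None = field(default_factory=lambda: {2: [0.3, 0.7, 0.0]})
    bootstrap_b: int = 200
    n_bins: int = 20
    min_cluster_size: int = 42
    generation_time: float = 25.0
    stages: list = field(default_factory=lambda: [
        "simulate", "paint", "profile", "diff-scan", "strat", "meta",
    ])

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.mixture is not None:
            cfg.mixture = {int(k): v for k, v in cfg.mixture.items()}
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the toggled stages; returns a manifest of written outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {}
    seed = config.seed
    dataset = None
    clusters = None
    matrices = {}

    if "simulate" in config.stages:
        sim_cfg = simdata.SimConfig(
            n_clusters=config.n_clusters,
            n_per_cluster=list(config.n_per_cluster),
            n_chrom=config.n_chrom,
            snps_per_chrom=config.snps_per_chrom,
            drift_f=list(config.drift_f),
            mixture=config.mixture,
            seed=seed,
        )
        dataset = simdata.simulate_haplotypes(sim_cfg)
        clusters = ClusterModel(dict(zip(dataset.individual_ids,
                                         dataset.population_labels)))
        vcf_path = out / "simulated.vcf"
        io.write_vcf(dataset, vcf_path, seed=seed)
        io.write_clusters(clusters, out / "clusters.tsv")
        manifest["vcf"] = str(vcf_path)
        manifest["clusters"] = str(out / "clusters.tsv")
        logger.info("simulate: %d individuals, %d chromosomes x %d SNPs",
                    dataset.n_individuals, config.n_chrom, config.snps_per_chrom)

    if "paint" in config.stages:
        if dataset is None:
            raise ValueError("paint stage requires the simulate stage (or inputs)")
        for mode, dialect in (("chunk_counts", "chunkcounts"),
                              ("chunk_lengths_cM", "chunklengths")):
            mat = painting.build_coancestry(dataset, painting.PaintingParams(), mode)
            path = out / f"coancestry.{dialect}.tsv"
            painting.write_chunk_matrix(mat, path)
            matrices[mode] = mat
            manifest[dialect] = str(path)
            logger.info("paint (%s): %d x %d matrix", mode, *mat.values.shape)

    if "profile" in config.stages:
        mat = matrices.get("chunk_lengths_cM")
        if mat is None:
            raise ValueError("profile stage requires the paint stage")
        target = "pop2" if config.mixture else sorted(set(dataset.population_labels))[0]
        donor_clusters = [p for p in sorted(set(dataset.population_labels)) if p != target]
        donor_ids = [i for i, p in zip(dataset.individual_ids, dataset.population_labels)
                     if p != target]
        xs = [ancestry_profile.cluster_mean_row(mat, clusters, g, donor_ids)
              for g in donor_clusters]
        y = ancestry_profile.cluster_mean_row(mat, clusters, target, donor_ids)
        prof = ancestry_profile.fit_profile(y, xs)
        per_chrom = [
            painting.CoancestryMatrix(m, mat.recipient_ids, mat.donor_ids, mat.mode)
            for m in mat.per_chromosome
        ]
        boot = ancestry_profile.bootstrap_profiles(
            per_chrom, clusters, target, xs, n_boot=config.bootstrap_b, seed=seed)
        ci = ancestry_profile.profile_ci(boot)
        io.write_json(
            {"target": target,
             "beta": dict(zip(donor_clusters, prof.beta)),
             "ci": {g: list(ci[k]) for k, g in enumerate(donor_clusters)}},
            out / "ancestry_profile.json", seed=seed, bootstrap=config.bootstrap_b)
        manifest["profile"] = str(out / "ancestry_profile.json")
        logger.info("profile %s: beta=%s", target, np.round(prof.beta, 3))

    if "diff-scan" in config.stages:
        if dataset is None:
            raise ValueError("diff-scan stage requires the simulate stage")
        swept, records = simdata.implant_sweep(
            dataset, [(0, 5, ["pop0"]), (1, 10, ["pop1"])], "concordant", seed=seed)
        io.write_bed(records, out / "sweeps.bed", seed=seed)
        pops = ["pop0", "pop1"]
        wt = differentiation.window_hfst_table(swept, pops)
        wt = differentiation.filter_outlier_windows(wt)
        wt = differentiation.bin_windows(wt, config.n_bins)
        wt = differentiation.mark_selected_windows(
            wt, io.read_bed(out / "sweeps.bed"))
        enr = differentiation.enrichment_by_bin(wt)
        io.write_table(wt.table, out / "scan_windows.tsv", seed=seed)
        io.write_table(enr, out / "scan_bins.tsv", seed=seed, bins=config.n_bins)
        dist = differentiation.pairwise_hfst_matrix(swept)
        if len(dist) >= 3:
            (out / "hfst_nj.nwk").write_text(
                differentiation.neighbor_joining(dist) + "\n")
            manifest["tree"] = str(out / "hfst_nj.nwk")
        manifest["scan"] = str(out / "scan_bins.tsv")
        logger.info("diff-scan: %d windows, %d bins", len(wt), config.n_bins)

    if "strat" in config.stages:
        if dataset is None:
            raise ValueError("strat stage requires the simulate stage")
        res = stratification.simulate_gwas_pair(dataset, clusters, "pop0", "pop1")
        io.write_json({"pair": ["pop0", "pop1"], "lambda_gc": res.lambda_gc,
                       "n_snps": res.n_snps}, out / "lambda_gc.json", seed=seed)
        manifest["lambda"] = str(out / "lambda_gc.json")
        logger.info("strat pop0-pop1: lambda_GC=%.3f over %d SNPs",
                    res.lambda_gc, res.n_snps)

    if "meta" in config.stages:
        table = admix_meta.load_bundled_estimates()
        rows = []
        for ref in sorted(table["reference"].unique()):
            for name, subset in (("all", None),
                                 ("hondo", admix_meta.HONDO_CLUSTERS),
                                 ("ryukyu", admix_meta.RYUKYU_CLUSTERS)):
                m = admix_meta.meta_by_reference(table, ref, subset)
                rows.append((ref, name, m.estimate, m.se, m.q, m.df, m.p_het))
        import pandas as pd

        meta_df = pd.DataFrame(rows, columns=[
            "reference", "group", "estimate_gen", "se_gen", "Q", "df", "p_het"])
        meta_df["estimate_years"] = [
            admix_meta.generations_to_years(g, config.generation_time)
            for g in meta_df["estimate_gen"]]
        io.write_table(meta_df, out / "admixture_meta.tsv", seed=seed,
                       generation_time=config.generation_time)
        manifest["meta"] = str(out / "admixture_meta.tsv")
        logger.info("meta: %d combinations", len(meta_df))

    return manifest
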