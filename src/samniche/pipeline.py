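"""End-to-end pipeline: simulate -> qc -> adjusted correlation -> clustering
-> group statistics (and optional sRNA profiling), with a provenance
manifest.

The config is a validated YAML/dict (unknown keys rejected).  One global
seed is expanded deterministically into per-stage streams, so re-running
with an identical config reproduces every output byte for byte; the
manifest records parameters, seeds and a sha256 checksum per output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib.metadata import version as pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import adjcorr, cluster, io, qc, simulate, srna, stats

log = logging.getLogger(__name__)


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimSection(_Section):
    n_nuclei: int = 200
    n_genes: int = 2000
    n_tes: int = 500
    niche_proportions: dict[str, float] = Field(
        default_factory=lambda: {"L1": 0.2, "L2": 0.3, "other": 0.5})
    depth_lognormal_mu: float = float(np.log(8000.0))
    depth_lognormal_sigma: float = 0.6
    marker_effect: float = 50.0
    te_program_effect: float = 8.0
    n_seed_genes: int = 30
    cell_cycle_proportions: dict[str, float] = Field(
        default_factory=lambda: {"G1": 0.5, "S-G2": 0.3, "G2-M": 0.2})
    program_factor_sigma: float = 0.8


class QCSection(_Section):
    min_features: int = 100
    min_reads: int = 1000
    min_feature_nuclei: int = 4
    exclude_ids: list[str] = Field(default_factory=list)


class CorrSection(_Section):
    n_null: int = 100


class ClusterSection(_Section):
    k_genes: int | None = None   # None -> silhouette selection
    k_tes: int | None = None
    k_min: int = 2
    k_max: int = 6


class StatsSection(_Section):
    ago5: str = "AGO5"
    ago9: str = "AGO9"
    marker_min_reads: int = 2
    cycle_min_reads: int = 1
    cargo_jaccard: float = 0.7
    cargo_sizes: dict[str, int] = Field(
        default_factory=lambda: {"AGO5_cargo": 100, "AGO9_cargo": 120})


class SrnaSection(_Section):
    enabled: bool = True
    n_reads: int = 20000
    positional_profile: str = "end_biased"
    body_bins: int = 100


class PipelineConfig(_Section):
    seed: int = 7
    simulate: bool = True
    counts: str | None = None        # used when simulate is false
    nucleus_meta: str | None = None
    feature_meta: str | None = None
    seed_genes: str | None = None    # id-list file when simulate is false
    sim: SimSection = Field(default_factory=SimSection)
    qc: QCSection = Field(default_factory=QCSection)
    corr: CorrSection = Field(default_factory=CorrSection)
    cluster: ClusterSection = Field(default_factory=ClusterSection)
    stats: StatsSection = Field(default_factory=StatsSection)
    srna: SrnaSection = Field(default_factory=SrnaSection)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(path: Path) -> Path:
        written.append(path)
        return path

    # --- stage 1: counts -------------------------------------------------
    if config.simulate:
        sim_cfg = simulate.SimConfig(**config.sim.model_dump(), seed=config.seed)
        adata, truth = simulate.generate_dataset(sim_cfg)
        for p in io.write_counts(adata, outdir, stem="counts.raw").values():
            emit(p)
        truth_df = pd.DataFrame({
            "niche": truth.niche_per_nucleus,
            "cycle": truth.cycle_per_nucleus,
            "dapi_covariate": truth.dapi_covariate,
        })
        truth_df.to_csv(emit(outdir / "truth.nuclei.tsv"), sep="\t")
        truth.program_per_feature.to_csv(emit(outdir / "truth.features.tsv"), sep="\t")
        seed_ids = truth.seed_gene_ids
    else:
        if not (config.counts and config.nucleus_meta and config.feature_meta
                and config.seed_genes):
            raise ValueError(
                "simulate=false requires counts, nucleus_meta, feature_meta "
                "and seed_genes paths")
        adata = io.read_counts(config.counts, config.nucleus_meta, config.feature_meta)
        truth = None
        seed_ids = io.read_id_list(config.seed_genes)

    # --- stage 2: qc ------------------------------------------------------
    adata = qc.filter_nuclei(adata, config.qc.min_features, config.qc.min_reads)
    adata = qc.filter_features(adata, config.qc.min_feature_nuclei,
                               set(config.qc.exclude_ids))
    for p in io.write_counts(adata, outdir, stem="counts.qc").values():
        emit(p)

    seed_ids = [s for s in seed_ids if s in adata.var_names]
    cycle_markers = [m for m in stats.DEFAULT_CYCLE_MARKERS if m in adata.var_names]
    te_ids = list(adata.var_names[adata.var["kind"] == "transposon"])

    # --- stage 3: adjusted correlation -----------------------------------
    gene_subset = seed_ids
    adj_genes = adjcorr.adjusted_from_counts(
        adata, n_null=config.corr.n_null, seed=config.seed, feature_subset=gene_subset)
    adjcorr.write_correlation_tsv(adj_genes, emit(outdir / "adjcorr.seed_genes.tsv"))

    te_subset = seed_ids + cycle_markers + te_ids
    adj_tes = adjcorr.adjusted_from_counts(
        adata, n_null=config.corr.n_null, seed=config.seed, feature_subset=te_subset)

    # --- stage 4: clustering ----------------------------------------------
    k_range = range(config.cluster.k_min, config.cluster.k_max + 1)
    seeds_only = cluster.SeedGeneSet(seed_ids, label="GESS")
    gene_profiles = cluster.extract_seed_profiles(adj_genes, seeds_only, seed_ids)
    k_genes = config.cluster.k_genes or cluster.select_k(
        gene_profiles, k_range, axis="seeds")
    gene_assign = cluster.cluster_features(gene_profiles, k_genes, axis="seeds")
    gene_assign.to_frame().to_csv(emit(outdir / "clusters.seed_genes.tsv"),
                                  sep="\t", index=False)

    seeds_cc = cluster.SeedGeneSet(seed_ids + cycle_markers, label="GESS+cellcycle")
    te_profiles = cluster.extract_seed_profiles(adj_tes, seeds_cc, te_ids)
    k_tes = config.cluster.k_tes or cluster.select_k(te_profiles, k_range, axis="targets")
    te_assign = cluster.cluster_features(te_profiles, k_tes, axis="targets")
    te_assign.to_frame().to_csv(emit(outdir / "clusters.tes.tsv"), sep="\t", index=False)
    cluster.cluster_composition(te_assign, adata.var).to_csv(
        emit(outdir / "clusters.tes.composition.tsv"), sep="\t", index=False)

    # --- stage 5: group statistics ----------------------------------------
    adata.obs["marker_group"] = stats.classify_nuclei_by_markers(
        adata, config.stats.ago5, config.stats.ago9, config.stats.marker_min_reads)
    adata.obs["cell_cycle"] = stats.assign_cell_cycle(
        adata, min_reads=config.stats.cycle_min_reads)
    adata.obs[["marker_group", "cell_cycle"]].to_csv(
        emit(outdir / "nucleus_groups.tsv"), sep="\t")
    comparisons = stats.compare_te_expression(adata, te_assign)
    comparisons.to_csv(emit(outdir / "te_group_comparisons.tsv"), sep="\t", index=False)

    overlap_rows = []
    if truth is not None:
        cargo_sets = simulate.generate_cargo_sets(
            truth, config.stats.cargo_jaccard, config.stats.cargo_sizes,
            seed=config.seed)
        universe = set(te_ids)
        for name, ids in cargo_sets.items():
            pd.Series(sorted(ids)).to_csv(
                emit(outdir / f"cargo.{name}.txt"), index=False, header=False)
            for c in range(1, te_assign.k + 1):
                ov = stats.hypergeometric_overlap(
                    set(te_assign.members(c)), ids & universe, universe)
                overlap_rows.append({
                    "cargo": name, "cluster": c, "size_cluster": ov.size_a,
                    "size_cargo": ov.size_b, "overlap": ov.overlap,
                    "universe": ov.universe, "p": ov.p, "fold": ov.fold,
                })
            length_cmp = stats.te_length_comparison(ids, adata.var)
            overlap_rows.append({
                "cargo": name, "cluster": "length_vs_genome",
                "size_cluster": length_cmp.n_a, "size_cargo": length_cmp.n_b,
                "overlap": np.nan, "universe": np.nan, "p": length_cmp.p,
                "fold": np.nan,
            })
    pd.DataFrame(overlap_rows).to_csv(emit(outdir / "overlaps.tsv"),
                                      sep="\t", index=False)

    # --- stage 6: sRNA (simulated cargo reads) ----------------------------
    if config.srna.enabled and truth is not None:
        reads = simulate.generate_srna_reads(
            cargo_sets["AGO5_cargo"], config.srna.n_reads,
            positional_profile=config.srna.positional_profile, seed=config.seed)
        io.write_srna_reads(reads, emit(outdir / "srna.reads.tsv"))
        profile = srna.size_5p_profile(reads)
        profile.counts.to_csv(emit(outdir / "srna.size_5p.tsv"), sep="\t")
        meta = srna.metaplot(reads, adata.var, body_bins=config.srna.body_bins)
        meta.matrix.to_csv(emit(outdir / "srna.metaplot.tsv"), sep="\t")

    manifest = {
        "package": "samniche",
        "version": pkg_version("samniche"),
        "seed": config.seed,
        "config": config.model_dump(),
        "stages": ["simulate" if config.simulate else "load", "qc", "adjcorr",
                   "cluster", "stats"] + (["srna"] if config.srna.enabled else []),
        "selected_k": {"genes": int(k_genes), "tes": int(k_tes)},
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in sorted(written)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
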