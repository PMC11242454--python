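"""End-to-end workflow: preprocess → growth clusters → diversity → assembly → networks.

Each stage writes its outputs into a stage-named directory under the run's
output directory and never mutates its inputs on disk.  A manifest records
the package version, the seed, every parameter value and a SHA-256 checksum
per output file, so a run is reproducible bit-for-bit from the manifest and
the same code version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx

from . import __version__, assembly, diversity, growth, io, networks, preprocessing
from .containers import FeatureTable
from .simulate import AssemblyRegime, simulate_dataset

logger = logging.getLogger("rhizobiome")

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """All pipeline parameters with their study-default values."""

    seed: int = 0
    output_dir: str = "rhizobiome_run"
    # inputs: either paths to files, or None to simulate
    table_path: str | None = None
    tree_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    traits_path: str | None = None
    # synthetic-data parameters (used when no input paths are given)
    n_cultivars: int = 10
    n_replicates: int = 3
    n_taxa: int = 150
    depth: int = 5000
    regime: str = "homogeneous_selection"
    selection_sd: float = 0.15
    recruitment: float = 0.2
    drift_sd: float = 1.0
    selection_floor: float = 0.05
    # preprocessing
    cultivar_col: str = "cultivar"
    # growth clustering
    k_max: int = 8
    k_criterion: str = "wss"
    anosim_permutations: int = 999
    # diversity
    permanova_permutations: int = 999
    permanova_factors: list = field(
        default_factory=lambda: ["cultivar", "growth_cluster", "breeding_purpose", "earliness"]
    )
    core_prevalence_min: float = 0.80
    core_abundance_min: float = 0.0001
    # assembly
    n_null: int = 1000
    # networks
    network_r_min: float = 0.3
    network_alpha: float = 0.0001
    network_lfdr_max: float = 0.2
    group_col: str = "growth_cluster"

    def validate(self) -> None:
        paths = [self.table_path, self.tree_path, self.metadata_path]
        if any(p is not None for p in paths) and not all(p is not None for p in paths):
            raise ValueError(
                "provide table_path, tree_path and metadata_path together (or none, to simulate)"
            )


def load_config(path: str) -> RunConfig:
    """Load a YAML/JSON config file, rejecting unknown keys before execution."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_dir(cfg: RunConfig, stage: str) -> str:
    d = os.path.join(cfg.output_dir, stage)
    os.makedirs(d, exist_ok=True)
    return d


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and return the in-memory result bundle."""
    cfg.validate()
    os.makedirs(cfg.output_dir, exist_ok=True)
    outputs: dict[str, str] = {}
    results: dict = {}

    # ---- stage 0: inputs -------------------------------------------------
    if cfg.table_path is None:
        logger.info("simulate: %d cultivars x %d replicates, %d taxa, depth %d, regime %s",
                    cfg.n_cultivars, cfg.n_replicates, cfg.n_taxa, cfg.depth, cfg.regime)
        ds = simulate_dataset(
            n_cultivars=cfg.n_cultivars,
            n_replicates=cfg.n_replicates,
            n_taxa=cfg.n_taxa,
            depth=cfg.depth,
            regime=AssemblyRegime(
                cfg.regime,
                selection_sd=cfg.selection_sd,
                recruitment=cfg.recruitment,
                drift_sd=cfg.drift_sd,
                selection_floor=cfg.selection_floor,
            ),
            seed=cfg.seed,
        )
        table, tree, taxonomy = ds.table, ds.tree, ds.taxonomy
        metadata, traits = ds.metadata, ds.traits
        sim_dir = _stage_dir(cfg, "simulate")
        for key, path in io.write_dataset(ds, sim_dir).items():
            outputs[f"simulate/{key}"] = path
    else:
        table = io.read_feature_table(cfg.table_path)
        tree = io.read_tree(cfg.tree_path)
        taxonomy = io.read_taxonomy(cfg.taxonomy_path) if cfg.taxonomy_path else None
        metadata = io.read_metadata(cfg.metadata_path)
        traits = io.read_traits(cfg.traits_path) if cfg.traits_path else None

    # ---- stage 1: preprocessing -----------------------------------------
    logger.info("preprocess: singletons -> 2-of-%d replicate prevalence -> TSS",
                cfg.n_replicates)
    counts = preprocessing.replicate_prevalence_filter(
        preprocessing.remove_singletons(table), metadata, cfg.cultivar_col
    )
    relative = preprocessing.tss_normalize(counts)
    pre_dir = _stage_dir(cfg, "preprocess")
    io.write_feature_table(counts, os.path.join(pre_dir, "filtered_counts.tsv"))
    io.write_feature_table(relative, os.path.join(pre_dir, "relative_abundance.tsv"))
    outputs["preprocess/filtered_counts"] = os.path.join(pre_dir, "filtered_counts.tsv")
    outputs["preprocess/relative_abundance"] = os.path.join(pre_dir, "relative_abundance.tsv")
    results["counts"] = counts
    results["relative"] = relative

    # ---- stage 2: growth clustering -------------------------------------
    if traits is not None:
        scaled = growth.scale_traits(traits)
        k = growth.select_k(scaled, k_max=min(cfg.k_max, scaled.shape[0] - 1),
                            criterion=cfg.k_criterion, seed=cfg.seed)
        logger.info("growth: %s criterion selected k=%d", cfg.k_criterion, k)
        km = growth.rank_clusters(growth.kmeans_cluster(scaled, k, seed=cfg.seed), traits)
        hc = growth.rank_clusters(growth.hierarchical_cluster(scaled, k), traits)
        an = growth.trait_anosim(scaled, km.labels, n_perm=cfg.anosim_permutations, seed=cfg.seed)
        gdir = _stage_dir(cfg, "growth")
        km.labels.rename("kmeans").to_frame().assign(hierarchical=hc.labels).to_csv(
            os.path.join(gdir, "cluster_assignments.tsv"), sep="\t"
        )
        with open(os.path.join(gdir, "growth_report.json"), "w") as fh:
            json.dump({"k": k, "criterion": cfg.k_criterion,
                       "anosim_R": an.R, "anosim_p": an.p}, fh, indent=2)
        outputs["growth/cluster_assignments"] = os.path.join(gdir, "cluster_assignments.tsv")
        outputs["growth/report"] = os.path.join(gdir, "growth_report.json")
        results["growth_clusters"] = km
        results["anosim"] = an
        sample_groups = metadata[cfg.cultivar_col].map(km.labels)
        sample_groups.name = cfg.group_col
    else:
        sample_groups = metadata[cfg.group_col]

    # ---- stage 3: diversity ---------------------------------------------
    alpha = diversity.alpha_metrics(relative)
    wu = diversity.weighted_unifrac(relative, tree)
    ord_res = diversity.pcoa(wu)
    factors = [f for f in cfg.permanova_factors if f in metadata.columns]
    meta_with_groups = metadata.copy()
    meta_with_groups[cfg.group_col] = sample_groups
    if cfg.group_col not in factors:
        factors = [cfg.group_col] + factors
    perm = diversity.permanova_factors(
        wu, meta_with_groups, factors, n_perm=cfg.permanova_permutations, seed=cfg.seed
    )
    core = preprocessing.core_microbiome(
        relative, sample_groups, cfg.core_prevalence_min, cfg.core_abundance_min
    )
    ddir = _stage_dir(cfg, "diversity")
    alpha.to_csv(os.path.join(ddir, "alpha_diversity.tsv"), sep="\t")
    pd.DataFrame(wu.data, index=wu.ids, columns=wu.ids).to_csv(
        os.path.join(ddir, "weighted_unifrac.tsv"), sep="\t"
    )
    ord_res.samples.to_csv(os.path.join(ddir, "pcoa_coordinates.tsv"), sep="\t")
    perm.to_csv(os.path.join(ddir, "permanova_factors.tsv"), sep="\t")
    with open(os.path.join(ddir, "core_microbiome.json"), "w") as fh:
        json.dump(
            {"+".join(k): {"taxa": sorted(v["taxa"]), "read_proportion": v["read_proportion"]}
             for k, v in core.items()},
            fh, indent=2,
        )
    for key in ("alpha_diversity", "weighted_unifrac", "pcoa_coordinates",
                "permanova_factors", "core_microbiome.json"):
        name = key.replace(".json", "")
        ext = ".json" if key.endswith(".json") else ".tsv"
        outputs[f"diversity/{name}"] = os.path.join(ddir, name + ext)
    results.update(alpha=alpha, unifrac=wu, pcoa=ord_res, permanova=perm, core=core)

    # ---- stage 4: assembly ----------------------------------------------
    logger.info("assembly: %d null replicates", cfg.n_null)
    bnti = assembly.beta_nti(counts, tree, n_null=cfg.n_null, seed=cfg.seed)
    rc = assembly.raup_crick_bray(counts, n_null=cfg.n_null, seed=cfg.seed + 1)
    bmntd = assembly.beta_mntd_matrix(counts, tree)
    pairs = assembly.classify_pairs(bnti, rc, groups=sample_groups)
    pairs.insert(3, "bmntd", [bmntd.loc[a, b] for a, b in zip(pairs.sample_a, pairs.sample_b)])
    fractions = assembly.summarize_fractions(pairs)
    adir = _stage_dir(cfg, "assembly")
    pairs.to_csv(os.path.join(adir, "pairwise_assembly.tsv"), sep="\t", index=False)
    fractions.to_csv(os.path.join(adir, "process_fractions.tsv"), sep="\t")
    with open(os.path.join(adir, "process_fractions.json"), "w") as fh:
        json.dump(json.loads(fractions.to_json(orient="index")), fh, indent=2)
    outputs["assembly/pairwise"] = os.path.join(adir, "pairwise_assembly.tsv")
    outputs["assembly/fractions"] = os.path.join(adir, "process_fractions.tsv")
    results.update(bnti=bnti, rcbray=rc, assembly_pairs=pairs, assembly_fractions=fractions)

    # ---- stage 5: networks ----------------------------------------------
    if taxonomy is not None:
        group_tables = {
            g: counts.select_samples(sample_groups.index[sample_groups == g])
            for g in sorted(sample_groups.unique())
        }
        comparison = networks.compare_networks(
            group_tables, taxonomy,
            r_min=cfg.network_r_min, alpha=cfg.network_alpha, lfdr_max=cfg.network_lfdr_max,
        )
        ndir = _stage_dir(cfg, "networks")
        for g, net in comparison["networks"].items():
            net.edges.assign(
                module_source=[net.modules.get(s, -1) for s in net.edges.source]
            ).to_csv(os.path.join(ndir, f"edges_{g}.tsv"), sep="\t", index=False)
            nx.write_graphml(net.graph, os.path.join(ndir, f"network_{g}.graphml"))
            outputs[f"networks/edges_{g}"] = os.path.join(ndir, f"edges_{g}.tsv")
        props = {g: p.as_dict() for g, p in comparison["properties"].items()}
        with open(os.path.join(ndir, "network_properties.json"), "w") as fh:
            json.dump(
                {"properties": props,
                 "core_hubs": sorted(comparison["core_hubs"]),
                 "group_specific_hubs": {g: sorted(h) for g, h in
                                         comparison["group_specific_hubs"].items()}},
                fh, indent=2,
            )
        outputs["networks/properties"] = os.path.join(ndir, "network_properties.json")
        results["networks"] = comparison

    # ---- manifest --------------------------------------------------------
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "parameters": dataclasses.asdict(cfg),
        "checksums": {k: _checksum(p) for k, p in sorted(outputs.items())},
    }
    with open(os.path.join(cfg.output_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    results["manifest"] = manifest
    return results
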