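"""Post-denoising filters, normalization and the core-microbiome partition.

The filter chain applied to a raw ASV count table, in order:

1. singleton removal — drop ASVs represented by exactly one read across
   all samples;
2. replicate prevalence — keep an ASV only if, in at least one cultivar,
   it is present (count > 0) in at least two of that cultivar's three
   replicates;
3. total-sum scaling (TSS) — divide each sample by its library size,
   yielding relative abundances.

The prevalence rule is existential over cultivars (one qualifying cultivar
keeps the taxon globally): a universal rule would empty the table, and the
downstream analyses never split the table per cultivar.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .containers import FeatureTable

__all__ = [
    "remove_singletons",
    "replicate_prevalence_filter",
    "tss_normalize",
    "core_microbiome",
    "preprocess",
    "CorePartition",
]


def remove_singletons(table: FeatureTable) -> FeatureTable:
    """Drop every taxon whose total count across all samples equals 1."""
    if table.is_relative:
        raise ValueError("singleton removal requires a count table, got relative abundances")
    totals = table.data.sum(axis=0)
    keep = table.data.columns[totals != 1]
    return FeatureTable(table.data.loc[:, keep].copy(), is_relative=False)


def replicate_prevalence_filter(
    table: FeatureTable,
    metadata: pd.DataFrame,
    cultivar_col: str = "cultivar",
    min_replicates: int = 2,
) -> FeatureTable:
    """Keep a taxon iff some cultivar has it present in ≥ ``min_replicates`` replicates."""
    missing = [s for s in table.sample_ids if s not in metadata.index]
    if missing:
        raise KeyError(f"samples missing from metadata: {missing}")
    presence = table.data > 0
    cultivars = metadata.loc[table.sample_ids, cultivar_col]
    reps_present = presence.groupby(cultivars.to_numpy()).sum()
    keep = table.data.columns[(reps_present >= min_replicates).any(axis=0)]
    return FeatureTable(table.data.loc[:, keep].copy(), table.is_relative)


def tss_normalize(table: FeatureTable) -> FeatureTable:
    """Total-sum scaling: divide each sample row by its library size."""
    sums = table.data.sum(axis=1)
    empty = sums.index[sums == 0].tolist()
    if empty:
        raise ValueError(f"cannot TSS-normalize samples with zero total: {empty}")
    return FeatureTable(table.data.div(sums, axis=0), is_relative=True)


def preprocess(table: FeatureTable, metadata: pd.DataFrame, cultivar_col: str = "cultivar") -> FeatureTable:
    """The full chain: singletons → replicate prevalence → TSS."""
    return tss_normalize(
        replicate_prevalence_filter(remove_singletons(table), metadata, cultivar_col)
    )


class CorePartition(dict):
    """Venn-region partition of core taxa.

    Maps each group combination (a sorted tuple of group labels) to a dict
    with the region's ``taxa`` (set) and the ``read_proportion`` those taxa
    carry, computed on the relative table averaged over all samples of the
    compared groups.  Regions are pairwise disjoint by construction.
    """

    @property
    def qualifying_taxa(self) -> set:
        out: set = set()
        for region in self.values():
            out |= region["taxa"]
        return out


def core_microbiome(
    table: FeatureTable,
    groups: pd.Series,
    prevalence_min: float = 0.80,
    abundance_min: float = 0.0001,
) -> CorePartition:
    """Core-microbiome Venn partition across sample groups.

    Within each group, a taxon qualifies if its relative abundance exceeds
    ``abundance_min`` (strict >) in at least ``prevalence_min`` (≥) of that
    group's samples — the 80%-prevalence / 0.01%-abundance core rule.
    Qualifying taxa are partitioned into Venn regions by the exact set of
    groups they qualify in.
    """
    if not table.is_relative:
        raise ValueError("core_microbiome requires a relative-abundance table")
    groups = groups.loc[table.sample_ids]
    group_levels = sorted(groups.unique())
    core_sets: dict[str, set] = {}
    for g in group_levels:
        members = groups.index[groups == g]
        if len(members) == 0:
            raise ValueError(f"empty group {g!r}")
        sub = table.data.loc[members]
        prevalence = (sub > abundance_min).mean(axis=0)
        core_sets[g] = set(sub.columns[prevalence >= prevalence_min])

    mean_abund = table.data.loc[groups.index].mean(axis=0)
    partition = CorePartition()
    for r in range(1, len(group_levels) + 1):
        for combo in combinations(group_levels, r):
            in_all = set.intersection(*(core_sets[g] for g in combo))
            out_of_rest = set.union(
                set(), *(core_sets[g] for g in group_levels if g not in combo)
            )
            region = in_all - out_of_rest
            if region:
                partition[tuple(combo)] = {
                    "taxa": region,
                    "read_proportion": float(mean_abund[sorted(region)].sum()),
                }
    return partition
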