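"""Alpha diversity, weighted-UniFrac beta diversity, PCoA and factor testing.

Alpha metrics are observed richness, the Shannon index (nats) and Simpson's
dominance λ = Σ p².  Because the direction of "Simpson's index" differs
between conventions, both the dominance λ and its complement 1 − λ
(Gini–Simpson diversity) are reported.

Beta diversity uses the normalized weighted UniFrac dissimilarity
(range [0, 1]); the unnormalized branch-length sum is available behind a
flag.  Factor testing runs an independent one-factor PERMANOVA per metadata
factor, mirroring a factor-wise variance-explained table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.stats.ordination import OrdinationResults, pcoa as _skbio_pcoa

from .containers import FeatureTable
from .stats import PermanovaResult, pairwise_wilcoxon_fdr, permanova

__all__ = [
    "alpha_metrics",
    "weighted_unifrac",
    "pcoa",
    "permanova",
    "permanova_factors",
    "pairwise_wilcoxon_fdr",
]


def alpha_metrics(table: FeatureTable) -> pd.DataFrame:
    """Per-sample richness, Shannon entropy (nats), Simpson dominance λ and 1−λ.

    Proportions are recomputed within each sample, so counts and TSS tables
    give identical results.
    """
    p = table.proportions()
    richness = (p > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)
    dominance = (p**2).sum(axis=1)
    return pd.DataFrame(
        {
            "richness": richness,
            "shannon": shannon,
            "simpson_dominance": dominance,
            "simpson_diversity": 1.0 - dominance,
        },
        index=table.sample_ids,
    )


def _branch_tip_structure(tree: TreeNode, taxa: list[str]):
    """Branch lengths and branch × taxon descendant incidence for the tree.

    Every non-root node contributes one branch; the incidence row marks the
    table taxa descending through that branch.
    """
    tip_index = {t: i for i, t in enumerate(taxa)}
    tree_tips = {t.name for t in tree.tips()}
    missing = sorted(set(taxa) - tree_tips)
    if missing:
        raise KeyError(f"taxa missing from the tree: {missing}")
    lengths: list[float] = []
    incidence_rows: list[np.ndarray] = []
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            row = np.zeros(len(taxa), dtype=bool)
            if node.name in tip_index:
                row[tip_index[node.name]] = True
        else:
            row = np.zeros(len(taxa), dtype=bool)
            for child in node.children:
                row |= below.pop(id(child))
        below[id(node)] = row
        if node.parent is not None:
            if node.length is None:
                raise ValueError(f"branch above {node.name or 'internal node'} has no length")
            lengths.append(float(node.length))
            incidence_rows.append(row)
    return np.array(lengths), np.array(incidence_rows)


def weighted_unifrac(
    table: FeatureTable, tree: TreeNode, normalized: bool = True
) -> DistanceMatrix:
    """Weighted UniFrac dissimilarity between all sample pairs.

    For samples A, B with per-branch descendant abundances A_i, B_i and
    branch lengths b_i:  Σ b_i·|A_i − B_i|, divided (normalized variant) by
    Σ b_i·(A_i + B_i), giving values in [0, 1].
    """
    p = table.proportions()
    lengths, incidence = _branch_tip_structure(tree, table.taxon_ids)
    # branch abundance per sample: samples × branches
    branch_ab = p @ incidence.T.astype(float)
    n = table.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(branch_ab[i] - branch_ab[i + 1 :])
        num = diff @ lengths
        if normalized:
            den = (branch_ab[i] + branch_ab[i + 1 :]) @ lengths
            vals = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        else:
            vals = num
        out[i, i + 1 :] = vals
        out[i + 1 :, i] = vals
    return DistanceMatrix(out, ids=table.sample_ids)


def pcoa(dm: DistanceMatrix) -> OrdinationResults:
    """Principal coordinates analysis (Gower-centred eigendecomposition).

    Axes are ordered by eigenvalue; negative eigenvalues are retained in
    the result rather than silently dropped.
    """
    if not isinstance(dm, DistanceMatrix):
        dm = DistanceMatrix(dm)  # validates symmetry / zero diagonal
    return _skbio_pcoa(dm, method="eigh")


def permanova_factors(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    factors: list[str],
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Independent one-factor PERMANOVAs, one row per metadata factor."""
    rows: list[PermanovaResult] = []
    for i, factor in enumerate(factors):
        res = permanova(
            dm,
            metadata.loc[list(dm.ids), factor],
            n_perm=n_perm,
            seed=seed + i,
            factor=factor,
        )
        rows.append(res)
    return pd.DataFrame(
        [{"factor": r.factor, "R2": r.R2, "pseudo_F": r.pseudo_F, "p": r.p} for r in rows]
    ).set_index("factor")
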