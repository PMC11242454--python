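"""Null-model partitioning of community assembly processes.

For every pair of communities two statistics are computed:

- βNTI, the z-score of the observed abundance-weighted β-mean-nearest-taxon
  distance (βMNTD) against a null distribution obtained by shuffling taxa
  across the phylogeny tips.  |βNTI| > 2 signals deterministic selection —
  heterogeneous (βNTI > 2, divergent compositions) or homogeneous
  (βNTI < −2, convergent compositions).
- RCbray, the Raup–Crick metric on Bray–Curtis dissimilarity rescaled to
  [−1, 1] under a null that fixes each sample's observed richness and total
  abundance: tails beyond ±0.95 signal dispersal limitation (> 0.95) or
  homogenizing dispersal (< −0.95); the remainder is "undominated".

Boundary values sit on the stochastic side: |βNTI| = 2 is not selection and
|RCbray| = 0.95 is undominated.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .containers import FeatureTable

__all__ = [
    "PROCESSES",
    "cophenetic_distances",
    "beta_mntd",
    "beta_mntd_matrix",
    "beta_nti",
    "raup_crick_bray",
    "classify_process",
    "classify_pairs",
    "summarize_fractions",
]

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)


def cophenetic_distances(tree: TreeNode) -> DistanceMatrix:
    """Patristic (tip-to-tip branch-length path sum) distances over taxa."""
    return tree.tip_tip_distances()


def beta_mntd(p_a: np.ndarray, p_b: np.ndarray, taxon_dist: np.ndarray) -> float:
    """Abundance-weighted β-mean-nearest-taxon distance between two communities.

    0.5·[Σ_{i∈A} p_a(i)·min_{j∈B} d(i,j) + Σ_{j∈B} p_b(j)·min_{i∈A} d(i,j)],
    minima over taxa with nonzero abundance in the other community; a taxon
    present in both contributes a nearest-taxon distance of 0.
    """
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    D = np.asarray(taxon_dist, dtype=float)
    if p_a.sum() == 0 or p_b.sum() == 0:
        raise ValueError("beta_mntd requires two non-empty communities")
    p_a = p_a / p_a.sum()
    p_b = p_b / p_b.sum()
    sup_a, sup_b = p_a > 0, p_b > 0
    term_a = p_a[sup_a] @ D[np.ix_(sup_a, sup_b)].min(axis=1)
    term_b = p_b[sup_b] @ D[np.ix_(sup_b, sup_a)].min(axis=1)
    return float(0.5 * (term_a + term_b))


def _bmntd_all_pairs(P: np.ndarray, D: np.ndarray, supports: np.ndarray) -> np.ndarray:
    """βMNTD for every sample pair at once.

    With M[s, i] = min_{j in support(s)} d(i, j), the matrix G = P·Mᵀ has
    G[a, b] = Σ_i p_a(i)·(nearest-taxon distance of i into community b), so
    the full βMNTD matrix is (G + Gᵀ)/2.
    """
    n_samples, n_taxa = P.shape
    M = np.empty((n_samples, n_taxa))
    for s in range(n_samples):
        M[s] = D[:, supports[s]].min(axis=1)
    G = P @ M.T
    return 0.5 * (G + G.T)


def beta_mntd_matrix(table: FeatureTable, tree: TreeNode, weighted: bool = True) -> pd.DataFrame:
    """Observed βMNTD between all sample pairs."""
    D, P, supports = _prepare(table, tree, weighted)
    out = _bmntd_all_pairs(P, D, supports)
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=table.sample_ids, columns=table.sample_ids)


def _prepare(table: FeatureTable, tree: TreeNode, weighted: bool):
    dm = cophenetic_distances(tree)
    missing = sorted(set(table.taxon_ids) - set(dm.ids))
    if missing:
        raise KeyError(f"taxa missing from the tree: {missing}")
    D = dm.filter(table.taxon_ids).data
    P = table.proportions()
    supports = P > 0
    if not weighted:
        P = supports / supports.sum(axis=1, keepdims=True)
    return D, P, supports


def beta_nti(
    table: FeatureTable,
    tree: TreeNode,
    n_null: int = 1000,
    seed: int = 0,
    weighted: bool = True,
) -> pd.DataFrame:
    """βNTI z-scores for all sample pairs.

    Each null replicate permutes the taxon labels across the phylogeny tips
    (abundances untouched) and recomputes βMNTD for every pair against the
    permuted distances; βNTI = (obs − mean_null) / sd_null.  Pairs whose
    null distribution has zero spread (e.g. a star phylogeny, where
    shuffling cannot change any distance) are flagged unclassifiable and
    returned as NaN.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if n_null < 100:
        raise ValueError("n_null must be >= 100 for a usable null distribution")
    D, P, supports = _prepare(table, tree, weighted)
    n_taxa = D.shape[0]
    obs = _bmntd_all_pairs(P, D, supports)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    acc = np.zeros_like(obs)
    acc2 = np.zeros_like(obs)
    for _ in range(n_null):
        perm = rng.permutation(n_taxa)
        null = _bmntd_all_pairs(P, D[np.ix_(perm, perm)], supports)
        acc += null
        acc2 += null**2
    mean = acc / n_null
    var = np.maximum(acc2 / n_null - mean**2, 0.0) * n_null / (n_null - 1)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    z[sd <= 1e-12] = np.nan
    np.fill_diagonal(z, np.nan)
    iu = np.triu_indices(table.n_samples, k=1)
    if np.isnan(z[iu]).any():
        warnings.warn(
            f"{int(np.isnan(z[iu]).sum())} sample pair(s) have a degenerate "
            "null (sd = 0) and are flagged unclassifiable",
            stacklevel=2,
        )
    return pd.DataFrame(z, index=table.sample_ids, columns=table.sample_ids)


def _bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    tot = x.sum() + y.sum()
    return float(np.abs(x - y).sum() / tot) if tot else 0.0


def raup_crick_bray(
    table: FeatureTable, n_null: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Raup–Crick Bray–Curtis for all sample pairs, rescaled to [−1, 1].

    Null communities preserve each sample's observed richness and total
    count: species are drawn without replacement with probability
    proportional to their occurrence frequency across samples, then the
    sample's total abundance is allocated multinomially with probability
    proportional to the mean relative abundance of the drawn species.
    RCbray = 2·[(#null < obs) + ½·(#null = obs)]/n_null − 1.
    """
    if table.is_relative:
        raise ValueError("raup_crick_bray operates on counts (pre-TSS)")
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    X = table.to_numpy()
    n_samples, n_taxa = X.shape
    richness = (X > 0).sum(axis=1)
    if np.any(richness == 0):
        empty = [table.sample_ids[i] for i in np.flatnonzero(richness == 0)]
        raise ValueError(f"samples with zero richness: {empty}")
    totals = X.sum(axis=1).astype(int)
    occ_freq = (X > 0).mean(axis=0)
    mean_rel = (X / X.sum(axis=1, keepdims=True)).mean(axis=0)
    log_occ = np.log(np.where(occ_freq > 0, occ_freq, 1e-300))

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = np.zeros((n_samples, n_samples))
    buf_a = np.zeros(n_taxa)
    buf_b = np.zeros(n_taxa)
    for a, b in combinations(range(n_samples), 2):
        obs = _bray_curtis(X[a], X[b])
        # Gumbel-top-k: weighted sampling without replacement, vectorized
        keys_a = log_occ + rng.gumbel(size=(n_null, n_taxa))
        keys_b = log_occ + rng.gumbel(size=(n_null, n_taxa))
        idx_a = np.argpartition(keys_a, n_taxa - richness[a], axis=1)[:, n_taxa - richness[a]:]
        idx_b = np.argpartition(keys_b, n_taxa - richness[b], axis=1)[:, n_taxa - richness[b]:]
        below = equal = 0
        for k in range(n_null):
            buf_a[:] = 0.0
            buf_b[:] = 0.0
            pa = mean_rel[idx_a[k]]
            pb = mean_rel[idx_b[k]]
            buf_a[idx_a[k]] = rng.multinomial(totals[a], pa / pa.sum())
            buf_b[idx_b[k]] = rng.multinomial(totals[b], pb / pb.sum())
            null_bc = _bray_curtis(buf_a, buf_b)
            if null_bc < obs - 1e-12:
                below += 1
            elif abs(null_bc - obs) <= 1e-12:
                equal += 1
        out[a, b] = out[b, a] = 2.0 * (below + 0.5 * equal) / n_null - 1.0
    return pd.DataFrame(out, index=table.sample_ids, columns=table.sample_ids)


def classify_process(bnti: float, rcbray: float) -> str:
    """Assign a sample pair to one of the five assembly processes.

    Thresholds are exactly ±2 (βNTI) and ±0.95 (RCbray), with boundary
    values assigned to the stochastic / undominated side.
    """
    if np.isnan(bnti) or np.isnan(rcbray):
        raise ValueError("classify_process requires finite bnti and rcbray")
    if bnti > 2:
        return "heterogeneous_selection"
    if bnti < -2:
        return "homogeneous_selection"
    if rcbray > 0.95:
        return "dispersal_limitation"
    if rcbray < -0.95:
        return "homogenizing_dispersal"
    return "undominated"


def classify_pairs(
    bnti: pd.DataFrame,
    rcbray: pd.DataFrame,
    groups: pd.Series | None = None,
    within_groups: bool = True,
) -> pd.DataFrame:
    """Long-format per-pair table: sample_a, sample_b, bnti, rcbray, process.

    With ``groups`` given and ``within_groups`` true (the default), only
    pairs whose two samples share a group are classified — matching
    per-group assembly summaries.  Degenerate pairs (NaN βNTI) get process
    ``unclassifiable``.
    """
    ids = list(bnti.index)
    rows = []
    for a, b in combinations(ids, 2):
        if groups is not None and within_groups and groups[a] != groups[b]:
            continue
        z = bnti.loc[a, b]
        rc = rcbray.loc[a, b]
        if np.isnan(z):
            proc = "unclassifiable"
        else:
            proc = classify_process(z, rc)
        rows.append(
            {
                "sample_a": a,
                "sample_b": b,
                "group": groups[a] if groups is not None and groups[a] == groups[b] else None,
                "bnti": z,
                "rcbray": rc,
                "process": proc,
            }
        )
    return pd.DataFrame(rows)


def summarize_fractions(pairs: pd.DataFrame, by_group: bool = True) -> pd.DataFrame:
    """Fraction of classified pairs per assembly process (per group).

    Unclassifiable pairs are excluded from the denominator and reported in
    their own column; fractions over the five processes sum to 1.
    """
    keys = ["group"] if (by_group and "group" in pairs.columns) else []

    def _one(sub: pd.DataFrame) -> pd.Series:
        classified = sub[sub["process"] != "unclassifiable"]
        n = len(classified)
        fracs = {p: (classified["process"] == p).sum() / n if n else np.nan for p in PROCESSES}
        fracs["n_pairs"] = n
        fracs["n_unclassifiable"] = int((sub["process"] == "unclassifiable").sum())
        return pd.Series(fracs)

    if keys:
        groups = []
        for g, sub in pairs.groupby("group", dropna=True):
            if len(sub) < 1:
                warnings.warn(f"group {g!r} has no within-group pairs; skipped", stacklevel=2)
                continue
            groups.append(_one(sub).rename(g))
        return pd.DataFrame(groups).rename_axis("group")
    return _one(pairs).to_frame("all").T
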