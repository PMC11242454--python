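"""Permutation tests on distance matrices and rank-based group comparisons.

ANOSIM and PERMANOVA are implemented directly on the squared/ranked distance
matrices so that large permutation counts and repeated calibration runs stay
cheap; both are cross-checked against scikit-bio in the test suite.  All
permutation p-values use the (count + 1)/(n_perm + 1) estimator, which can
never return p = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnosimResult",
    "PermanovaResult",
    "anosim",
    "permanova",
    "pairwise_wilcoxon_fdr",
]


@dataclass
class AnosimResult:
    R: float
    p: float
    n_perm: int


@dataclass
class PermanovaResult:
    factor: str
    R2: float
    pseudo_F: float
    p: float
    n_perm: int


def _check_groups(labels: np.ndarray, min_size: int = 2) -> None:
    levels, counts = np.unique(labels, return_counts=True)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    small = levels[counts < min_size]
    if small.size:
        raise ValueError(f"groups with fewer than {min_size} members: {small.tolist()}")


def _as_labels(grouping, ids) -> np.ndarray:
    if isinstance(grouping, pd.Series):
        return grouping.loc[list(ids)].to_numpy()
    return np.asarray(grouping)


def anosim(dm: DistanceMatrix, grouping, n_perm: int = 999, seed: int = 0) -> AnosimResult:
    """Analysis of similarities on ranked distances.

    R = (mean between-group rank − mean within-group rank) / (N(N−1)/4),
    with ranks over the N(N−1)/2 pairwise distances.  The p-value is the
    fraction of label permutations with R at least as large as observed.
    """
    labels = _as_labels(grouping, dm.ids)
    _check_groups(labels)
    n = len(labels)
    ranks = rankdata(squareform(dm.data, checks=False))
    denom = n * (n - 1) / 4.0

    i_idx, j_idx = np.triu_indices(n, k=1)

    def r_stat(lab: np.ndarray) -> float:
        within = lab[i_idx] == lab[j_idx]
        return float((ranks[~within].mean() - ranks[within].mean()) / denom)

    r_obs = r_stat(labels)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    count = 0
    for _ in range(n_perm):
        if r_stat(rng.permutation(labels)) >= r_obs:
            count += 1
    return AnosimResult(R=r_obs, p=(count + 1) / (n_perm + 1), n_perm=n_perm)


def permanova(
    dm: DistanceMatrix,
    grouping,
    n_perm: int = 999,
    seed: int = 0,
    factor: str = "factor",
) -> PermanovaResult:
    """One-factor PERMANOVA (distance-based sum-of-squares partition).

    SS_total = Σ_{i<j} d²_ij / N; SS_within = Σ_groups Σ_{i<j ∈ g} d²_ij / n_g;
    pseudo-F = (SS_between/(a−1)) / (SS_within/(N−a)); R² = SS_between/SS_total.
    The p-value comes from free permutation of the group labels.
    """
    labels = _as_labels(grouping, dm.ids)
    _check_groups(labels)
    n = len(labels)
    levels, inverse = np.unique(labels, return_inverse=True)
    a = len(levels)
    d2 = dm.data**2
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n

    # indicator trick: SS_within = sum_g (1_g' D2 1_g) / (2 n_g)
    def ss_within(inv: np.ndarray) -> float:
        ss = 0.0
        for g in range(a):
            mask = inv == g
            ss += d2[np.ix_(mask, mask)].sum() / (2.0 * mask.sum())
        return ss

    def f_stat(inv: np.ndarray) -> tuple[float, float]:
        ssw = ss_within(inv)
        ssa = ss_total - ssw
        if ssw == 0:  # perfect separation: all variation between groups
            return ssa, np.inf
        return ssa, (ssa / (a - 1)) / (ssw / (n - a))

    ssa_obs, f_obs = f_stat(inverse)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    count = 0
    for _ in range(n_perm):
        if f_stat(rng.permutation(inverse))[1] >= f_obs:
            count += 1
    return PermanovaResult(
        factor=factor,
        R2=float(ssa_obs / ss_total),
        pseudo_F=float(f_obs),
        p=(count + 1) / (n_perm + 1),
        n_perm=n_perm,
    )


def _wilcoxon_two_sided(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum p-value: exact enumeration for small untied samples,
    tie-corrected normal approximation otherwise."""
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied; Wilcoxon p set to 1", stacklevel=3)
        return float(len(x) * len(y) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = max(len(x), len(y)) <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def pairwise_wilcoxon_fdr(
    values: pd.DataFrame | pd.Series,
    groups: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests with Benjamini–Hochberg FDR.

    ``values`` holds one column per feature (a Series is treated as a single
    feature); every group pair × feature combination is tested and the BH
    adjustment runs across the whole family.  Rows are flagged significant
    at q < ``alpha``.
    """
    if isinstance(values, pd.Series):
        values = values.to_frame(values.name or "value")
    groups = groups.loc[values.index]
    levels = sorted(groups.unique())
    for g in levels:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    rows = []
    for g1, g2 in combinations(levels, 2):
        x_idx = groups.index[groups == g1]
        y_idx = groups.index[groups == g2]
        for feat in values.columns:
            stat, p = _wilcoxon_two_sided(
                values.loc[x_idx, feat].to_numpy(dtype=float),
                values.loc[y_idx, feat].to_numpy(dtype=float),
            )
            rows.append({"feature": feat, "group_a": g1, "group_b": g2, "statistic": stat, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = out["q"] < alpha
    return out
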