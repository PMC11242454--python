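"""Null-model machinery: βMNTD against hand expansion, βNTI degeneracy and
branch-scale invariance, RCbray bounds and tails, and the five-process
classification thresholds."""

import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from rhizobiome import assembly
from rhizobiome.containers import FeatureTable
from rhizobiome.simulate import (
    AssemblyRegime,
    simulate_community,
    simulate_phylogeny,
    simulate_trait_optima,
)

import oracles


class TestCopheneticDistances:
    def test_two_tip_path(self):
        tree = TreeNode.read(io.StringIO("(A:0.3,B:0.7);"))
        dm = assembly.cophenetic_distances(tree)
        assert dm["A", "B"] == pytest.approx(1.0)

    def test_symmetric_zero_diagonal(self):
        tree = simulate_phylogeny(12, seed=0)
        dm = assembly.cophenetic_distances(tree)
        assert np.allclose(dm.data, dm.data.T)
        assert np.allclose(np.diag(dm.data), 0)

    def test_matches_path_walk_oracle(self):
        tree = simulate_phylogeny(5, seed=8)
        taxa = [t.name for t in tree.tips()]
        dm = assembly.cophenetic_distances(tree).filter(taxa)
        np.testing.assert_allclose(dm.data, oracles.cophenetic_oracle(tree, taxa), atol=1e-10)


class TestBetaMntd:
    def test_identical_communities_zero(self):
        D = np.array([[0, 1.0], [1.0, 0]])
        assert assembly.beta_mntd([0.5, 0.5], [0.5, 0.5], D) == 0.0

    def test_single_taxon_each_side(self):
        D = np.array([[0, 2.0], [2.0, 0]])
        assert assembly.beta_mntd([1, 0], [0, 1], D) == pytest.approx(2.0)

    def test_three_taxon_hand_expansion(self):
        D = np.array([[0.0, 1.0, 4.0], [1.0, 0.0, 2.0], [4.0, 2.0, 0.0]])
        pa, pb = [0.5, 0.5, 0.0], [0.0, 0.5, 0.5]
        # A side: taxon0 -> nearest in B is taxon1 (d=1); taxon1 shared -> 0
        # B side: taxon1 shared -> 0; taxon2 -> nearest in A is taxon1 (d=2)
        expected = 0.5 * ((0.5 * 1.0 + 0.5 * 0.0) + (0.5 * 0.0 + 0.5 * 2.0))
        assert assembly.beta_mntd(pa, pb, D) == pytest.approx(expected)
        assert assembly.beta_mntd(pa, pb, D) == pytest.approx(
            oracles.beta_mntd_oracle(pa, pb, D.tolist())
        )

    def test_empty_community_rejected(self):
        D = np.zeros((2, 2))
        with pytest.raises(ValueError, match="non-empty"):
            assembly.beta_mntd([0, 0], [1, 0], D)

    def test_matrix_is_symmetric_and_matches_scalar(self, dataset):
        sub = dataset.table.select_samples(dataset.table.sample_ids[:5])
        mat = assembly.beta_mntd_matrix(sub, dataset.tree)
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T)
        D = assembly.cophenetic_distances(dataset.tree).filter(sub.taxon_ids).data
        P = sub.proportions()
        expected = assembly.beta_mntd(P[0], P[1], D)
        assert mat.iloc[0, 1] == pytest.approx(expected, abs=1e-12)


class TestBetaNti:
    def test_star_phylogeny_flagged_degenerate(self):
        """All tips equidistant: shuffling cannot change βMNTD, sd = 0."""
        newick = "(" + ",".join(f"t{i}:1.0" for i in range(8)) + ");"
        tree = TreeNode.read(io.StringIO(newick))
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 20, size=(4, 8))
        counts[:, :4] = 0  # partial overlap so bMNTD > 0
        counts[0, 0] = 5
        table = FeatureTable(
            pd.DataFrame(counts, index=[f"s{i}" for i in range(4)],
                         columns=[f"t{i}" for i in range(8)])
        )
        with pytest.warns(UserWarning, match="degenerate"):
            z = assembly.beta_nti(table, tree, n_null=100, seed=0)
        assert z.isna().to_numpy()[np.triu_indices(4, 1)].any()

    def test_invariant_to_branch_length_scaling(self, dataset):
        sub = dataset.table.select_samples(dataset.table.sample_ids[:6])
        z1 = assembly.beta_nti(sub, dataset.tree, n_null=150, seed=5)
        scaled = dataset.tree.copy()
        for node in scaled.traverse(include_self=False):
            node.length *= 10.0
        z2 = assembly.beta_nti(sub, scaled, n_null=150, seed=5)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-6)

    def test_symmetric(self, dataset):
        sub = dataset.table.select_samples(dataset.table.sample_ids[:5])
        z = assembly.beta_nti(sub, dataset.tree, n_null=120, seed=2)
        np.testing.assert_allclose(z.to_numpy(), z.to_numpy().T, equal_nan=True)

    def test_minimum_null_count_enforced(self, dataset):
        with pytest.raises(ValueError, match="n_null"):
            assembly.beta_nti(dataset.table, dataset.tree, n_null=10)


class TestRaupCrickBray:
    def test_bounded(self, dataset):
        sub = dataset.table.select_samples(dataset.table.sample_ids[:5])
        rc = assembly.raup_crick_bray(sub, n_null=100, seed=0)
        vals = rc.to_numpy()[np.triu_indices(5, 1)]
        assert (vals >= -1).all() and (vals <= 1).all()

    def test_identical_rich_samples_strongly_negative(self):
        """Two identical diverse samples are far more similar than the null."""
        rng = np.random.default_rng(3)
        base = rng.integers(1, 30, size=60)
        pool = rng.integers(0, 30, size=(8, 60))  # background occurrence variation
        counts = np.vstack([base, base, pool])
        table = FeatureTable(
            pd.DataFrame(counts, index=[f"s{i}" for i in range(10)],
                         columns=[f"t{j}" for j in range(60)])
        )
        successes = 0
        for seed in range(10):
            rc = assembly.raup_crick_bray(table, n_null=150, seed=seed)
            successes += rc.iloc[0, 1] < -0.95
        assert successes >= 8

    def test_disjoint_island_samples_strongly_positive(self):
        """Cross-island pairs under dispersal limitation hit the +1 tail."""
        tree = simulate_phylogeny(200, seed=4)
        optima = simulate_trait_optima(tree, 1.0, seed=5)
        successes = 0
        for seed in range(10):
            table, groups = simulate_community(
                tree, optima, AssemblyRegime("dispersal_limitation"), 8, 1000, seed=seed
            )
            rc = assembly.raup_crick_bray(table, n_null=150, seed=seed)
            cross = [
                rc.iloc[a, b]
                for a in range(8) for b in range(a + 1, 8)
                if groups.iloc[a] != groups.iloc[b]
            ]
            successes += np.median(cross) > 0.95
        assert successes >= 8

    def test_relative_table_rejected(self, dataset):
        from rhizobiome.preprocessing import tss_normalize
        with pytest.raises(ValueError, match="counts"):
            assembly.raup_crick_bray(tss_normalize(dataset.table), n_null=100)


class TestClassifyProcess:
    @pytest.mark.parametrize(
        "bnti,rc,expected",
        [
            (2.5, 0.0, "heterogeneous_selection"),
            (-2.5, 0.0, "homogeneous_selection"),
            (0.5, 0.97, "dispersal_limitation"),
            (0.1, -0.97, "homogenizing_dispersal"),
            (0.0, 0.0, "undominated"),
            # boundary values fall on the stochastic / undominated side
            (2.0, 0.0, "undominated"),
            (-2.0, 0.0, "undominated"),
            (0.0, 0.95, "undominated"),
            (0.0, -0.95, "undominated"),
        ],
    )
    def test_thresholds(self, bnti, rc, expected):
        assert assembly.classify_process(bnti, rc) == expected

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            assembly.classify_process(float("nan"), 0.0)


class TestSummarizeFractions:
    def _pairs(self, processes, group="g"):
        return pd.DataFrame(
            {
                "sample_a": [f"a{i}" for i in range(len(processes))],
                "sample_b": [f"b{i}" for i in range(len(processes))],
                "group": group,
                "bnti": 0.0,
                "rcbray": 0.0,
                "process": processes,
            }
        )

    def test_single_process_fractions(self):
        out = assembly.summarize_fractions(self._pairs(["homogeneous_selection"] * 4))
        assert out.loc["g", "homogeneous_selection"] == 1.0
        assert out.loc["g", list(assembly.PROCESSES)].sum() == pytest.approx(1.0)

    def test_fractions_sum_to_one_with_unclassifiable_reported(self):
        procs = ["undominated", "dispersal_limitation", "unclassifiable"]
        out = assembly.summarize_fractions(self._pairs(procs))
        assert out.loc["g", list(assembly.PROCESSES)].sum() == pytest.approx(1.0)
        assert out.loc["g", "n_unclassifiable"] == 1

    def test_rcbray_invariant_to_taxon_relabeling(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 20, size=(4, 30))
        counts[:, 0] += 1
        t1 = FeatureTable(
            pd.DataFrame(counts, index=list("abcd"), columns=[f"t{j}" for j in range(30)])
        )
        t2 = FeatureTable(
            pd.DataFrame(counts, index=list("abcd"), columns=[f"renamed_{j}" for j in range(30)])
        )
        rc1 = assembly.raup_crick_bray(t1, n_null=120, seed=9)
        rc2 = assembly.raup_crick_bray(t2, n_null=120, seed=9)
        np.testing.assert_allclose(rc1.to_numpy(), rc2.to_numpy(), atol=1e-12)
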