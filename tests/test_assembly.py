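"""betaMNTD/betaNTI, NST and the mother-daughter permutation test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vinherit.assembly import (
    beta_mntd,
    beta_mntd_profiles,
    beta_nti,
    md_permutation_test,
    nst,
    nst_pairwise,
    pair_stochasticity,
    significance_stars,
)
from vinherit.core_io import CommunityTable, Family, FamilyDesign, ValidationError
from conftest import brute_force_beta_mntd, random_phylogeny_matrix


def community(counts, taxa=None):
    counts = np.asarray(counts)
    names = [f"s{i}" for i in range(counts.shape[1])]
    taxa = taxa or [f"T{i + 1:04d}" for i in range(counts.shape[0])]
    meta = pd.DataFrame({
        "chateau": "X", "compartment": "leaf",
        "generation": ["PM"] + ["PF"] * (len(names) - 1),
        "lineage": "L1", "vine_id": names,
    }, index=pd.Index(names, name="sample_id"))
    return CommunityTable(counts, taxa, names, meta)


class TestBetaMntd:
    def test_identical_communities_zero(self):
        D = np.array([[0.0, 2.0], [2.0, 0.0]])
        assert beta_mntd_profiles([0.5, 0.5], [0.5, 0.5], D) == 0.0

    def test_two_singleton_communities_hand_value(self):
        D = np.array([[0.0, 2.0], [2.0, 0.0]])
        assert beta_mntd_profiles([1.0, 0.0], [0.0, 1.0], D) == pytest.approx(2.0)

    def test_empty_sample_rejected(self):
        D = np.zeros((2, 2))
        with pytest.raises(ValidationError, match="empty"):
            beta_mntd_profiles([0.0, 0.0], [1.0, 0.0], D)

    def test_missing_tip_named(self, small_study):
        from vinherit.simulate import simulate_tree

        table, *_ = small_study
        small_tree = simulate_tree(3, 1)  # only T0001..T0003
        with pytest.raises(ValidationError, match="T0"):
            beta_mntd(table, small_tree, tuple(table.sample_ids[:2]))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        D = random_phylogeny_matrix(rng, n)
        f = rng.dirichlet(np.ones(n)) * (rng.random(n) > 0.3)
        g = rng.dirichlet(np.ones(n)) * (rng.random(n) > 0.3)
        if f.sum() == 0 or g.sum() == 0:
            return
        f, g = f / f.sum(), g / g.sum()
        got = beta_mntd_profiles(f, g, D)
        want = brute_force_beta_mntd(list(f), list(g), D.tolist())
        assert got == pytest.approx(want, abs=1e-12)


class TestBetaNti:
    def test_identical_communities_nonpositive(self):
        from vinherit.simulate import simulate_tree

        phylo = simulate_tree(12, 3)
        counts = np.tile(np.arange(1, 13)[:, None], (1, 2))
        t = community(counts)
        res = beta_nti(t, phylo, [("s0", "s1")], n_null=99, seed=0)
        row = res.iloc[0]
        assert row["beta_mntd"] == 0.0
        assert row["degenerate_null"] or row["beta_nti"] <= 0

    def test_seed_determinism(self):
        from vinherit.simulate import simulate_tree

        phylo = simulate_tree(15, 4)
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 40, size=(15, 3))
        counts[0] += 1
        t = community(counts)
        pairs = [("s0", "s1"), ("s1", "s2")]
        r1 = beta_nti(t, phylo, pairs, n_null=99, seed=5)
        r2 = beta_nti(t, phylo, pairs, n_null=99, seed=5)
        pd.testing.assert_frame_equal(r1, r2)

    def test_branch_rescaling_leaves_z_invariant(self):
        """betaNTI is scale-free: multiplying all branch lengths by c
        rescales betaMNTD but not the Z-score."""
        from vinherit.simulate import simulate_tree

        phylo = simulate_tree(10, 8)
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 30, size=(10, 2))
        counts[:2] += 1
        t = community(counts)
        r1 = beta_nti(t, phylo, [("s0", "s1")], n_null=199, seed=9)
        scaled = phylo.prune_to(phylo.tip_labels)
        for edge in scaled.tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * 7.5
        r2 = beta_nti(t, scaled, [("s0", "s1")], n_null=199, seed=9)
        assert r2["beta_mntd"].iloc[0] == pytest.approx(7.5 * r1["beta_mntd"].iloc[0])
        assert r2["beta_nti"].iloc[0] == pytest.approx(r1["beta_nti"].iloc[0], abs=1e-9)

    def test_too_few_nulls_rejected(self, small_study):
        table, phylo, *_ = small_study
        with pytest.raises(ValidationError, match="n_null"):
            beta_nti(table, phylo, [tuple(table.sample_ids[:2])], n_null=10)


class TestNst:
    def test_pair_stochasticity_definitions(self):
        # observed equals null expectation -> fully stochastic (ST = 1)
        assert pair_stochasticity(np.array(0.4), np.array(0.4)) == pytest.approx(1.0)
        # identical communities vs a nonzero null expectation -> deterministic
        assert pair_stochasticity(np.array(1.0), np.array(0.3)) == pytest.approx(0.0)
        # complete divergence under a similar null -> deterministic
        assert pair_stochasticity(np.array(0.0), np.array(0.6)) == pytest.approx(0.0)

    def test_family_of_one_skipped(self):
        rng = np.random.default_rng(2)
        t = community(rng.integers(1, 20, size=(8, 3)))
        design = FamilyDesign(("X", "leaf", "bacteria"), [
            Family("L1", "s0", ["s1", "s2"]),
            Family("L2", "sZ", []),  # mother sample absent, no daughters
        ])
        with pytest.warns(UserWarning, match="fewer than 2"):
            out = nst(t, design, n_null=50, seed=1)
        assert list(out["lineage"]) == ["L1"]
        assert 0.0 <= out["nst"].iloc[0] <= 1.0

    def test_null_expectation_within_bounds(self):
        rng = np.random.default_rng(3)
        t = community(rng.integers(0, 25, size=(12, 5)) + (rng.random((12, 5)) < 0.3))
        G, E = nst_pairwise(t, n_null=80, seed=4)
        assert np.all((E >= 0) & (E <= 1))
        assert np.all((G >= 0) & (G <= 1))
        np.testing.assert_allclose(G, G.T)


class TestMdPermutationTest:
    @staticmethod
    def design(n_fam=4, dpm=2):
        fams = [Family(f"L{i}", f"m{i}", [f"d{i}_{j}" for j in range(dpm)])
                for i in range(n_fam)]
        return FamilyDesign(("X", "leaf", "bacteria"), fams)

    def test_assignment_invariant_statistic_is_degenerate(self):
        out = md_permutation_test(lambda m, ds: 1.0, self.design(), n_perm=49, seed=0)
        assert out["degenerate_null"].all()
        assert out["z_score"].isna().all()

    def test_two_singleton_families_resolution_floor(self):
        """With 2 families of 1 daughter only 2 distinct assignments exist, so
        the exact p is 1/2 per mother; sampled permutations jitter around it
        but can never suggest significance."""
        values = {"d0_0": 0.1, "d1_0": 0.9}
        out = md_permutation_test(
            lambda m, ds: values[ds[0]], self.design(2, 1), n_perm=199, seed=1)
        assert (out["p_value"] >= 0.4).all()

    def test_exchangeable_values_give_moderate_p(self):
        rng = np.random.default_rng(5)
        values = {f"d{i}_{j}": rng.normal() for i in range(4) for j in range(2)}
        out = md_permutation_test(
            lambda m, ds: float(np.mean([values[d] for d in ds])),
            self.design(), n_perm=199, seed=2)
        assert (out["p_value"] > 0.001).all()

    def test_single_family_rejected(self):
        with pytest.raises(ValidationError, match=">= 2 families"):
            md_permutation_test(lambda m, ds: 0.0, self.design(1), n_perm=9)

    def test_stars(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.2) == ""
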