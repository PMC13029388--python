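"""Synthetic-community generator: trees, traits, assembly, full studies."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from vinherit.beta import bray_curtis
from vinherit.simulate import (
    SimulationConfig,
    assemble_sample,
    evolve_optima,
    filtering_weights,
    paper_preset,
    simulate_study,
    simulate_tree,
)


class TestSimulateTree:
    def test_two_taxa_cherry_equal_depths(self):
        phylo = simulate_tree(2, seed=5)
        _, D = phylo.patristic_matrix()
        depths = [leaf.distance_from_root() for leaf in phylo.tree.leaf_node_iter()]
        assert depths[0] == pytest.approx(depths[1])

    def test_ultrametric(self):
        phylo = simulate_tree(20, seed=2)
        depths = [leaf.distance_from_root() for leaf in phylo.tree.leaf_node_iter()]
        assert np.ptp(depths) < 1e-9

    def test_distinct_seeds_distinct_topologies(self):
        assert simulate_tree(50, 1).as_newick() != simulate_tree(50, 2).as_newick()

    def test_seed_reproducibility(self):
        assert simulate_tree(30, 7).as_newick() == simulate_tree(30, 7).as_newick()


class TestEvolveOptima:
    def test_zero_rate_gives_zero_optima(self):
        phylo = simulate_tree(10, 1)
        assert (evolve_optima(phylo, 0.0, 3) == 0).all()

    def test_seed_reproducibility(self):
        phylo = simulate_tree(10, 1)
        assert evolve_optima(phylo, 1.0, 4).equals(evolve_optima(phylo, 1.0, 4))

    def test_cherry_covariance_matches_shared_path(self):
        """Empirical tip covariance over replicate draws equals bm_rate times
        the shared root-to-ancestor path length (Brownian-motion closed form)."""
        import dendropy

        from vinherit.core_io import Phylogeny

        tree = dendropy.Tree.get(data="((A:1.0,B:1.0):2.0,C:3.0);", schema="newick")
        phylo = Phylogeny(tree=tree)
        rate = 0.7
        draws = np.array([
            evolve_optima(phylo, rate, seed)[["A", "B", "C"]].to_numpy()
            for seed in range(1500)
        ])
        cov_ab = np.cov(draws[:, 0], draws[:, 1])[0, 1]
        var_a = draws[:, 0].var(ddof=1)
        assert cov_ab == pytest.approx(rate * 2.0, rel=0.15)   # shared path = 2
        assert var_a == pytest.approx(rate * 3.0, rel=0.15)    # total depth = 3
        assert abs(np.cov(draws[:, 0], draws[:, 2])[0, 1]) < 0.15  # no shared path


class TestAssembleSample:
    def test_neutral_limit_proportional_to_base(self):
        base = np.array([4.0, 1.0, 3.0])
        p = filtering_weights(np.array([0.0, 5.0, -2.0]), 0.0, 1e9, base)
        np.testing.assert_allclose(p, base / base.sum(), atol=1e-12)

    def test_strong_selection_excludes_distant_taxon(self):
        p = filtering_weights(np.array([0.0, 10.0]), 0.0, 1.0, np.array([1.0, 1.0]))
        assert p[0] == pytest.approx(1.0, abs=1e-20)
        # ratio p1/p2 = exp(50): taxon 2 effectively absent
        counts = assemble_sample(np.array([0.0, 10.0]), 0.0, 1.0,
                                 np.array([1.0, 1.0]), depth=10000, rng=1)
        assert counts[1] == 0

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            assemble_sample(np.zeros(2), 0.0, 1.0, np.ones(2), depth=0, rng=1)

    def test_all_zero_base_rejected(self):
        with pytest.raises(ValueError, match="all zero"):
            filtering_weights(np.zeros(2), 0.0, 1.0, np.zeros(2))


class TestSimulateStudy:
    def test_full_transmission_limit(self):
        cfg = SimulationConfig(n_taxa=30, n_sites=1, families_per_site=2,
                               daughters_per_mother=1, compartments=("leaf",),
                               depth=1_000_000, v=1.0, sigma_sel=1e9, seed=4)
        table, _, designs, _ = simulate_study(cfg)
        F = table.relative_abundance()
        for _, mother, daughter in designs[0].md_pairs():
            l1 = np.abs(F[:, table.sample_index(mother)]
                        - F[:, table.sample_index(daughter)]).sum()
            assert l1 < 0.01

    def test_paper_preset_counts(self):
        cfg = paper_preset(n_taxa=12, depth=100)
        table, _, designs, _ = simulate_study(cfg)
        leaf = [d for d in designs if d.stratum[1] == "leaf"]
        assert sum(len(d.families) for d in leaf) == 47
        assert sum(len(f.daughters) for d in leaf for f in d.families) == 151
        assert table.n_samples == 2 * (47 + 151)

    def test_truth_probabilities_sum_to_one(self, small_study):
        *_, truth = small_study
        np.testing.assert_allclose(truth.expected_abundance.sum(axis=0), 1.0, atol=1e-12)

    def test_library_sizes_near_depth(self, small_study):
        table, *_ = small_study
        sizes = table.library_sizes()
        # Poisson(2000): all sizes within 6 sd of the mean
        assert np.all(np.abs(sizes - 2000) < 6 * np.sqrt(2000))

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(n_taxa=20, n_sites=1, families_per_site=2,
                               daughters_per_mother=2, depth=500, seed=9)
        t1, *_ = simulate_study(cfg)
        t2, *_ = simulate_study(cfg)
        np.testing.assert_array_equal(t1.counts, t2.counts)

    def test_adding_samples_never_perturbs_existing(self):
        """Per-sample hashed RNG streams: growing the design keeps shared
        samples' counts identical."""
        base = dict(n_taxa=20, n_sites=1, families_per_site=2, depth=500,
                    compartments=("leaf",), seed=9)
        t1, *_ = simulate_study(SimulationConfig(daughters_per_mother=1, **base))
        t2, *_ = simulate_study(SimulationConfig(daughters_per_mother=3, **base))
        shared = [s for s in t1.sample_ids if s in set(t2.sample_ids)]
        assert shared
        for s in shared:
            np.testing.assert_array_equal(
                t1.counts[:, t1.sample_index(s)], t2.counts[:, t2.sample_index(s)])

    def test_v0_daughters_exchangeable(self):
        """Without transmission, daughter-to-own-mother distances look like
        daughter-to-other-mother distances."""
        own, other = [], []
        for seed in range(5):
            cfg = SimulationConfig(n_taxa=40, n_sites=1, families_per_site=4,
                                   daughters_per_mother=2, compartments=("leaf",),
                                   depth=2000, v=0.0, seed=100 + seed)
            table, _, designs, _ = simulate_study(cfg)
            dm = bray_curtis(table)
            design = designs[0]
            for fam in design.families:
                for d in fam.daughters:
                    own.append(dm[fam.mother, d])
                    for g in design.families:
                        if g.lineage != fam.lineage:
                            other.append(dm[g.mother, d])
        p = mannwhitneyu(own, other).pvalue
        assert p > 0.01

    def test_mother_daughter_distance_decreases_with_v(self):
        means = []
        for v in (0.0, 0.5, 1.0):
            dists = []
            for seed in range(3):
                cfg = SimulationConfig(n_taxa=40, n_sites=1, families_per_site=3,
                                       daughters_per_mother=2, compartments=("leaf",),
                                       depth=2000, v=v, seed=200 + seed)
                table, _, designs, _ = simulate_study(cfg)
                dm = bray_curtis(table)
                dists.extend(dm[m, d] for _, m, d in designs[0].md_pairs())
            means.append(np.mean(dists))
        assert means[0] > means[1] > means[2]
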