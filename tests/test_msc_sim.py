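import math

import msprime
import numpy as np
import pytest

from plastcap.msc_sim import SimulationConfig, simulate_gene_tree, simulate_null_trees
from plastcap.trees import TreeError, nontrivial_splits, parse_newick, write_newick


def _is_concordant_triplet(gene_tree, pair):
    """True if the two labels in ``pair`` are sisters in a 3-leaf tree."""
    for child in gene_tree.root.children:
        if not child.is_leaf:
            labs = set()
            stack = [child]
            while stack:
                n = stack.pop()
                if n.is_leaf:
                    labs.add(n.label)
                stack.extend(n.children)
            return labs == set(pair)
    raise AssertionError("no cherry found")


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_sims=0)
        with pytest.raises(ValueError):
            SimulationConfig(ploidy_factor=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(samples_per_species=0)

    def test_json_roundtrip(self):
        cfg = SimulationConfig(n_sims=5, ploidy_factor=2.0, seed=3)
        assert '"n_sims": 5' in cfg.to_json()


class TestSimulateGeneTree:
    def test_single_species_single_sample(self):
        sp = parse_newick("A;")
        g = simulate_gene_tree(sp, SimulationConfig(seed=1))
        assert g.leaf_labels() == ["A"]

    def test_leaf_labels_match_species(self):
        sp = parse_newick("((A:1,B:1):1,C:2);")
        g = simulate_gene_tree(sp, SimulationConfig(seed=1))
        assert sorted(g.leaf_labels()) == ["A", "B", "C"]

    def test_multi_sample_suffixing(self):
        sp = parse_newick("(A:1,B:1);")
        g = simulate_gene_tree(sp, SimulationConfig(seed=1, samples_per_species=3))
        assert sorted(g.leaf_labels()) == ["A_1", "A_2", "A_3", "B_1", "B_2", "B_3"]

    def test_lineage_and_coalescence_count(self):
        sp = parse_newick("(((A:1,B:1):1,C:2):1,D:3);")
        cfg = SimulationConfig(seed=9, samples_per_species=2)
        g = simulate_gene_tree(sp, cfg)
        n_leaves = g.n_leaves
        assert n_leaves == 8
        internals = sum(1 for n in g.preorder() if not n.is_leaf)
        assert internals == n_leaves - 1  # strictly bifurcating

    def test_polytomy_rejected(self):
        sp = parse_newick("(A:1,B:1,C:1);")
        with pytest.raises(TreeError, match="bifurcating"):
            simulate_gene_tree(sp, SimulationConfig(seed=1))

    def test_missing_lengths_rejected(self):
        sp = parse_newick("((A,B),C);")
        with pytest.raises(TreeError, match="missing"):
            simulate_gene_tree(sp, SimulationConfig(seed=1))

    def test_gene_depth_at_least_species_depth(self):
        sp = parse_newick("((A:0.5,B:0.5):0.5,C:1.0);")
        cfg = SimulationConfig(seed=4)
        for r in range(200):
            g = simulate_gene_tree(sp, cfg, replicate_index=r)
            assert g.depth() >= sp.depth() - 1e-12

    def test_ultrametric_preserved(self):
        sp = parse_newick("(((A:1,B:1):1,C:2):1,D:3);")
        for r in range(50):
            g = simulate_gene_tree(sp, SimulationConfig(seed=6), replicate_index=r)
            assert g.is_ultrametric(1e-9)

    def test_zero_length_edge_passes_lineages_through(self):
        # internal edge of length 0: the cherry cannot coalesce inside it,
        # so all three topologies occur (anisomorphy of a hard polytomy)
        sp = parse_newick("((A:1,B:1):0,C:1);")
        cfg = SimulationConfig(seed=12)
        seen = set()
        for r in range(300):
            g = simulate_gene_tree(sp, cfg, replicate_index=r)
            for pair in (("A", "B"), ("A", "C"), ("B", "C")):
                if _is_concordant_triplet(g, pair):
                    seen.add(pair)
        assert seen == {("A", "B"), ("A", "C"), ("B", "C")}

    def test_two_species_mean_root_time(self):
        # divergence T=2.0: root age is T + Exponential(1); mean over
        # 10,000 replicates within +-0.03 of 3.0
        sp = parse_newick("(A:2.0,B:2.0);")
        cfg = SimulationConfig(n_sims=10_000, ploidy_factor=1.0, seed=7)
        depths = [t.depth() for t in simulate_null_trees(sp, cfg)]
        assert np.mean(depths) == pytest.approx(3.0, abs=0.03)

    def test_three_taxon_concordance_oracle(self):
        # P(concordant) = 1 - (2/3) e^{-t} with internal edge t = 1
        sp = parse_newick("((A:1.0,B:1.0):1.0,C:2.0);")
        cfg = SimulationConfig(n_sims=10_000, ploidy_factor=1.0, seed=42)
        trees = simulate_null_trees(sp, cfg)
        frac = np.mean([_is_concordant_triplet(t, ("A", "B")) for t in trees])
        assert frac == pytest.approx(1 - (2 / 3) * math.exp(-1), abs=0.01)


class TestSimulateNullTrees:
    def test_count_and_determinism(self):
        sp = parse_newick("((A:1,B:1):1,C:2);")
        cfg = SimulationConfig(n_sims=3, seed=5)
        run1 = [write_newick(t) for t in simulate_null_trees(sp, cfg)]
        run2 = [write_newick(t) for t in simulate_null_trees(sp, cfg)]
        assert len(run1) == 3
        assert run1 == run2

    def test_replicates_independent_of_order(self):
        sp = parse_newick("((A:1,B:1):1,C:2);")
        cfg = SimulationConfig(n_sims=5, seed=5)
        batch = [write_newick(t) for t in simulate_null_trees(sp, cfg)]
        from plastcap.trees import scale_branch_lengths

        scaled = scale_branch_lengths(sp, cfg.ploidy_factor)
        solo = write_newick(simulate_gene_tree(scaled, cfg, replicate_index=3))
        assert solo == batch[3]

    def test_ploidy_scaling_raises_concordance(self):
        # factor 4 on internal edge 1 -> 1 - (2/3) e^{-4}
        sp = parse_newick("((A:1.0,B:1.0):1.0,C:2.0);")
        cfg = SimulationConfig(n_sims=10_000, ploidy_factor=4.0, seed=13)
        trees = simulate_null_trees(sp, cfg)
        frac = np.mean([_is_concordant_triplet(t, ("A", "B")) for t in trees])
        assert frac == pytest.approx(1 - (2 / 3) * math.exp(-4), abs=0.005)

    def test_huge_ploidy_factor_freezes_topology(self):
        sp = parse_newick("(((A:1,B:1):1,C:2):1,D:3);")
        cfg = SimulationConfig(n_sims=100, ploidy_factor=1e6, seed=2)
        expected = nontrivial_splits(sp)
        for t in simulate_null_trees(sp, cfg):
            assert nontrivial_splits(t) == expected

    def test_monophyly_monotone_in_stem_length(self):
        # concordance is non-decreasing in the internal edge length
        fracs = []
        for i, t_len in enumerate((0.2, 1.0, 2.5)):
            sp = parse_newick(f"((A:1.0,B:1.0):{t_len},C:{1.0 + t_len});")
            cfg = SimulationConfig(n_sims=5_000, ploidy_factor=1.0, seed=100 + i)
            trees = simulate_null_trees(sp, cfg)
            fracs.append(np.mean([_is_concordant_triplet(t, ("A", "B")) for t in trees]))
        assert fracs[0] < fracs[1] < fracs[2]


class TestAgainstMsprime:
    """Cross-check topology frequencies against msprime (independent
    coalescent implementation), within 3 combined Monte-Carlo SEs."""

    N = 4000

    def _msprime_triplet_freq(self, t_internal):
        dem = msprime.Demography()
        for name in ("A", "B", "C", "AB", "ABC"):
            dem.add_population(name=name, initial_size=1.0)
        dem.add_population_split(time=t_internal, derived=["A", "B"], ancestral="AB")
        dem.add_population_split(
            time=2.0 * t_internal, derived=["AB", "C"], ancestral="ABC"
        )
        reps = msprime.sim_ancestry(
            samples={"A": 1, "B": 1, "C": 1},
            demography=dem,
            ploidy=1,
            num_replicates=self.N,
            random_seed=77,
        )
        hits = 0
        for ts in reps:
            tree = ts.first()
            if tree.mrca(0, 1) != tree.root:
                hits += 1
        return hits / self.N

    def test_three_taxon_frequency_agreement(self):
        t_int = 0.8
        sp = parse_newick(f"((A:{t_int},B:{t_int}):{t_int},C:{2 * t_int});")
        cfg = SimulationConfig(n_sims=self.N, ploidy_factor=1.0, seed=55)
        ours = np.mean(
            [
                _is_concordant_triplet(t, ("A", "B"))
                for t in simulate_null_trees(sp, cfg)
            ]
        )
        theirs = self._msprime_triplet_freq(t_int)
        se = math.sqrt(2 * 0.25 / self.N)
        assert abs(ours - theirs) < 3 * se

    def test_four_taxon_split_frequency_agreement(self):
        # balanced quartet, both cherries with stem 1.0
        sp = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        cfg = SimulationConfig(n_sims=self.N, ploidy_factor=1.0, seed=56)
        from plastcap.trees import Split

        target = Split("ABCD", "AB")
        ours = np.mean(
            [target in nontrivial_splits(t) for t in simulate_null_trees(sp, cfg)]
        )

        dem = msprime.Demography()
        for name in ("A", "B", "C", "D", "AB", "CD", "R"):
            dem.add_population(name=name, initial_size=1.0)
        dem.add_population_split(time=1.0, derived=["A", "B"], ancestral="AB")
        dem.add_population_split(time=1.0, derived=["C", "D"], ancestral="CD")
        dem.add_population_split(time=2.0, derived=["AB", "CD"], ancestral="R")
        reps = msprime.sim_ancestry(
            samples={"A": 1, "B": 1, "C": 1, "D": 1},
            demography=dem,
            ploidy=1,
            num_replicates=self.N,
            random_seed=78,
        )
        hits = 0
        for ts in reps:
            tree = ts.first()
            # unrooted split AB|CD exists iff AB or CD forms a rooted clade
            ab_clade = set(tree.leaves(tree.mrca(0, 1))) == {0, 1}
            cd_clade = set(tree.leaves(tree.mrca(2, 3))) == {2, 3}
            if ab_clade or cd_clade:
                hits += 1
        theirs = hits / self.N
        se = math.sqrt(2 * 0.25 / self.N)
        assert abs(ours - theirs) < 3 * se
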