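"""Operation-graph construction, pruning, decompression and measures."""

from __future__ import annotations

import numpy as np
import pytest

from ogsim import genotype_models as gm
from ogsim.fixtures import random_og
from ogsim.genotype_models import SequenceGenotype
from ogsim.operation_graph import IntegrityError, OperationGraph


def chain(n_mutations: int, root_seq: str = "ACGTACGTAC", unit_cost: float = 1.0):
    """root -> m1 -> ... -> mk chain of point mutations."""
    og = OperationGraph()
    nodes = [og.add_root(SequenceGenotype(root_seq))]
    for i in range(n_mutations):
        pos = 1 + i % len(root_seq)
        base = "ACGT"[(i + 1) % 4]
        nodes.append(og.add_mutation(nodes[-1], gm.point_mutation(pos, base, cost=unit_cost)))
    return og, nodes


class TestConstruction:
    def test_mutation_chain_counts(self):
        og, _ = chain(10)
        assert len(og) == 11
        assert og.edge_count == 10

    def test_example_counts(self, example_og):
        assert len(example_og) == 12
        assert example_og.edge_count == 12

    def test_add_mutation_leaves_existing_parents_alone(self):
        og, nodes = chain(3)
        before = {i: og.nodes[i].parents for i in og.nodes}
        og.add_mutation(nodes[1], gm.point_mutation(2, "T"))
        for i, parents in before.items():
            assert og.nodes[i].parents == parents

    def test_recombination_in_degree_and_acyclicity(self):
        og, nodes = chain(3)
        r = og.add_recombination(nodes[1], nodes[3], gm.crossover(4))
        assert len(og.nodes[r].parents) == 2
        og.check_invariants()

    def test_self_recombination_allowed(self):
        og, nodes = chain(1)
        r = og.add_recombination(nodes[1], nodes[1], gm.crossover(3))
        assert og.nodes[r].parents == (nodes[1], nodes[1])
        assert og.edge_count == 1 + 2

    def test_unknown_parent_rejected(self):
        og, _ = chain(1)
        with pytest.raises(KeyError):
            og.add_mutation(999, gm.point_mutation(1, "T"))

    def test_arity_enforced(self):
        og, nodes = chain(1)
        with pytest.raises(ValueError):
            og.add_mutation(nodes[0], gm.crossover(2))
        with pytest.raises(ValueError):
            og.add_recombination(nodes[0], nodes[1], gm.point_mutation(1, "T"))


class TestAnc:
    def test_explicit_node_is_its_own_anc(self, example_og):
        assert example_og.anc(0) == {0}
        assert example_og.anc(2) == {2}

    def test_example_anc_of_i_is_c(self, example_og):
        # C(V) = {a, c}; the only path a->c->f->i has c as lowest explicit
        assert example_og.anc(8) == {2}

    def test_recombination_child_with_both_parents_explicit(self):
        og, nodes = chain(2)
        og.set_label(nodes[1], og.decompress(nodes[1]))
        og.set_label(nodes[2], og.decompress(nodes[2]))
        r = og.add_recombination(nodes[1], nodes[2], gm.crossover(4))
        assert og.anc(r) == {nodes[1], nodes[2]}


class TestDecompress:
    def test_explicit_returns_stored_label(self, example_og):
        assert example_og.decompress(0) is example_og.nodes[0].label

    def test_worked_point_mutation(self):
        og = OperationGraph()
        root = og.add_root(SequenceGenotype("ACCAAAT"))
        child = og.add_mutation(root, gm.point_mutation(3, "T"))
        assert og.decompress(child).bases == "ACTAAAT"

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_replay_oracle(self, seed, replay):
        og = random_og(n_nodes=25, recomb_fraction=0.3, seed=seed, cached_mode="random")
        for x in og.nodes:
            assert og.decompress(x) == replay(og, x)

    def test_partial_matches_full(self, replay):
        rng = np.random.default_rng(1)
        for seed in range(25):
            og = random_og(n_nodes=20, recomb_fraction=0.25, seed=seed,
                           cached_mode="random")
            for x in og.nodes:
                full = og.decompress(x).bases
                for pos in rng.integers(1, len(full) + 1, size=5):
                    assert og.partial_decompress(x, int(pos)) == full[int(pos) - 1]

    def test_partial_out_of_range(self, example_og):
        with pytest.raises(IndexError):
            example_og.partial_decompress(0, 21)

    def test_compressed_root_is_integrity_error(self):
        og, nodes = chain(2)
        og.set_label(nodes[2], og.decompress(nodes[2]))
        og.nodes[nodes[0]].label = None  # corrupt deliberately
        og._cached.discard(nodes[0])
        with pytest.raises(IntegrityError):
            og.decompress(nodes[1])


class TestPrune:
    def test_dead_chain_collapses_to_root(self):
        og, nodes = chain(2)
        deleted = og.prune_lost(nodes[2])
        assert deleted == {nodes[1], nodes[2]}
        assert set(og.nodes) == {nodes[0]}

    def test_lost_internal_node_with_descendants_survives(self):
        og, nodes = chain(2)
        og.nodes[nodes[2]].weight = 1
        assert og.prune_lost(nodes[1]) == set()
        assert nodes[1] in og.nodes

    def test_leaf_under_active_parent(self):
        og, nodes = chain(2)
        og.nodes[nodes[1]].weight = 3
        assert og.prune_lost(nodes[2]) == {nodes[2]}
        assert nodes[1] in og.nodes

    def test_active_node_rejected(self):
        og, nodes = chain(1)
        og.nodes[nodes[1]].weight = 2
        with pytest.raises(ValueError):
            og.prune_lost(nodes[1])

    def test_prune_keeps_active_nodes_decompressible(self, replay):
        for seed in range(20):
            og = random_og(n_nodes=25, recomb_fraction=0.2, seed=seed,
                           cached_mode="random")
            before = {x: og.decompress(x) for x in og.active_ids()}
            leaves = [i for i, n in og.nodes.items() if n.is_leaf]
            for leaf in leaves[: len(leaves) // 2]:
                og.nodes[leaf].weight = 0
                og.prune_lost(leaf)
            og.check_invariants()
            for x, genotype in before.items():
                if x in og.nodes and og.nodes[x].weight > 0:
                    assert og.decompress(x) == genotype


class TestMeasures:
    def test_cost_zero_for_explicit(self, example_og):
        for x in example_og.cached_set:
            assert example_og.cost(x) == 0.0

    def test_chain_cost(self):
        og, nodes = chain(2)
        assert og.cost(nodes[2]) == 2.0
        assert og.cost(nodes[1]) == 1.0

    def test_cost_between_off_path_is_zero(self):
        og, nodes = chain(2)
        side = og.add_mutation(nodes[0], gm.point_mutation(5, "T"))
        assert og.cost_between(nodes[2], side) == 0.0

    def test_chain_load(self):
        og, nodes = chain(2)
        og.nodes[nodes[2]].weight = 1
        assert og.load(nodes[1]) == og.cost_between(nodes[2], nodes[1]) == 1.0
        # compressed active node demands its own operation
        assert og.load(nodes[2]) == 1.0

    def test_no_dependent_actives_means_zero_load(self):
        og, nodes = chain(2)
        assert og.load(nodes[1]) == 0.0

    def test_cost_depends_on_cost_assignment(self):
        light, nodes_a = chain(3, unit_cost=1.0)
        heavy, nodes_b = chain(3, unit_cost=2.5)
        assert light.cost(nodes_a[3]) != heavy.cost(nodes_b[3])

    def test_anc_path_cost_consistency(self, replay):
        # summing the per-node contributions along decompression paths
        # reproduces cost(x)
        for seed in range(15):
            og = random_og(n_nodes=18, recomb_fraction=0.25, seed=seed,
                           cached_mode="random")
            for x in og.nodes:
                if og.nodes[x].is_explicit:
                    continue
                applied = [v for v in og.need(x) if not og.nodes[v].is_explicit]
                assert og.cost(x) == pytest.approx(
                    sum(og.nodes[v].op.cost for v in applied))


class TestStructureInvariants:
    @pytest.mark.parametrize("recomb", [0.0, 0.3])
    def test_edge_count_identity(self, recomb):
        for seed in range(10):
            og = random_og(n_nodes=30, recomb_fraction=recomb, seed=seed)
            n_recomb = len(og.recombination_ids())
            assert og.edge_count == (len(og) - len(og.root_ids)) + n_recomb

    def test_mutation_only_graphs_are_trees(self):
        og = random_og(n_nodes=40, recomb_fraction=0.0, seed=2)
        for i, n in og.nodes.items():
            assert len(n.parents) == (0 if n.is_root else 1)


class TestExport:
    def test_networkx_round_trip(self, example_og):
        g = example_og.to_networkx()
        assert g.number_of_nodes() == 12
        assert g.number_of_edges() == 12
        assert g.nodes[0]["explicit"] is True
        assert g.nodes[3]["kind"] == "crossover"

    def test_graphml(self, example_og, tmp_path):
        import networkx as nx

        path = tmp_path / "og.graphml"
        example_og.write_graphml(path)
        g = nx.read_graphml(path)
        assert g.number_of_nodes() == 12

    def test_dot_structure(self, example_og, tmp_path):
        path = tmp_path / "og.dot"
        example_og.write_dot(path)
        text = path.read_text()
        assert text.startswith("digraph OG {")
        assert text.rstrip().endswith("}")
        assert text.count("->") == example_og.edge_count
        assert text.count("[shape=") == len(example_og)
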