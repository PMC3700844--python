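"""Deterministic small operation graphs: the twelve-node worked example and
seeded random instances backing the property tests.

The worked example is a 12-node, 12-edge graph with root ``a``, leaves
``j, k, h, e, l``, and one recombination node ``d`` (parents ``b`` and
``c``); the leaves plus internal node ``i`` are active at unit weight, all
operation costs are 1, and the starting cache is ``{a, c}``.  Running
Greedy-Load with budget k=4 in exact-load mode walks the cache through
``{a,c} -> {d,c} -> {d,i,e} -> {e,g,h,i}``, exercising every branch of
``advance``: pushing past a dead chain, stopping at a two-branch node,
stopping at an active internal node, and back-filling the budget.
"""

from __future__ import annotations

import numpy as np

from . import cache_policies as cp
from . import genotype_models as gm
from .genotype_models import ALPHABET, SequenceGenotype
from .operation_graph import OperationGraph

EXAMPLE_ROOT_SEQUENCE = "ACGTACGTACGTACGTACGT"
EXAMPLE_LETTERS = "abcdefghijkl"
EXAMPLE_ACTIVE = frozenset("ehijkl")

#: the cache trajectory of Greedy-Load (k=4, exact load) on the example
EXAMPLE_TRACE = (
    frozenset("ac"),
    frozenset("cd"),
    frozenset("dei"),
    frozenset("eghi"),
)


def letters(ids) -> frozenset[str]:
    """Map example node ids (creation order 0..11) to their letters a..l."""
    return frozenset(EXAMPLE_LETTERS[i] for i in ids)


def build_example_og() -> OperationGraph:
    """Construct the worked-example graph with concrete sequence genotypes,
    unit costs and the initial cache ``{a, c}``.

    Creation order is alphabetical, so node id ``i`` is letter
    ``EXAMPLE_LETTERS[i]``.  Edges: a->b, a->c, (b,c)->d, c->e, c->f, f->i,
    i->l, d->g, d->h, g->j, g->k."""
    og = OperationGraph()
    a = og.add_root(SequenceGenotype(EXAMPLE_ROOT_SEQUENCE))          # id 0
    b = og.add_mutation(a, gm.point_mutation(1, "C", cost=1.0))       # id 1
    c = og.add_mutation(a, gm.point_mutation(2, "G", cost=1.0))       # id 2
    d = og.add_recombination(b, c, gm.crossover(10, cost=1.0))        # id 3
    e = og.add_mutation(c, gm.point_mutation(3, "T", cost=1.0))       # id 4
    f = og.add_mutation(c, gm.point_mutation(4, "A", cost=1.0))       # id 5
    g = og.add_mutation(d, gm.point_mutation(5, "C", cost=1.0))       # id 6
    h = og.add_mutation(d, gm.point_mutation(6, "G", cost=1.0))       # id 7
    i = og.add_mutation(f, gm.point_mutation(7, "T", cost=1.0))       # id 8
    j = og.add_mutation(g, gm.point_mutation(8, "A", cost=1.0))       # id 9
    k = og.add_mutation(g, gm.point_mutation(9, "C", cost=1.0))       # id 10
    l = og.add_mutation(i, gm.point_mutation(10, "G", cost=1.0))      # id 11
    for node_id in (e, h, i, j, k, l):
        og.nodes[node_id].weight = 1
    og.set_label(c, og.decompress(c))
    og.check_invariants()
    return og


def trace_example(k: int = 4) -> list[frozenset[str]]:
    """Run Greedy-Load on the example in exact-load mode and return the
    cache snapshots as letter sets: the initial cache, the cache after the
    compress/advance sweep, and one snapshot per budget-growth step."""
    og = build_example_og()
    snapshots = [letters(og.cached_set)]

    def observer(stage: str, cached) -> None:
        snapshots.append(letters(cached))

    cp.greedy_load(og, k, exact_load=True, observer=observer)
    return snapshots


def random_og(
    n_nodes: int,
    recomb_fraction: float = 0.0,
    seed: int = 0,
    seq_length: int = 30,
    internal_active_fraction: float = 0.2,
    cached_mode: str = "root",
) -> OperationGraph:
    """A seeded random operation graph with concrete sequence genotypes.

    Nodes after the root are recombinations with probability
    ``recomb_fraction`` (two uniformly chosen existing parents, uniform
    breakpoint) and point mutations otherwise (uniform parent, uniform
    position, substitute base drawn from the three alternatives), so the
    edge count is ``(n_nodes - 1) + #recombinations`` by construction.
    Leaves are active; internal nodes are active with probability
    ``internal_active_fraction``.  ``cached_mode`` chooses the explicit set:
    ``"root"`` (only the root) or ``"random"`` (root plus each other node
    with probability 0.3)."""
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if not 0 <= recomb_fraction <= 1:
        raise ValueError("recomb_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    og = OperationGraph()
    bases = "".join(ALPHABET[v] for v in rng.integers(0, 4, size=seq_length))
    root = og.add_root(SequenceGenotype(bases))
    genotypes = {root: og.nodes[root].label}

    for _ in range(n_nodes - 1):
        existing = sorted(genotypes)
        if len(existing) >= 2 and rng.random() < recomb_fraction:
            pa, pb = (int(existing[int(rng.integers(len(existing)))]) for _ in range(2))
            bp = int(rng.integers(1, seq_length))
            op = gm.crossover(bp)
            geno = gm.apply(op, genotypes[pa], genotypes[pb])
            node = og.add_recombination(pa, pb, op, label=geno)
        else:
            pa = int(existing[int(rng.integers(len(existing)))])
            pos = int(rng.integers(1, seq_length + 1))
            cur = genotypes[pa].bases[pos - 1]
            new = ALPHABET[(ALPHABET.index(cur) + 1 + int(rng.integers(3))) % 4]
            op = gm.point_mutation(pos, new)
            geno = gm.apply(op, genotypes[pa])
            node = og.add_mutation(pa, op, label=geno)
        genotypes[node] = geno

    for i, n in og.nodes.items():
        if n.is_leaf:
            n.weight = 1 + int(rng.integers(0, 3))
        elif rng.random() < internal_active_fraction:
            n.weight = 1

    if cached_mode == "root":
        keep = {root}
    elif cached_mode == "random":
        keep = {root} | {i for i in og.nodes if i != root and rng.random() < 0.3}
    else:
        raise ValueError(f"unknown cached_mode {cached_mode!r}")
    for i in sorted(og.nodes):
        if i not in keep:
            og.clear_label(i)
    og.check_invariants()
    return og
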