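"""The operation graph: a rooted, labeled, weighted DAG compressing genotypes.

Every genotype that arises in a simulation is a node; the node stores the
evolutionary operation that produced it (point mutation, indel, crossover,
binding-site change) rather than the genotype itself.  A node whose genotype
label is stored uncompressed is *explicit* (cached); the set of explicit
nodes is ``C(V)``.  Any node's genotype can be reconstructed losslessly by
walking up to its lowest explicit ancestors (``Anc``) and re-applying the
operations on the way down.  Mutation nodes have one parent, recombination
nodes two, so mutation-only histories yield trees and recombination yields a
general DAG.

The module also provides the graph-quality measures used by the cache
policies: ``cost(x)`` (total operation cost to decompress ``x``),
``cost_between`` and the exact ``load(x)`` (frequency-weighted decompression
demand placed on ``x`` by the nodes beneath it).  Exact load enumerates
decompression paths and is intended for small graphs and tests; production
policy decisions use the per-node data-request counters maintained by
:mod:`ogsim.cache_policies` as a cheap proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from . import genotype_models as gm
from .genotype_models import Genotype, Operation, SequenceGenotype


class IntegrityError(RuntimeError):
    """The graph violates a structural invariant (e.g. a compressed root)."""


@dataclass(slots=True)
class OGNode:
    """One node of the operation graph.

    ``label`` is the genotype when the node is explicit, else ``None``.
    ``weight`` is the number of individuals currently carrying the genotype.
    ``request_count`` and ``required`` are maintained by the cache policies:
    the former counts data requests (the load proxy), the latter flags nodes
    needed to decompress some active genotype.  ``seq_length`` caches the
    sequence length so event positions can be sampled and bounds checked
    without decompressing (``None`` for pathway genotypes).
    """

    id: int
    op: Operation
    parents: tuple[int, ...]
    children: set[int] = field(default_factory=set)
    label: Genotype | None = None
    weight: int = 0
    request_count: float = 0.0
    required: bool = False
    seq_length: int | None = None

    @property
    def is_explicit(self) -> bool:
        return self.label is not None

    @property
    def is_root(self) -> bool:
        return not self.parents

    @property
    def is_leaf(self) -> bool:
        return not self.children


class OperationGraph:
    """Rooted weighted DAG of evolutionary operations with explicit-node
    bookkeeping.  Node ids are monotonically increasing integers; all
    tie-breaks elsewhere use the smaller id, which keeps runs deterministic.
    """

    def __init__(self) -> None:
        self.nodes: dict[int, OGNode] = {}
        self.root_ids: set[int] = set()
        self._cached: set[int] = set()
        self._next_id = 0
        # incremental totals: per-generation bookkeeping must not scan the
        # whole (ever-growing) ancestry, or per-generation time would grow
        # with simulation length
        self._edge_total = 0
        self._op_record_bytes = 0
        self._required_marked: set[int] = set()

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, node_id: int) -> bool:
        return node_id in self.nodes

    def node(self, node_id: int) -> OGNode:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise KeyError(f"no node {node_id} in operation graph") from None

    @property
    def cached_set(self) -> frozenset[int]:
        """C(V): ids of explicit (uncompressed) nodes."""
        return frozenset(self._cached)

    def active_ids(self) -> set[int]:
        """A(OG): ids of nodes with non-zero population frequency."""
        return {i for i, n in self.nodes.items() if n.weight > 0}

    @property
    def edge_count(self) -> int:
        return self._edge_total

    @property
    def operation_record_bytes(self) -> int:
        """Byte-model cost of all stored operation records."""
        return self._op_record_bytes

    def recombination_ids(self) -> set[int]:
        return {i for i, n in self.nodes.items() if len(n.parents) == 2}

    # -- label management --------------------------------------------------

    def set_label(self, node_id: int, genotype: Genotype) -> None:
        node = self.node(node_id)
        node.label = genotype
        if isinstance(genotype, SequenceGenotype):
            node.seq_length = genotype.length
        self._cached.add(node_id)

    def clear_label(self, node_id: int) -> None:
        """Compress a node.  Refuses to empty C(V): at least one explicit
        genotype must always remain, or nothing could ever be decompressed."""
        node = self.node(node_id)
        if node.label is None:
            return
        if self._cached == {node_id}:
            raise IntegrityError("cannot compress the last explicit node")
        node.label = None
        self._cached.discard(node_id)

    # -- construction ------------------------------------------------------

    def add_root(self, genotype: Genotype, weight: int = 0) -> int:
        node_id = self._new_node(gm.root_op(), (), weight)
        self.root_ids.add(node_id)
        self.set_label(node_id, genotype)
        return node_id

    def add_mutation(
        self,
        parent_id: int,
        op: Operation,
        weight: int = 0,
        label: Genotype | None = None,
    ) -> int:
        """Add a single-parent (mutation-class) node below ``parent_id``.

        The new node is created compressed unless ``label`` is supplied (the
        Store-Active policy materializes new genotypes immediately; the
        compressing policies do not)."""
        if op.arity != 1:
            raise ValueError(f"{op.kind} is not a single-parent operation")
        parent = self.node(parent_id)
        node_id = self._new_node(op, (parent_id,), weight)
        parent.children.add(node_id)
        node = self.nodes[node_id]
        if parent.seq_length is not None and op.kind in gm.SEQUENCE_KINDS:
            node.seq_length = gm.output_length(op, (parent.seq_length,))
        if label is not None:
            self.set_label(node_id, label)
        return node_id

    def add_recombination(
        self,
        parent_a_id: int,
        parent_b_id: int,
        op: Operation,
        weight: int = 0,
        label: Genotype | None = None,
    ) -> int:
        """Add a two-parent (recombination) node.  Parent order is
        meaningful and recorded: the first parent donates the prefix up to
        the breakpoint.  ``parent_a_id == parent_b_id`` is allowed
        (self-recombination copies the genotype)."""
        if op.arity != 2:
            raise ValueError(f"{op.kind} is not a two-parent operation")
        pa, pb = self.node(parent_a_id), self.node(parent_b_id)
        node_id = self._new_node(op, (parent_a_id, parent_b_id), weight)
        pa.children.add(node_id)
        pb.children.add(node_id)
        node = self.nodes[node_id]
        if pa.seq_length is not None and pb.seq_length is not None:
            node.seq_length = gm.output_length(op, (pa.seq_length, pb.seq_length))
        if label is not None:
            self.set_label(node_id, label)
        return node_id

    def _new_node(self, op: Operation, parents: tuple[int, ...], weight: int) -> int:
        node_id = self._next_id
        self._next_id += 1
        self.nodes[node_id] = OGNode(id=node_id, op=op, parents=parents, weight=weight)
        self._edge_total += len(parents)
        self._op_record_bytes += op.record_bytes
        return node_id

    # -- pruning -----------------------------------------------------------

    def prune_lost(self, x: int) -> set[int]:
        """Remove the chain of dead ancestry above a lost leaf.

        Precondition: ``x`` carries no individuals.  If ``x`` still has
        children nothing is removed (active genotypes may sit under it).
        Otherwise ``x`` and every ancestor that becomes a childless,
        zero-weight non-root node is deleted; deletion stops at nodes that
        are active, still have other descendants, or are roots.  The last
        remaining explicit node is never deleted, so every surviving active
        node stays decompressible."""
        node = self.node(x)
        if node.weight != 0:
            raise ValueError(f"node {x} is active (weight {node.weight})")
        if node.children:
            return set()
        deleted: set[int] = set()
        stack = [x]
        while stack:
            v = stack.pop()
            n = self.nodes.get(v)
            if n is None or n.children or n.weight != 0 or n.is_root:
                continue
            if self._cached == {v}:
                continue  # keep the last explicit genotype
            for p in set(n.parents):
                self.nodes[p].children.discard(v)
            del self.nodes[v]
            self._cached.discard(v)
            self._required_marked.discard(v)
            self._edge_total -= len(n.parents)
            self._op_record_bytes -= n.op.record_bytes
            deleted.add(v)
            stack.extend(set(n.parents))
        return deleted

    # -- decompression -----------------------------------------------------

    def need(self, x: int) -> set[int]:
        """The decompression closure of ``x``: ``x`` itself plus, for every
        compressed node reached, its parents, recursively — i.e. all nodes
        visited when decompressing ``x``, including the explicit boundary
        nodes where recursion stops."""
        seen: set[int] = set()
        stack = [x]
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            n = self.node(v)
            if v == x and n.is_explicit:
                break
            if not n.is_explicit:
                if n.is_root:
                    raise IntegrityError(f"compressed root {v} cannot be decompressed")
                stack.extend(n.parents)
        return seen

    def anc(self, x: int) -> set[int]:
        """Anc(x): the lowest explicit nodes between ``x`` and the root; for
        an explicit node this is ``{x}`` itself."""
        if self.node(x).is_explicit:
            return {x}
        return {v for v in self.need(x) if self.nodes[v].is_explicit}

    def decompress(self, x: int, memo: dict[int, Genotype] | None = None) -> Genotype:
        """Reconstruct the explicit genotype of ``x`` without altering any
        label.  Iterative post-order with memoization, so shared sub-paths
        (recombination ancestry) are applied once per call; pass a ``memo``
        dict to share work across several decompressions."""
        if memo is None:
            memo = {}
        stack = [x]
        while stack:
            v = stack[-1]
            if v in memo:
                stack.pop()
                continue
            n = self.node(v)
            if n.is_explicit:
                memo[v] = n.label
                stack.pop()
                continue
            if n.is_root:
                raise IntegrityError(f"compressed root {v} cannot be decompressed")
            pending = [p for p in n.parents if p not in memo]
            if pending:
                stack.extend(pending)
                continue
            vals = [memo[p] for p in n.parents]
            memo[v] = gm.apply(n.op, *vals)
            stack.pop()
        return memo[x]

    def partial_decompress(self, x: int, position: int) -> str:
        """Base at 1-based ``position`` of node ``x``'s sequence genotype,
        recovered by walking coordinate mappings up the graph to the first
        explicit ancestor instead of reconstructing the whole sequence.  At
        a recombination node only the parent owning the mapped coordinate is
        followed."""
        n = self.node(x)
        if n.seq_length is not None and not 1 <= position <= n.seq_length:
            raise IndexError(f"position {position} outside sequence of length {n.seq_length}")
        v, pos = x, position
        while True:
            n = self.node(v)
            if n.is_explicit:
                bases = n.label.bases
                if not 1 <= pos <= len(bases):
                    raise IndexError(f"mapped position {pos} outside node {v}")
                return bases[pos - 1]
            if n.is_root:
                raise IntegrityError(f"compressed root {v} cannot be decompressed")
            res = gm.apply_at(n.op, pos)
            if isinstance(res, str):
                return res
            v, pos = n.parents[res.parent_index], res.position

    # -- quality measures --------------------------------------------------

    def cost(self, x: int) -> float:
        """Total operation cost to decompress ``x``: the sum of c(v) over the
        compressed nodes in its decompression closure (``x`` included when
        compressed; the explicit boundary excluded).  Zero for explicit
        nodes."""
        if self.node(x).is_explicit:
            return 0.0
        return sum(
            self.nodes[v].op.cost for v in self.need(x) if not self.nodes[v].is_explicit
        )

    def cost_between(self, x: int, y: int) -> float:
        """Cost of the part of ``x``'s decompression that flows through
        ``y``: the summed cost of nodes on decompression paths from ``y``
        down to ``x``, excluding ``y`` and including ``x``.  Zero when ``y``
        is on no decompression path of ``x``.  ``cost_between(x, x)`` is
        ``c(x)`` for a compressed ``x`` (a compressed active node demands its
        own operation) and 0 for an explicit one."""
        if x == y:
            return 0.0 if self.node(x).is_explicit else self.node(x).op.cost
        needed = self.need(x)
        if y not in needed:
            return 0.0
        # nodes strictly between y and x must be compressed: decompression
        # restarts at explicit nodes, so a path through one is not used.
        allowed = {v for v in needed if v in (x, y) or not self.nodes[v].is_explicit}
        down: set[int] = set()  # reachable from y within allowed
        stack = [y]
        while stack:
            v = stack.pop()
            for ch in self.nodes[v].children:
                if ch in allowed and ch not in down:
                    down.add(ch)
                    stack.append(ch)
        if x not in down:
            return 0.0
        up: set[int] = {x}  # co-reachable to x within allowed
        stack = [x]
        while stack:
            v = stack.pop()
            for p in self.nodes[v].parents:
                if p in allowed and p not in up:
                    up.add(p)
                    stack.append(p)
        path_nodes = (down & up) - {y}
        return sum(self.nodes[v].op.cost for v in path_nodes)

    def load(self, x: int) -> float:
        """Exact load: summed over every node ``y`` with non-zero weight that
        needs ``x`` for decompression, the frequency ``w(y)`` times the cost
        of the decompression segment from ``x`` down to ``y``.  Exponential
        in the worst case on recombination-heavy graphs; use the request
        counters as a proxy at scale."""
        total = 0.0
        for y, n in self.nodes.items():
            if n.weight <= 0:
                continue
            contribution = self.cost_between(y, x)
            if contribution:
                total += n.weight * contribution
        return total

    # -- export ------------------------------------------------------------

    def to_networkx(self):
        """Export to a ``networkx.DiGraph`` (edges parent -> child) with
        explicit/weight/request/required/kind node attributes."""
        import networkx as nx

        g = nx.DiGraph()
        for i, n in sorted(self.nodes.items()):
            g.add_node(
                i,
                explicit=n.is_explicit,
                weight=n.weight,
                request_count=n.request_count,
                required=n.required,
                kind=n.op.kind,
            )
        for i, n in sorted(self.nodes.items()):
            for p in n.parents:
                g.add_edge(p, i)
        return g

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)

    def write_dot(self, path_or_handle) -> None:
        """Write the graph in Graphviz DOT syntax: boxes for explicit nodes,
        double circles for active ones."""
        own = isinstance(path_or_handle, (str, bytes)) or hasattr(path_or_handle, "__fspath__")
        fh = open(path_or_handle, "w") if own else path_or_handle
        try:
            fh.write("digraph OG {\n")
            for i, n in sorted(self.nodes.items()):
                shape = "box" if n.is_explicit else ("doublecircle" if n.weight > 0 else "circle")
                fh.write(
                    f'  n{i} [shape={shape}, label="{i}:{n.op.kind}\\n'
                    f'w={n.weight} req={n.request_count:g}"];\n'
                )
            for i, n in sorted(self.nodes.items()):
                for p in n.parents:
                    fh.write(f"  n{p} -> n{i};\n")
            fh.write("}\n")
        finally:
            if own:
                fh.close()

    # -- integrity ---------------------------------------------------------

    def check_invariants(self) -> None:
        """Raise :class:`IntegrityError` on any structural violation; used by
        tests and the example runner."""
        if not self._cached:
            raise IntegrityError("no explicit node in graph")
        for i in self._cached:
            if i not in self.nodes or self.nodes[i].label is None:
                raise IntegrityError(f"cached set out of sync at node {i}")
        for i, n in self.nodes.items():
            if n.label is not None and i not in self._cached:
                raise IntegrityError(f"explicit node {i} missing from cached set")
            if len(n.parents) not in (0, 1, 2):
                raise IntegrityError(f"node {i} has {len(n.parents)} parents")
            if n.is_root and i not in self.root_ids:
                raise IntegrityError(f"parentless node {i} not registered as root")
            for p in n.parents:
                if p not in self.nodes:
                    raise IntegrityError(f"node {i} references missing parent {p}")
                if i not in self.nodes[p].children:
                    raise IntegrityError(f"edge {p}->{i} missing from child set")
        if self._edge_total != sum(len(n.parents) for n in self.nodes.values()):
            raise IntegrityError("incremental edge total out of sync")
        if self._op_record_bytes != sum(n.op.record_bytes for n in self.nodes.values()):
            raise IntegrityError("incremental operation-byte total out of sync")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[int, int] = {}

        def visit(v: int) -> None:
            stack: list[tuple[int, Iterator[int]]] = [(v, iter(self.nodes[v].children))]
            state[v] = 1
            while stack:
                node_id, it = stack[-1]
                advanced = False
                for ch in it:
                    if state.get(ch) == 1:
                        raise IntegrityError(f"cycle through node {ch}")
                    if ch not in state:
                        state[ch] = 1
                        stack.append((ch, iter(self.nodes[ch].children)))
                        advanced = True
                        break
                if not advanced:
                    state[node_id] = 2
                    stack.pop()

        for v in self.nodes:
            if v not in state:
                visit(v)
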