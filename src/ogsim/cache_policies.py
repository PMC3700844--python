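"""Cache-management policies deciding which operation-graph nodes stay
explicit.

Three policies are provided:

* **Greedy-Load** — the bounded cache.  Keeps at most ``k`` explicit
  genotypes, re-evaluated every ``t`` generations.  Each application first
  compresses cached nodes no active genotype needs and pushes the remaining
  cache entries down toward the active frontier (:func:`advance`), then
  greedily decompresses the highest-demand children of the highest-demand
  cached nodes until the budget ``k`` is filled.
* **Store-Active** — the conventional simulator behaviour: every genotype
  present in the population is explicit, nothing else is.  No compression.
* **Store-Root** — maximal compression: only root genotypes are explicit.

Demand ("load") can be measured two ways, selected by
``PolicyState.exact_load``: the exact frequency-weighted path-cost sum
(:meth:`OperationGraph.load`; exponential worst case, used for tests and
small graphs) or the per-node data-request counters accumulated during the
simulation, a cheap proxy.  Zero-vs-non-zero load tests always use the
boolean *required* flag (is the node on some active genotype's decompression
path), which is exact and computable in linear time; a node can be required
while having seen no requests, e.g. when its genotype went untouched for a
whole period.
"""

from __future__ import annotations

from dataclasses import dataclass

from .operation_graph import IntegrityError, OperationGraph

GREEDY_LOAD = "greedy_load"
STORE_ACTIVE = "store_active"
STORE_ROOT = "store_root"
POLICIES = (GREEDY_LOAD, STORE_ACTIVE, STORE_ROOT)


@dataclass
class PolicyState:
    """Which policy is in force plus its parameters and trigger bookkeeping.

    ``k`` is the explicit-genotype budget and ``t`` the number of
    generations between Greedy-Load applications (``t=0``: every
    generation); both are ignored by the baseline policies.  With
    ``low_water_trigger`` set, Greedy-Load runs whenever the cache has
    drained below ``k/2`` instead of on the fixed cadence."""

    policy: str = GREEDY_LOAD
    k: int = 10
    t: int = 0
    exact_load: bool = False
    low_water_trigger: bool = False
    generation_counter: int = 0

    def __post_init__(self) -> None:
        if self.policy not in POLICIES:
            raise ValueError(f"unknown policy {self.policy!r}; choose from {POLICIES}")
        if self.k < 1:
            raise ValueError("cache budget k must be >= 1")
        if self.t < 0:
            raise ValueError("t must be >= 0")


# ---------------------------------------------------------------------------
# data-request proxy


def record_request(og: OperationGraph, x: int) -> None:
    """Count one data request against node ``x``.

    A request on an explicit node touches only that node.  A request on a
    compressed node propagates up every decompression path, incrementing the
    counter of each compressed node on the way; the explicit ancestors that
    terminate the paths are not incremented (their counters retain whatever
    they accumulated while they themselves were compressed)."""
    n = og.node(x)
    if n.is_explicit:
        n.request_count += 1
        return
    for v in og.need(x):
        nv = og.nodes[v]
        if not nv.is_explicit:
            nv.request_count += 1


def compute_required_flags(og: OperationGraph) -> dict[int, bool]:
    """Mark every node that lies on a decompression path of some active
    genotype (the active node itself, the compressed nodes above it, and the
    explicit boundary where decompression starts).  Linear in the number of
    nodes marked, not in graph size: only previously marked nodes are
    cleared.  Returns the flags (false for any node not in the mapping) and
    stores them on the nodes."""
    for v in og._required_marked:
        node = og.nodes.get(v)
        if node is not None:
            node.required = False
    visited: set[int] = set()
    stack = list(og.active_ids())
    for y in stack:
        visited.add(y)
    while stack:
        v = stack.pop()
        n = og.nodes[v]
        n.required = True
        if n.is_explicit:
            continue  # decompression restarts here; do not climb further
        for p in n.parents:
            if p not in visited:
                visited.add(p)
                stack.append(p)
    og._required_marked = visited
    return {i: og.nodes[i].required for i in visited}


# ---------------------------------------------------------------------------
# Greedy-Load


def advance(og: OperationGraph, x: int) -> int:
    """Maximally advance the explicit frontier from cached node ``x`` toward
    the leaves.

    Walks down from ``x`` through its dependent subgraph to the highest node
    ``y`` that is a leaf, is active, or has at least two compressed required
    children (a genuine branch point that must keep serving both sides).
    Descent proceeds only through a *unique* compressed required child —
    children already in C(V) do not depend on ``x`` and required traffic
    behind them never reaches ``x``.  If ``y`` differs from ``x``, ``y`` is
    decompressed and ``x`` compressed (net cache size unchanged).  Requires
    up-to-date required flags; recomputes them when labels move.  Returns
    the node now holding the cache slot."""
    node = og.node(x)
    if not node.is_explicit:
        raise ValueError(f"advance requires an explicit node, got compressed {x}")
    y = x
    while True:
        n = og.node(y)
        if n.is_leaf or n.weight > 0:
            break
        qualifying = sorted(
            c for c in n.children
            if og.nodes[c].required and not og.nodes[c].is_explicit
        )
        if len(qualifying) != 1:
            break  # 0: nothing below needs us; >=2: genuine branch point
        y = qualifying[0]
    if y != x:
        og.set_label(y, og.decompress(y))
        og.clear_label(x)
        compute_required_flags(og)
    return y


def greedy_load(
    og: OperationGraph,
    k: int,
    exact_load: bool = False,
    observer=None,
) -> frozenset[int]:
    """One application of Greedy-Load with cache budget ``k``.

    Phase 1 sweeps the current cache: nodes no longer required by any active
    genotype are compressed (their request counters reset; at least one
    explicit node is always kept), the rest are advanced toward the leaves.
    Phase 2 grows the cache back to ``k`` by repeatedly decompressing the
    max-load child of the max-load cached node, then advancing both; the
    child's request count is subtracted from its former explicit ancestors'
    counters.  Load is the exact measure or the request-count proxy per
    ``exact_load``; ties break to the smaller node id.  Afterwards
    ``|C(V)| <= k``.  Returns the new cached set.

    ``observer``, if given, is called as ``observer(stage, cached_set)``
    after phase 1 and after every phase-2 growth step — the hook behind the
    step-by-step example trace."""
    if k < 1:
        raise ValueError("cache budget k must be >= 1")

    def measured_load(v: int) -> float:
        return og.load(v) if exact_load else og.nodes[v].request_count

    # phase 1: compress the unneeded, advance the rest
    compute_required_flags(og)
    for x in sorted(og.cached_set):
        n = og.nodes.get(x)
        if n is None or not n.is_explicit:
            continue
        if not n.required:
            if len(og.cached_set) > 1:
                og.clear_label(x)
                n.request_count = 0
                compute_required_flags(og)
        else:
            advance(og, x)
    if observer is not None:
        observer("phase1", og.cached_set)

    # phase 2: grow the cache to k
    while len(og.cached_set) < k:
        compute_required_flags(og)
        candidates: dict[int, list[int]] = {}
        for x in og.cached_set:
            kids = [
                c for c in og.nodes[x].children
                if og.nodes[c].required and not og.nodes[c].is_explicit
            ]
            if kids:
                candidates[x] = kids
        if not candidates:
            break
        x = min(candidates, key=lambda v: (-measured_load(v), v))
        y = min(candidates[x], key=lambda v: (-measured_load(v), v))
        former_anc = og.anc(y)
        og.set_label(y, og.decompress(y))
        y_count = og.nodes[y].request_count
        for a in former_anc:
            if a in og.nodes:
                og.nodes[a].request_count = max(0.0, og.nodes[a].request_count - y_count)
        compute_required_flags(og)
        advance(og, y)
        if og.nodes[x].is_explicit:
            advance(og, x)
        if observer is not None:
            observer("grow", og.cached_set)
    return og.cached_set


# ---------------------------------------------------------------------------
# baseline policies


def store_active(og: OperationGraph) -> frozenset[int]:
    """Set C(V) to exactly the active set: decompress every active genotype
    (sharing decompression work across them), then compress the rest."""
    memo: dict = {}
    actives = og.active_ids()
    for y in sorted(actives):
        if not og.nodes[y].is_explicit:
            og.set_label(y, og.decompress(y, memo))
    for x in sorted(og.cached_set):
        if x not in actives:
            og.clear_label(x)
    return og.cached_set


def store_root(og: OperationGraph) -> frozenset[int]:
    """Set C(V) to the root set (maximum compression).  Roots must still be
    explicit — a compressed root is unrecoverable since operations are not
    invertible."""
    for r in og.root_ids:
        if not og.nodes[r].is_explicit:
            raise IntegrityError(f"root {r} is compressed; Store-Root cannot recover it")
    for x in sorted(og.cached_set):
        if x not in og.root_ids:
            og.clear_label(x)
    return og.cached_set


def apply_policy(og: OperationGraph, state: PolicyState) -> frozenset[int]:
    """Run the configured policy for one generation boundary and advance the
    generation counter.  Greedy-Load fires on its cadence (generations
    ``0, t, 2t, ...``; every generation for ``t=0``) or, with the low-water
    trigger, whenever the cache has drained below ``k/2``."""
    try:
        if state.policy == STORE_ACTIVE:
            return store_active(og)
        if state.policy == STORE_ROOT:
            return store_root(og)
        if state.low_water_trigger:
            due = len(og.cached_set) < state.k / 2
        else:
            due = state.generation_counter % max(state.t, 1) == 0
        if due:
            return greedy_load(og, state.k, exact_load=state.exact_load)
        return og.cached_set
    finally:
        state.generation_counter += 1
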