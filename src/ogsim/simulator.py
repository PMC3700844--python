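"""Neutral forward-time population simulation driving the operation graph.

The engine implements a haploid Wright–Fisher loop (non-overlapping
generations, each of the N offspring drawing its parent uniformly from the
previous generation) and a Moran variant (one birth–death replacement per
step, N steps reported as one generation).  Evolution is strictly neutral;
the per-individual "fitness evaluation" of a real simulator is stubbed as a
genotype data request so that cache-demand dynamics are realistic without
imposing selection.

Every evolutionary event becomes an operation-graph node; individuals are
node ids; a genotype is only materialized when the active cache policy
decides to store it.  All randomness flows through one seeded generator
with a fixed draw order (parent indices, recombination draws, event counts,
then per-offspring event parameters, in offspring order), so two runs with
the same seed — even under different cache policies — see the identical
event stream; this is what makes cross-policy losslessness checks exact.

Parameter rescaling follows the standard practice of trading population
size and run length against rates: a run at (N, u, c, G) with scaling
factor lambda reproduces the coalescent-scale behaviour of a population
lambda·N evolved for lambda·G generations at rates u/lambda and c/lambda,
preserving the products N·u and N·c.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from . import cache_policies as cp
from . import genotype_models as gm
from .genotype_models import (ALPHABET, EventRates, PathwayGenotype,
                              PlannedMutation, SequenceGenotype)
from .operation_graph import OperationGraph

WRIGHT_FISHER = "wright_fisher"
MORAN = "moran"

SEQUENCE = "sequence"
PATHWAY = "pathway"


@dataclass
class SimulationConfig:
    """Parameters of one simulation run.

    Rates are per base (sequence: ``u`` point mutation, ``u_i`` insertion,
    ``u_d`` deletion, ``c_rate`` crossover) or per potential binding site
    (pathway: ``u_l`` loss, ``u_g`` gain), per generation.  ``burn_in``
    generations run before metrics are recorded; ``None`` selects the
    conventional 10·N.  ``lambda_scale`` documents the rescaling factor the
    supplied parameters already embed (see :func:`rescale`)."""

    N: int = 100
    genotype: str = SEQUENCE
    L: int = 1000
    genes: int = 50
    u: float = 0.0
    u_i: float = 0.0
    u_d: float = 0.0
    c_rate: float = 0.0
    u_l: float = 0.0
    u_g: float = 0.0
    indel_mean_length: float = 3.0
    model: str = WRIGHT_FISHER
    generations: int = 100
    burn_in: int | None = 0
    lambda_scale: float = 1.0
    seed: int = 0
    policy: cp.PolicyState = field(default_factory=cp.PolicyState)
    fitness_requests: bool = True
    initial_pathway_density: float | None = None

    def __post_init__(self) -> None:
        if self.model not in (WRIGHT_FISHER, MORAN):
            raise ValueError(f"unknown model {self.model!r}")
        if self.genotype not in (SEQUENCE, PATHWAY):
            raise ValueError(f"unknown genotype model {self.genotype!r}")
        if self.N < 1:
            raise ValueError("population size N must be positive")
        if self.genotype == SEQUENCE and self.L < 2:
            raise ValueError("sequence length L must be >= 2")
        if self.genotype == PATHWAY and self.genes < 1:
            raise ValueError("gene count must be positive")
        for name in ("u", "u_i", "u_d", "c_rate", "u_l", "u_g"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be non-negative")
        if self.c_rate > 0 and self.genotype != SEQUENCE:
            raise ValueError("c_rate is meaningful only for sequence genotypes")
        if self.generations < 1:
            raise ValueError("generations must be positive")
        if self.burn_in is not None and self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")
        if self.lambda_scale < 1:
            raise ValueError("lambda_scale must be >= 1")

    @property
    def resolved_burn_in(self) -> int:
        return 10 * self.N if self.burn_in is None else self.burn_in

    @property
    def rates(self) -> EventRates:
        return EventRates(u=self.u, u_i=self.u_i, u_d=self.u_d,
                          u_l=self.u_l, u_g=self.u_g,
                          indel_mean_length=self.indel_mean_length)


@dataclass(frozen=True, slots=True)
class GenerationMetrics:
    """Per-generation instrumentation emitted after burn-in."""

    generation: int
    seconds_per_generation: float
    heap_bytes: int
    explicit_genotype_bytes: int
    operation_bytes: int
    cached_count: int
    node_count: int
    edge_count: int
    compression_ratio: float
    space_savings: float


@dataclass
class SimulationResult:
    """Final state handle: metrics plus the population as node ids into the
    operation graph."""

    config: SimulationConfig
    metrics: list[GenerationMetrics]
    population: np.ndarray
    og: OperationGraph
    policy: cp.PolicyState

    def population_genotypes(self) -> list:
        """Decompress the final population, one genotype per individual."""
        memo: dict = {}
        return [self.og.decompress(int(i), memo) for i in self.population]


@dataclass(frozen=True, slots=True)
class EffectiveParameters:
    effective_N: float
    effective_generations: float
    effective_u: float
    effective_c: float


def rescale(N: int, u: float, c_rate: float, generations: int,
            lambda_scale: float) -> EffectiveParameters:
    """Effective (unscaled) parameters a run represents under rescaling
    factor ``lambda_scale`` >= 1: population and generations scale up by
    lambda, rates scale down, so N·u and N·c are invariant."""
    if lambda_scale < 1:
        raise ValueError("lambda_scale must be >= 1")
    return EffectiveParameters(
        effective_N=N * lambda_scale,
        effective_generations=generations * lambda_scale,
        effective_u=u / lambda_scale,
        effective_c=c_rate / lambda_scale,
    )


# ---------------------------------------------------------------------------
# batch decompression sessions


class GenotypeSession:
    """One event's worth of reads against a node's genotype.

    Opening the session issues a single data request (batch-decompression
    accounting: counters move once per event, not once per base).  Single
    positions are served by partial decompression; :meth:`full` materializes
    the sequence once and reuses it, so an event touching many bases costs
    exactly one decompression."""

    def __init__(self, og: OperationGraph, node_id: int, count_requests: bool = True):
        self.og = og
        self.node_id = node_id
        self.decompressions = 0
        self._full: SequenceGenotype | None = None
        if count_requests:
            cp.record_request(og, node_id)

    def base(self, position: int) -> str:
        if self._full is not None:
            return self._full.bases[position - 1]
        return self.og.partial_decompress(self.node_id, position)

    def full(self) -> SequenceGenotype:
        if self._full is None:
            node = self.og.node(self.node_id)
            if not node.is_explicit:
                self.decompressions += 1
            self._full = self.og.decompress(self.node_id)
        return self._full


def batch_decompress(og: OperationGraph, x: int, count_requests: bool = True) -> GenotypeSession:
    """Open a read session on node ``x`` (see :class:`GenotypeSession`)."""
    return GenotypeSession(og, x, count_requests=count_requests)


# ---------------------------------------------------------------------------
# engine


def _initial_genotype(config: SimulationConfig, rng: np.random.Generator):
    if config.genotype == SEQUENCE:
        idx = rng.integers(0, 4, size=config.L)
        return SequenceGenotype("".join(ALPHABET[i] for i in idx))
    density = config.initial_pathway_density
    if density is None:
        # stationary density of the gain/loss chain, so burn-in starts near
        # equilibrium instead of an empty network
        total = config.u_g + config.u_l
        density = config.u_g / total if total > 0 else 0.0
    sites = set()
    for r in range(1, config.genes + 1):
        for t in range(1, config.genes + 1):
            if rng.random() < density:
                sites.add((r, t))
    return PathwayGenotype(config.genes, frozenset(sites))


def _derive_offspring(og: OperationGraph, base: int, events: list,
                      count_requests: bool) -> int:
    """Append this offspring's event chain below node ``base`` and return the
    final node id.  Point-mutation bases are resolved by reading through the
    partially built chain; events with two or more reads share one session
    (batch decompression)."""
    n_reads = sum(isinstance(ev, PlannedMutation) for ev in events)
    session = GenotypeSession(og, base, count_requests=count_requests)
    cur = base
    buffer: bytearray | None = None
    if n_reads >= 2:
        buffer = bytearray(session.full().bases, "ascii")
    for ev in events:
        if isinstance(ev, PlannedMutation):
            if buffer is not None:
                old = chr(buffer[ev.position - 1])
                op = ev.resolve(old)
                buffer[ev.position - 1] = ord(op.params[1])
            else:
                op = ev.resolve(og.partial_decompress(cur, ev.position))
        else:
            op = ev
            if buffer is not None:
                # keep the local copy in sync through indels
                g = gm.apply(op, SequenceGenotype(buffer.decode("ascii")))
                buffer = bytearray(g.bases, "ascii")
        cur = og.add_mutation(cur, op)
    return cur


def run(config: SimulationConfig,
        per_generation: Callable[[int, OperationGraph, np.ndarray], None] | None = None,
        ) -> SimulationResult:
    """Run the configured simulation and return metrics plus the final
    population.

    ``per_generation(gen, og, population)`` — if given — is called after the
    policy application of every generation (burn-in included); it must not
    consume randomness or alter the graph, so instrumented and plain runs
    stay identical.
    """
    rng = np.random.default_rng(config.seed)
    policy = replace(config.policy, generation_counter=0)
    og = OperationGraph()
    root = og.add_root(_initial_genotype(config, rng), weight=config.N)
    population = np.full(config.N, root, dtype=np.int64)

    total = config.resolved_burn_in + config.generations
    metrics: list[GenerationMetrics] = []
    active: set[int] = {root}
    for gen in range(total):
        t0 = time.perf_counter()
        if config.model == WRIGHT_FISHER:
            population = _wf_generation(og, population, config, rng)
        else:
            population = _moran_generation(og, population, config, rng)
        active = _update_weights_and_prune(og, population, active)
        if config.fitness_requests:
            ids, counts = np.unique(population, return_counts=True)
            for i, c in zip(ids, counts):
                _record_requests(og, int(i), int(c))
        cp.apply_policy(og, policy)
        elapsed = time.perf_counter() - t0
        if gen >= config.resolved_burn_in:
            metrics.append(_measure(og, config, gen, elapsed))
        if per_generation is not None:
            per_generation(gen, og, population)
    return SimulationResult(config, metrics, population, og, policy)


def _record_requests(og: OperationGraph, x: int, count: int) -> None:
    n = og.node(x)
    if n.is_explicit:
        n.request_count += count
        return
    for v in og.need(x):
        nv = og.nodes[v]
        if not nv.is_explicit:
            nv.request_count += count


def _wf_generation(og: OperationGraph, population: np.ndarray,
                   config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    N = config.N
    parents = population[rng.integers(0, N, size=N)]
    rates = config.rates
    count_req = True

    if config.genotype == SEQUENCE:
        lens = np.array([og.nodes[int(p)].seq_length for p in parents], dtype=np.int64)
        if config.c_rate > 0:
            rec_u = rng.random(N)
            second = population[rng.integers(0, N, size=N)]
            bp_u = rng.random(N)
            p_rec = -np.expm1(-config.c_rate * lens)
            recombine = rec_u < p_rec
        else:
            recombine = np.zeros(N, dtype=bool)
        # recombination replaces the base genotype before indels/mutations;
        # its output length is the second parent's length by convention
        base_lens = lens.copy()
        if config.c_rate > 0:
            for i in np.flatnonzero(recombine):
                other = og.nodes[int(second[i])].seq_length
                if min(lens[i], other) < 2:
                    recombine[i] = False
                else:
                    base_lens[i] = other
        n_ins = rng.poisson(config.u_i * base_lens) if config.u_i > 0 else np.zeros(N, dtype=np.int64)
        n_del = rng.poisson(config.u_d * base_lens) if config.u_d > 0 else np.zeros(N, dtype=np.int64)
        n_mut = rng.poisson(config.u * base_lens) if config.u > 0 else np.zeros(N, dtype=np.int64)

        offspring = np.empty(N, dtype=np.int64)
        for i in range(N):
            base = int(parents[i])
            if recombine[i]:
                other = int(second[i])
                minlen = min(og.nodes[base].seq_length, og.nodes[other].seq_length)
                bp = 1 + int(bp_u[i] * (minlen - 1))
                cp.record_request(og, base)
                if other != base:
                    cp.record_request(og, other)
                base = og.add_recombination(base, other, gm.crossover(bp))
            total_events = int(n_ins[i] + n_del[i] + n_mut[i])
            if total_events == 0:
                offspring[i] = base
                continue
            events = gm.plan_from_counts(
                og.nodes[base].seq_length, int(n_ins[i]), int(n_del[i]),
                int(n_mut[i]), rates, rng)
            offspring[i] = _derive_offspring(og, base, events, count_req)
        return offspring

    # pathway genotypes
    n2 = config.genes ** 2
    n_loss = rng.poisson(config.u_l * n2, size=N) if config.u_l > 0 else np.zeros(N, dtype=np.int64)
    n_gain = rng.poisson(config.u_g * n2, size=N) if config.u_g > 0 else np.zeros(N, dtype=np.int64)
    offspring = np.empty(N, dtype=np.int64)
    for i in range(N):
        base = int(parents[i])
        events: list = []
        for kind, count in ((gm.BS_LOSS, int(n_loss[i])), (gm.BS_GAIN, int(n_gain[i]))):
            for _ in range(count):
                r = int(rng.integers(1, config.genes + 1))
                t = int(rng.integers(1, config.genes + 1))
                events.append(gm.bs_loss(r, t) if kind == gm.BS_LOSS else gm.bs_gain(r, t))
        if not events:
            offspring[i] = base
            continue
        offspring[i] = _derive_offspring(og, base, events, count_req)
    return offspring


def _moran_generation(og: OperationGraph, population: np.ndarray,
                      config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """N single birth-death replacements; weights are kept consistent at the
    generation boundary by the shared bookkeeping in :func:`run`."""
    population = population.copy()
    N = config.N
    rates = config.rates
    count_req = True
    for _ in range(N):
        die = int(rng.integers(0, N))
        base = int(population[int(rng.integers(0, N))])
        if config.genotype == SEQUENCE:
            length = og.nodes[base].seq_length
            if config.c_rate > 0 and rng.random() < -math.expm1(-config.c_rate * length):
                other = int(population[int(rng.integers(0, N))])
                minlen = min(length, og.nodes[other].seq_length)
                if minlen >= 2:
                    bp = 1 + int(rng.random() * (minlen - 1))
                    cp.record_request(og, base)
                    if other != base:
                        cp.record_request(og, other)
                    base = og.add_recombination(base, other, gm.crossover(bp))
            events = gm.plan_sequence_events(og.nodes[base].seq_length, rates, rng)
        else:
            events = gm.plan_pathway_events(config.genes, rates, rng)
        if events:
            base = _derive_offspring(og, base, events, count_req)
        population[die] = base
    return population


def _update_weights_and_prune(og: OperationGraph, population: np.ndarray,
                              prev_active: set[int]) -> set[int]:
    """Refresh node weights from the new population and prune lost leaf
    lineages.  Touches only nodes whose weight changes — per-generation cost
    must not scale with the total ancestry the graph has accumulated."""
    ids, counts = np.unique(population, return_counts=True)
    new_weights = {int(i): int(c) for i, c in zip(ids, counts)}
    lost = [i for i in prev_active if i not in new_weights]
    for i in lost:
        node = og.nodes.get(i)
        if node is not None:
            node.weight = 0
    for i, c in new_weights.items():
        og.nodes[i].weight = c
    for i in lost:
        node = og.nodes.get(i)
        if node is not None and node.is_leaf:
            og.prune_lost(i)
    return set(new_weights)


def _measure(og: OperationGraph, config: SimulationConfig, gen: int,
             elapsed: float) -> GenerationMetrics:
    from . import metrics_io

    account = metrics_io.heap_account(og)
    ratio, savings = metrics_io.compression_metrics(len(og.cached_set), config.N)
    return GenerationMetrics(
        generation=gen,
        seconds_per_generation=elapsed,
        heap_bytes=account.total,
        explicit_genotype_bytes=account.explicit_genotype_bytes,
        operation_bytes=account.operation_bytes,
        cached_count=len(og.cached_set),
        node_count=len(og),
        edge_count=og.edge_count,
        compression_ratio=ratio,
        space_savings=savings,
    )


# ---------------------------------------------------------------------------
# sequence-sample verification statistics


def verify_stats(sequences: Sequence[SequenceGenotype], N: int, L: int,
                 lambda_scale: float = 1.0) -> dict[str, float]:
    """Population-genetic summary statistics of an aligned sample, used to
    check that the engine reproduces neutral coalescent expectations.

    Returns Watterson's theta (``S / a_n`` with ``S`` segregating sites and
    ``a_n = sum_{i<n} 1/i``), its per-site value, the mean pairwise
    difference ``pi``, and the mutation rate implied by the sample under the
    haploid coalescent, ``estimated_u = theta_per_site / (2 N)`` — for a
    haploid Wright-Fisher population of N sequences the expected per-site
    theta is 2·N·u.  ``estimated_c`` is reported as NaN: no recombination
    rate estimator is implemented (theta is insensitive to recombination).
    Requires at least two sequences of equal length; run verification
    configurations with indels disabled."""
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    lengths = {s.length for s in sequences}
    if len(lengths) != 1:
        raise ValueError(
            "sequences have unequal lengths; rerun verification with "
            "insertion and deletion rates set to zero")
    arr = np.array([np.frombuffer(s.bases.encode("ascii"), dtype=np.uint8)
                    for s in sequences])
    n, sites = arr.shape
    segregating = int(np.count_nonzero((arr != arr[0]).any(axis=0)))
    a_n = sum(1.0 / i for i in range(1, n))
    theta_w = segregating / a_n
    diffs = 0
    for i in range(n):
        diffs += int((arr[i + 1:] != arr[i]).sum())
    pi = diffs / (n * (n - 1) / 2)
    effective_N = N * lambda_scale
    theta_site = theta_w / sites
    return {
        "segregating_sites": float(segregating),
        "watterson_theta": theta_w,
        "watterson_theta_per_site": theta_site,
        "pi": pi,
        "pi_per_site": pi / sites,
        "estimated_u": theta_site / (2.0 * effective_N),
        "estimated_c": float("nan"),
    }
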