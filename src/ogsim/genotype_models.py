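"""Concrete genotype representations and the evolutionary operations on them.

Two genotype models are provided:

* :class:`SequenceGenotype` — a DNA string over ``{A, C, G, T}`` evolving by
  point mutation, insertion, deletion and single-breakpoint crossover.
* :class:`PathwayGenotype` — a regulatory pathway of ``n`` genes whose state
  is the set of (regulator, target) binding sites, evolving by binding-site
  gain and loss.

All coordinates are **1-based**: "position 3" is the third base.  Operations
are immutable value objects (:class:`Operation`); applying one never mutates
its input genotype.  Besides whole-genotype application (:func:`apply`),
sequence operations support per-position application (:func:`apply_at`) so a
single base can be recovered by walking an operation chain without
reconstructing the full sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_NON_ACGT = re.compile(r"[^ACGT]")

# operation kinds
ROOT = "root"
POINT_MUTATION = "point_mutation"
INSERTION = "insertion"
DELETION = "deletion"
CROSSOVER = "crossover"
BS_GAIN = "bs_gain"
BS_LOSS = "bs_loss"

SEQUENCE_KINDS = frozenset({POINT_MUTATION, INSERTION, DELETION, CROSSOVER})
PATHWAY_KINDS = frozenset({BS_GAIN, BS_LOSS})

#: default computational cost c(v) per operation kind; insertion cost is the
#: number of inserted bases and is filled in by the constructor helpers.
DEFAULT_COSTS = {
    ROOT: 0.0,
    POINT_MUTATION: 1.0,
    DELETION: 1.0,
    CROSSOVER: 2.0,
    BS_GAIN: 1.0,
    BS_LOSS: 1.0,
}

#: bytes charged for one stored operation record under the deterministic
#: byte model: the payload of a point mutation is the single new base; an
#: insertion is charged one byte per inserted base; deletions and crossovers
#: carry a fixed two-byte payload (position + length / breakpoint), binding
#: site events one byte.
RECORD_PAYLOAD_BYTES = {
    ROOT: 0,
    POINT_MUTATION: 1,
    DELETION: 2,
    CROSSOVER: 2,
    BS_GAIN: 1,
    BS_LOSS: 1,
}


@dataclass(frozen=True, slots=True)
class SequenceGenotype:
    """A DNA sequence; ``bases`` is an upper-case string over ACGT."""

    bases: str

    def __post_init__(self) -> None:
        if _NON_ACGT.search(self.bases):
            bad = sorted(set(self.bases) - set(ALPHABET))
            raise ValueError(f"illegal symbols in sequence: {bad}")

    @property
    def length(self) -> int:
        return len(self.bases)

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True, slots=True)
class PathwayGenotype:
    """A regulatory pathway: ``gene_count`` genes plus directed binding sites.

    Each binding site is an ordered pair ``(regulator, target)`` of 1-based
    gene indices; self-regulation is allowed.
    """

    gene_count: int
    binding_sites: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.gene_count < 1:
            raise ValueError("gene_count must be positive")
        object.__setattr__(self, "binding_sites", frozenset(self.binding_sites))
        for r, t in self.binding_sites:
            if not (1 <= r <= self.gene_count and 1 <= t <= self.gene_count):
                raise ValueError(f"binding site {(r, t)} outside 1..{self.gene_count}")


Genotype = SequenceGenotype | PathwayGenotype


@dataclass(frozen=True, slots=True)
class Operation:
    """One evolutionary event: a kind, kind-specific parameters, and a cost.

    Parameter layout by kind (all positions 1-based):

    * ``root`` — ``()``; identity on the stored initial genotype.
    * ``point_mutation`` — ``(position, new_base)``
    * ``insertion`` — ``(position, inserted)``: ``inserted`` goes in front of
      the base currently at ``position`` (``position == L+1`` appends).
    * ``deletion`` — ``(position, length)``: removes ``length`` bases starting
      at ``position``; the stored length is the realized (clipped) length.
    * ``crossover`` — ``(breakpoint,)``: output is the first parent's prefix
      ``[1..breakpoint]`` followed by the second parent's suffix
      ``[breakpoint+1..]``.  Requires two input genotypes.
    * ``bs_gain`` / ``bs_loss`` — ``((regulator, target),)``; gaining an
      existing site or losing an absent one is a no-op.
    """

    kind: str
    params: tuple = ()
    cost: float = 0.0

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ValueError("operation cost must be non-negative")

    @property
    def arity(self) -> int:
        """Number of input genotypes (0 for root, 2 for crossover, else 1)."""
        if self.kind == ROOT:
            return 0
        return 2 if self.kind == CROSSOVER else 1

    @property
    def record_bytes(self) -> int:
        """Payload bytes charged for this record under the byte model."""
        if self.kind == INSERTION:
            return len(self.params[1])
        return RECORD_PAYLOAD_BYTES[self.kind]


# ---------------------------------------------------------------------------
# constructor helpers


def root_op() -> Operation:
    return Operation(ROOT, (), DEFAULT_COSTS[ROOT])


def point_mutation(position: int, new_base: str, cost: float | None = None) -> Operation:
    if new_base not in _BASE_INDEX:
        raise ValueError(f"not a DNA base: {new_base!r}")
    return Operation(POINT_MUTATION, (position, new_base),
                     DEFAULT_COSTS[POINT_MUTATION] if cost is None else cost)


def insertion(position: int, inserted: str, cost: float | None = None) -> Operation:
    if not inserted or set(inserted) - set(ALPHABET):
        raise ValueError("insertion payload must be a non-empty ACGT string")
    return Operation(INSERTION, (position, inserted),
                     float(len(inserted)) if cost is None else cost)


def deletion(position: int, length: int, cost: float | None = None) -> Operation:
    if length < 1:
        raise ValueError("deletion length must be >= 1")
    return Operation(DELETION, (position, length),
                     DEFAULT_COSTS[DELETION] if cost is None else cost)


def crossover(breakpoint: int, cost: float | None = None) -> Operation:
    if breakpoint < 1:
        raise ValueError("breakpoint must be >= 1")
    return Operation(CROSSOVER, (breakpoint,),
                     DEFAULT_COSTS[CROSSOVER] if cost is None else cost)


def bs_gain(regulator: int, target: int, cost: float | None = None) -> Operation:
    return Operation(BS_GAIN, ((regulator, target),),
                     DEFAULT_COSTS[BS_GAIN] if cost is None else cost)


def bs_loss(regulator: int, target: int, cost: float | None = None) -> Operation:
    return Operation(BS_LOSS, ((regulator, target),),
                     DEFAULT_COSTS[BS_LOSS] if cost is None else cost)


# ---------------------------------------------------------------------------
# application


def apply(op: Operation, a: Genotype, b: Genotype | None = None) -> Genotype:
    """Apply ``op`` to genotype ``a`` (and ``b`` for crossover).

    Pure: inputs are never modified.  Raises ``IndexError`` for out-of-range
    positions and ``TypeError`` when the arity of ``op`` does not match the
    supplied inputs.
    """
    if op.kind == CROSSOVER:
        if b is None:
            raise TypeError("crossover requires two input genotypes")
    elif b is not None:
        raise TypeError(f"{op.kind} takes exactly one input genotype")

    if op.kind == ROOT:
        return a

    if op.kind in SEQUENCE_KINDS:
        if not isinstance(a, SequenceGenotype):
            raise TypeError(f"{op.kind} applies to SequenceGenotype")
        s = a.bases
        if op.kind == POINT_MUTATION:
            pos, base = op.params
            if not 1 <= pos <= len(s):
                raise IndexError(f"position {pos} outside sequence of length {len(s)}")
            return SequenceGenotype(s[: pos - 1] + base + s[pos:])
        if op.kind == INSERTION:
            pos, ins = op.params
            if not 1 <= pos <= len(s) + 1:
                raise IndexError(f"insertion position {pos} outside 1..{len(s) + 1}")
            return SequenceGenotype(s[: pos - 1] + ins + s[pos - 1:])
        if op.kind == DELETION:
            pos, length = op.params
            if not 1 <= pos <= len(s) or pos + length - 1 > len(s):
                raise IndexError(f"deletion {op.params} outside sequence of length {len(s)}")
            if length >= len(s) and pos == 1:
                raise ValueError("deletion may not empty the sequence")
            return SequenceGenotype(s[: pos - 1] + s[pos - 1 + length:])
        # crossover
        assert isinstance(b, SequenceGenotype)
        (bp,) = op.params
        if bp >= len(s) or bp >= len(b.bases):
            raise IndexError(f"breakpoint {bp} must be < both parent lengths")
        return SequenceGenotype(s[:bp] + b.bases[bp:])

    if op.kind in PATHWAY_KINDS:
        if not isinstance(a, PathwayGenotype):
            raise TypeError(f"{op.kind} applies to PathwayGenotype")
        (pair,) = op.params
        r, t = pair
        if not (1 <= r <= a.gene_count and 1 <= t <= a.gene_count):
            raise IndexError(f"gene pair {pair} outside 1..{a.gene_count}")
        if op.kind == BS_GAIN:
            return PathwayGenotype(a.gene_count, a.binding_sites | {pair})
        return PathwayGenotype(a.gene_count, a.binding_sites - {pair})

    raise ValueError(f"unknown operation kind {op.kind!r}")


@dataclass(frozen=True, slots=True)
class Passthrough:
    """Coordinate mapping returned by :func:`apply_at` when the queried output
    position is copied unchanged from an input genotype."""

    parent_index: int  # 0 = first input, 1 = second (crossover only)
    position: int      # 1-based position in that input


def apply_at(op: Operation, position: int) -> str | Passthrough:
    """Resolve one output position of a sequence operation.

    Returns either the base itself (when the operation determines it, e.g. a
    point mutation queried at its own position) or a :class:`Passthrough`
    naming which input genotype and input position holds the base, so a
    caller can recurse up an operation chain.  Consistent with :func:`apply`:
    for every valid output position ``p``, following the passthrough chain
    yields ``apply(op, a, b).bases[p-1]``.
    """
    if position < 1:
        raise IndexError(f"position must be >= 1, got {position}")
    if op.kind == ROOT:
        return Passthrough(0, position)
    if op.kind == POINT_MUTATION:
        pos, base = op.params
        return base if position == pos else Passthrough(0, position)
    if op.kind == INSERTION:
        pos, ins = op.params
        if position < pos:
            return Passthrough(0, position)
        if position < pos + len(ins):
            return ins[position - pos]
        return Passthrough(0, position - len(ins))
    if op.kind == DELETION:
        pos, length = op.params
        if position < pos:
            return Passthrough(0, position)
        return Passthrough(0, position + length)
    if op.kind == CROSSOVER:
        (bp,) = op.params
        return Passthrough(0 if position <= bp else 1, position)
    raise TypeError(f"apply_at is defined for sequence operations, not {op.kind!r}")


def output_length(op: Operation, input_lengths: Sequence[int]) -> int:
    """Length of the output sequence given the input length(s)."""
    if op.kind in (ROOT, POINT_MUTATION):
        return input_lengths[0]
    if op.kind == INSERTION:
        return input_lengths[0] + len(op.params[1])
    if op.kind == DELETION:
        return input_lengths[0] - op.params[1]
    if op.kind == CROSSOVER:
        (bp,) = op.params
        return bp + input_lengths[1] - bp  # == second parent's length
    raise TypeError(f"no sequence length for {op.kind!r}")


def footprint(g: Genotype) -> int:
    """Memory footprint of an explicit genotype in bytes: L for a sequence of
    length L, n**2 for a pathway of n genes."""
    if isinstance(g, SequenceGenotype):
        return g.length
    if isinstance(g, PathwayGenotype):
        return g.gene_count ** 2
    raise TypeError(f"not a genotype: {type(g).__name__}")


# ---------------------------------------------------------------------------
# stochastic event sampling


@dataclass(frozen=True, slots=True)
class EventRates:
    """Per-generation event rates.

    ``u``, ``u_i``, ``u_d`` are per-base rates (expected counts are rate
    times sequence length); ``u_l`` and ``u_g`` are per-potential-site rates
    for pathways (expected counts are rate times gene_count**2).
    ``indel_mean_length`` is the mean of the geometric length distribution
    used for insertions and deletions.
    """

    u: float = 0.0
    u_i: float = 0.0
    u_d: float = 0.0
    u_l: float = 0.0
    u_g: float = 0.0
    indel_mean_length: float = 3.0

    def __post_init__(self) -> None:
        for name in ("u", "u_i", "u_d", "u_l", "u_g"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be non-negative")
        if self.indel_mean_length < 1:
            raise ValueError("indel_mean_length must be >= 1")


@dataclass(frozen=True, slots=True)
class PlannedMutation:
    """A point mutation whose new base is still unresolved: the base is
    stored as an offset in {1,2,3} from the current base, so resolving it
    needs exactly one read of the pre-mutation sequence."""

    position: int
    offset: int

    def resolve(self, current_base: str) -> Operation:
        new = ALPHABET[(_BASE_INDEX[current_base] + self.offset) % 4]
        return point_mutation(self.position, new)


def plan_sequence_events(
    length: int, rates: EventRates, rng: np.random.Generator
) -> list[Operation | PlannedMutation]:
    """Sample this generation's events for one sequence lineage of ``length``
    bases.

    Event counts are Poisson with means ``rate * length``; positions are
    uniform; indel lengths are geometric with mean ``indel_mean_length``.
    Events are returned in application order — insertions and deletions
    first, then point mutations — with positions valid against the
    intermediate sequence at each step (indels shift coordinates).  Point
    mutations are returned as :class:`PlannedMutation` because the substitute
    base depends on the base currently at the site; all randomness is drawn
    here so resolution is deterministic.

    A deletion that would empty the sequence is resampled; deletions are
    skipped entirely once the intermediate sequence has a single base.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    n_ins = int(rng.poisson(rates.u_i * length)) if rates.u_i > 0 else 0
    n_del = int(rng.poisson(rates.u_d * length)) if rates.u_d > 0 else 0
    n_mut = int(rng.poisson(rates.u * length)) if rates.u > 0 else 0
    return plan_from_counts(length, n_ins, n_del, n_mut, rates, rng)


def plan_from_counts(
    length: int,
    n_ins: int,
    n_del: int,
    n_mut: int,
    rates: EventRates,
    rng: np.random.Generator,
) -> list[Operation | PlannedMutation]:
    """Sample event parameters for pre-drawn event counts; the engine draws
    counts for a whole generation in one vectorized call and delegates here
    per offspring.  Same semantics as :func:`plan_sequence_events`."""
    events: list[Operation | PlannedMutation] = []
    cur = length
    p_geom = 1.0 / rates.indel_mean_length
    for _ in range(n_ins):
        pos = int(rng.integers(1, cur + 2))
        n = int(rng.geometric(p_geom))
        ins = "".join(ALPHABET[i] for i in rng.integers(0, 4, size=n))
        events.append(insertion(pos, ins))
        cur += n
    for _ in range(n_del):
        if cur <= 1:
            continue
        while True:
            pos = int(rng.integers(1, cur + 1))
            n = min(int(rng.geometric(p_geom)), cur - pos + 1)
            if n < cur:
                break
        events.append(deletion(pos, n))
        cur -= n
    for _ in range(n_mut):
        pos = int(rng.integers(1, cur + 1))
        events.append(PlannedMutation(pos, int(rng.integers(1, 4))))
    return events


def plan_pathway_events(
    gene_count: int, rates: EventRates, rng: np.random.Generator
) -> list[Operation]:
    """Sample binding-site gain/loss events for one pathway lineage.

    Counts are Poisson with mean ``rate * gene_count**2``; gene pairs are
    uniform over all ordered pairs.  Gains of present sites and losses of
    absent sites apply as no-ops."""
    n2 = gene_count ** 2
    n_loss = int(rng.poisson(rates.u_l * n2)) if rates.u_l > 0 else 0
    n_gain = int(rng.poisson(rates.u_g * n2)) if rates.u_g > 0 else 0
    events: list[Operation] = []
    for kind, n in ((BS_LOSS, n_loss), (BS_GAIN, n_gain)):
        for _ in range(n):
            r = int(rng.integers(1, gene_count + 1))
            t = int(rng.integers(1, gene_count + 1))
            events.append(bs_loss(r, t) if kind == BS_LOSS else bs_gain(r, t))
    return events


def sample_events(
    g: Genotype, rates: EventRates, rng: np.random.Generator
) -> list[Operation]:
    """Sample one generation of events for genotype ``g`` and resolve them to
    concrete :class:`Operation` records (see :func:`plan_sequence_events` for
    the distributions).  Deterministic for a fixed rng state."""
    if isinstance(g, PathwayGenotype):
        return plan_pathway_events(g.gene_count, rates, rng)
    ops: list[Operation] = []
    current = g
    for ev in plan_sequence_events(g.length, rates, rng):
        if isinstance(ev, PlannedMutation):
            ev = ev.resolve(current.bases[ev.position - 1])
        ops.append(ev)
        current = apply(ev, current)
    return ops


# ---------------------------------------------------------------------------
# export


def write_fasta(path, genotypes: Iterable[SequenceGenotype], ids: Iterable[str]) -> int:
    """Write sequence genotypes as standard 70-column FASTA; returns the
    number of records written."""
    from Bio.Seq import Seq
    from Bio.SeqIO.FastaIO import FastaWriter
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(g.bases), id=str(i), description="")
        for g, i in zip(genotypes, ids)
    ]
    with open(path, "w") as fh:
        count = FastaWriter(fh, wrap=70).write_file(records)
    return count


def write_edge_list(path, pathway: PathwayGenotype) -> int:
    """Write a pathway's binding sites as a tab-separated regulator/target
    edge list; returns the number of edges written."""
    edges = sorted(pathway.binding_sites)
    with open(path, "w") as fh:
        for r, t in edges:
            fh.write(f"{r}\t{t}\n")
    return len(edges)
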