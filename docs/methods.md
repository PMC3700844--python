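# Methods

## The problem

A forward-time population simulator keeps N genotypes alive at once and, if
it tracks ancestry, every genotype that ever arose. For genome-scale
genotypes (megabase sequences, whole regulatory networks) the genotype heap
quickly exceeds a compute node's memory. `ogsim` stores genotypes
*implicitly*: each one is the sequence of evolutionary events that produced
it, and only a small, strategically chosen set is kept explicit.

## The operation graph

Every evolutionary event is a node in a rooted, weighted DAG, the operation
graph OG = (V, E, ℓ, f, w, c):

- `f(v)` — the operation (point mutation, insertion, deletion, crossover,
  binding-site gain/loss); mutation-class nodes have one parent,
  recombination nodes two, so mutation-only histories are trees;
- `ℓ(v)` — the genotype, stored only for *explicit* nodes; the explicit set
  is the cache C(V), and at least one node is always explicit;
- `w(v)` — the number of individuals currently carrying the genotype
  (*active* nodes have w > 0);
- `c(v)` — the non-negative cost of applying the operation.

Any node is decompressed losslessly by walking up to its lowest explicit
ancestors Anc(x) and re-applying operations downward; recombination nodes
decompress both parents, with memoization so shared ancestry is applied
once per call. *Partial* decompression recovers a single base by mapping
the queried coordinate through each operation up to the first explicit
ancestor (a crossover forwards the query only to the parent owning the
coordinate); *batch* decompression (`GenotypeSession`) materializes a
sequence once per event, however many bases the event touches.

Measures: `cost(x)` is the summed cost of the compressed nodes applied when
decompressing x (zero for explicit nodes). `cost_between(x, y)` restricts
the sum to the segment through y, excluding y and including x; it is zero
when y is on no decompression path of x, and `cost(x, x) = c(x)` for a
compressed x. `load(x) = Σ_y w(y)·cost(y, x)` over nodes needing x is the
decompression demand on x. Exact load enumerates paths and can be
exponential on recombination-rich graphs; it is used for tests and small
graphs. Production runs use per-node *data-request counters* as a proxy: a
request on a compressed node increments it and every compressed node on
its decompression paths (explicit ancestors excluded — they retain counts
accumulated while they were compressed). Measured on scripted request
patterns over random graphs, the proxy's top-choice agrees with exact load
88% of the time; zero-vs-nonzero decisions never use the proxy but a
boolean *required* flag (node lies on some active genotype's decompression
path), recomputed in time linear in the number of flagged nodes.

### Graph maintenance

When a genotype is lost from the population its node's weight drops to
zero; if it is a leaf, the chain of childless, inactive, non-root ancestors
above it is deleted. Non-leaf dead nodes persist (active genotypes may sit
below them). Inactive nodes can never become active again — parents are
drawn from the living population — which is what makes cache decisions
safe. All per-generation bookkeeping (weights, edge and byte totals,
required flags) is incremental: per-generation cost must not scale with the
total ancestry accumulated, or per-generation time would grow with
simulation length.

## Cache policies

- **Store-Active** (the conventional simulator): C(V) = active set. No
  compression; memory grows with the number of distinct living genotypes.
- **Store-Root**: C(V) = roots. Maximal compression; decompression chains
  lengthen with simulation time, so per-generation time grows.
- **Greedy-Load(k, t)**, applied every t generations (t = 0: every one),
  starting from C(V) = {root}:
  1. every cached node that no active genotype requires is compressed (its
     counter reset; the last explicit node is never dropped); every other
     cached node is *advanced*: the cache slot slides down through unique
     required compressed children to the highest node that is a leaf, is
     active, or has two or more required compressed children — net cache
     size unchanged;
  2. while |C(V)| < k and some cached node has a required compressed child:
     decompress the max-load child y of the max-load cached node x
     (subtracting y's request count from its former explicit ancestors'),
     then advance y and x. Ties break to the smaller node id.

  After every application |C(V)| ≤ k, and every active genotype remains
  decompressible (descent never passes a branch with two required
  compressed children, so no dependent subtree is orphaned). An optional
  low-water trigger re-runs the policy when |C(V)| < k/2 instead of on the
  fixed cadence.

The twelve-node worked example (`ogsim.fixtures`, `ogsim example-og`)
walks the cache through {a,c} → {d,c} → {d,i,e} → {e,g,h,i} at k = 4 under
exact load; the fixture's unit weights and costs realize the inequalities
the walkthrough assumes (load(c) > load(d), load(f) > load(e)), which the
test suite checks directly.

## Genotype models and conventions

All positions are 1-based. Sequences are ACGT strings of L bytes
(byte-model footprint L); pathways are n genes with a set of directed
binding sites, footprint n². Choices the underlying literature leaves open,
fixed here and isolated behind one function each:

- **Crossover** is single-breakpoint: first parent's prefix [1..b] plus
  second parent's suffix; the output length is the second parent's length.
  With unequal lengths (possible after indels) b is uniform on
  [1, min(lengths) − 1]; pairs too short to cross over fall back to clonal
  inheritance of the first parent.
- **Indel lengths** are geometric with mean 3 (configurable); insertion
  positions uniform on [1, L+1], deletion lengths clipped at the sequence
  end, and a deletion that would empty the sequence is resampled (length-1
  sequences skip deletion): empty genotypes are undefined.
- **Event order** within an offspring: crossover, insertions, deletions,
  then point mutations, each against the intermediate coordinates.
- **Substitute bases** are drawn uniformly from the three alternatives to
  the current base (reading the current base is what generates honest
  decompression traffic during simulation).
- **Pathway events**: gain/loss counts are Poisson with mean rate·n²; a
  gain of a present site or loss of an absent one applies as a no-op,
  keeping operation application total. Initial networks start at the
  stationary density u_g/(u_g + u_l).
- **Operation costs** default to 1 (point mutation, deletion, binding-site
  events), |inserted| for insertions, 2 for crossover; all configurable
  per operation.
- **Record bytes** (memory model): 1 for a point mutation or binding-site
  event, |inserted| for insertions, 2 for deletions and crossovers — so
  10⁶ point-mutation records weigh exactly one megabase sequence.

## The simulation engine

Haploid Wright–Fisher: each of N offspring draws its parent uniformly from
the previous generation; an offspring recombines with probability
1 − exp(−c·L) with a uniformly drawn second parent; event counts are
Poisson(rate·L). A Moran variant performs N single birth–death
replacements per reported generation. Evolution is neutral; per-individual
fitness evaluation is stubbed as a genotype data request so cache-demand
dynamics match a real simulator without imposing selection. Burn-in
defaults to the conventional 10·N generations when not set explicitly.

One seeded generator drives everything in a fixed draw order (parent
indices; recombination uniforms; vectorized event counts; per-offspring
event parameters in offspring order). Cache policies consume no
randomness, so runs under different policies see the identical event
stream — the cross-policy losslessness checks compare per-generation
SHA-256 hashes of the fully decompressed population and require equality,
not approximation.

Rescaling: a run at (N, u, c, G) with factor λ ≥ 1 stands for a population
λN evolved λG generations at rates u/λ and c/λ; N·u and N·c are invariant.

### Verification statistics

For an indel-free sample of n sequences, `verify_stats` reports
segregating sites S, Watterson's θ_W = S / a_n (a_n = Σ_{i<n} 1/i), mean
pairwise difference π, and the implied mutation rate. For this haploid
model the neutral expectation is θ = 2Nu per site, so
`estimated_u = θ_site / (2N)`; a diploid reading (2N gene copies) would use
4Nu. No recombination-rate estimator is implemented (`estimated_c` is NaN);
θ_W is insensitive to recombination, so verification runs simply disable
it. Across 50 replicates at N = 200, L = 5000, u = 5·10⁻⁵ after a 10N
burn-in, the mean per-site θ̂_W lands within three standard errors of 2Nu;
per-site θ of 0.02 keeps recurrent-mutation (finite-sites) bias well below
sampling noise.

## What the synthetic data does and does not show

The generator and engine emulate neutral, panmictic, constant-size
populations with uniform event rates — exactly the regime the compression
method is defined over, since Greedy-Load uses only inheritance topology
and frequencies. They do not emulate selection, demography, linkage maps,
or empirical base composition; passing tests therefore demonstrate
correctness and scaling of the *storage layer*, not realism of any
particular biological scenario. Because the cache policy never touches the
event stream, losslessness results transfer directly to any future
fitness-aware engine built on the same graph.

## Problem sizes and numerical choices

Test and acceptance workloads are desk-scale by design: losslessness runs
up to N = 200, L = 5000 over 200 generations across ten seeded
configurations; coalescent validation uses 50 replicates at N = 200,
L = 5000; the time-scaling comparison runs 500 recorded generations at
N = 100, L = 10⁵, u = 2·10⁻⁶ (≈20 events per generation). Time trends are
measured with the robust Theil–Sen slope, since the bounded cache's
periodic reorganizations produce bursty per-generation times that dominate
a least-squares fit; "flat" means total drift within a quarter of the
median over the window, while the maximally compressing baseline at least
doubles. Wall-clock seconds per generation are reported for shape, never
as absolute targets. Memory is reported under the deterministic byte model
(hardware-independent); the operation-record share of the heap is reported,
not asserted, as it depends on run length.

## Known limitations

- Exact load is exponential on recombination-rich graphs; it is gated to
  tests and small fixtures. The request proxy is approximate by design.
- A root compressed by Greedy-Load is unrecoverable (operations are not
  invertible); switching to Store-Root afterwards raises an integrity
  error rather than guessing.
- Pathway genotypes have no partial decompression (sites are cheap to
  materialize relative to sequences).
- The graph is an in-memory structure; there is no cross-run serialization
  of full OG state.
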