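# Methods

## Problem

A pangenome is modelled as a directed acyclic graph whose vertices carry
non-empty sequence labels and whose haplotypes are walks from a first to a
last vertex; every vertex and edge must be supported by at least one
haplotype.  Sequencing reads from a new sample are sketched into a set of
query strings `S` (window minimizers).  The object being inferred is an
*inferred path*: a sequence of (vertex, haplotype) steps such that
consecutive steps follow graph edges, and two consecutive steps may keep the
same haplotype annotation only where that haplotype actually traverses the
edge.  A change of haplotype annotation between consecutive steps is a
*recombination*.  For a recombination penalty `c ≥ 0`, the cost of an
inferred path `P` is

```
cost(P) = c · γ(P) + |{ r ∈ S : r does not occur in the spelled sequence of P }|
```

where `γ(P)` is the number of recombinations and the spelled sequence is the
concatenation of vertex labels along `P`.  The inference problem is to find
a minimum-cost inferred path.  Each distinct string counts at most once,
regardless of read multiplicity; with canonical sketching a string counts as
occurring if it or its reverse complement occurs.

## Expanded flow graph

The solver works on an *expanded graph* built in three preprocessing steps:

1. **Label splitting** — labels longer than the shortest query string are
   split into chains of shorter vertices so that no query can hide strictly
   inside one label.
2. **Edge splitting** — every edge is subdivided by an ε-labelled vertex
   inheriting the supporting haplotypes of the edge.  This makes the two
   natural semantics of "switching haplotypes across an edge" coincide (see
   *Semantics of recombination* below).
3. **Expansion** — each haplotype becomes its own chain of vertex copies
   from a global source `s` to a sink `t` (weight-0 edges).  Recombination
   edges connect chains at *useful departures* only: haplotype `j` may leave
   its copy of vertex `u` along graph edge `(u, v)` only if `j` does not
   itself continue to `v` at that position.

Two recombination-edge constructions are provided:

- **naive**: one direct weight-`c` arc per (useful departure, landing copy)
  pair — `D·L` arcs for a site with `D` departures and `L` landing copies;
- **optimized**: one ε-labelled intermediate vertex per graph edge, with
  weight-`c/2` arcs from each departing copy and to each landing copy —
  `D + L` arcs per site.

Both admit exactly the same set of recombinations with the same total
weight (`c/2 + c/2` through the intermediate vertex), so optimal objectives
are identical.  The optimized form is smaller at any site with `D ≥ 2` and
`L ≥ 2`; at sparse sites (`min(D, L) = 1`) it is larger by one arc, so the
aggregate edge count is only conditionally smaller.  Halving `c` is exact in
double precision for any integer `c`.

A unit `s → t` flow in the expanded graph corresponds one-to-one (up to
traversal of intermediate vertices) to an inferred path, with flow weight
`c · γ`.

## Hits and the matching model

A *hit* of query string `r` is a minimal walk in the expanded graph whose
spelled labels contain `r` with proper anchoring: `r` must end with a
non-empty prefix of the last label and start with a non-empty suffix of the
first (label splitting guarantees `r` cannot sit inside one label).  Two hit
finders are provided:

- `find_restricted_hits` — occurrences of `r` (and, for canonical sketches,
  its reverse complement) within single haplotype sequences, mapped onto the
  chains.  Fast and the pipeline default, but blind to occurrences spanning
  a recombination breakpoint.
- `find_graph_hits` — a DFS over (vertex, offset) anchors enumerating every
  occurrence, including across recombination edges; complete but intended
  for small graphs and for tests.  Enumeration is capped with an explicit
  error, never silently truncated.

## Integer programs

Decision variables: `x_uv ∈ {0,1}` per expanded edge (flow), one `z_r ∈
{0,1}` per query string (matched), and one indicator per hit.  Constraints:
unit flow out of `s` and into `t`, flow conservation elsewhere, and
`z_r = 1` only if some hit of `r` has all of its edges selected.  Strings
with no hit are fixed unmatched.  The objective minimises
`Σ weight(u,v) · x_uv + Σ (1 − z_r)`.

Two equivalent formulations are built:

- **ILP** — one linear constraint per hit (hit indicator ≤ each edge
  variable, `z_r ≤ Σ` hit indicators);
- **IQP** — one product constraint per string (`z_r ≤ Σ_hits Π edges`),
  linearised exactly by McCormick envelopes, which is lossless because all
  variables involved are binary.

Optionally the edge variables are relaxed to `[0, 1]` (`z` stays binary).
The relaxation is not guaranteed integral in general, so a returned
fractional flow is *integralized*: the positive-flow support forms an
acyclic unit flow, and a deterministic shortest path by edge weight
(lowest-id tie-break) through that support is itself an optimal 0/1 flow
with the same objective and the same selected hits.  All models are solved
with HiGHS via `scipy.optimize.milp`, single-threaded and deterministic.
The inferred path is then extracted from the 0/1 flow and re-scored
independently; `cost(path) = objective` is asserted on every run.

## Semantics of recombination and the brute-force oracle

On a graph that has **not** been ε-edge-split, the step-annotation
definition of a recombination allows a switch onto a haplotype that
contains the landing vertex but not the traversed edge, at the price of a
single recombination; the expanded graph charges such a move two (land on a
supporting haplotype's ε vertex, switch again at the landing vertex).  On
an ε-split graph the two semantics provably coincide: every recombination
edge lands on an ε vertex of a haplotype supporting the traversed edge, and
any annotation can be rewritten, without increasing γ, into one whose
switches all land that way.  All solver comparisons are therefore made on
the preprocessed (split) graph.  Panel-style graphs (bubble chains, where
every allele vertex has a unique predecessor) never exercise the gap, so
oracle results on the unsplit graph agree there as well.

The test-suite oracle (`brute_force_optimum`) is an independent code path
that never builds the expanded graph: it enumerates vertex sequences by
DFS and, for each sequence, minimises the recombination count over all
valid haplotype annotations with an exact dynamic program (the unmatched
term depends only on the spelled text, so the split is lossless).
Enumerating annotated paths explicitly is exponential in the number of
shared vertices; the DP form is equivalent and is itself cross-checked
against explicit enumeration in the tests.

## Hardness gadget

`build_reduction` encodes a directed-graph Hamiltonian-path question as an
inference instance: `n` layers of vertex copies between terminals `s` and
`t`, unambiguous fixed-width binary blocks as labels, one haplotype per
gadget edge, and a query set that forces any low-cost solution to traverse
`s`, a full permutation layer sequence, and `t`.  Because each haplotype
covers exactly one edge, the starting haplotype covers the first edge of an
`s–t` traversal free and each subsequent edge costs exactly one
recombination, so the optimal cost equals `c·n` exactly when the digraph
has a Hamiltonian path and is strictly larger otherwise (a non-permutation
traversal leaves at least one block unmatched; avoiding a terminal forfeits
more than `c(n+1)` blocks).  Note the threshold is `c·n`, not `c·(n+1)`:
an annotation that switches on every edge costs `c·(n+1)`, but it is not
the optimum, and `c·(n+1)` as a decision threshold misclassifies some
non-Hamiltonian digraphs (e.g. two disjoint 2-cycles on three vertices
reach cost exactly `4 = c·(n+1)` at `c = 1`).  The tests assert the tight
`c·n` threshold.

## Minimizer sketching

`window_minimizers(seq, (w, k))` selects, in every window of `w`
consecutive k-mers, the k-mer with the smallest hash (ties by sequence);
`w = 1` therefore yields exactly the k-mer set.  Hashing is a fixed
splitmix64 finalizer over the 2-bit packing of the k-mer, so sketches are
deterministic across runs and platforms.  With `canonical=True` each k-mer
is replaced by the lexicographically smaller of itself and its reverse
complement before hashing, making the sketch strand-symmetric.  k-mers
containing non-ACGT characters are excluded.  `k` is capped at 31 so codes
fit in 64 bits.  The implementation is vectorised (NumPy sliding windows)
and is tested against a naive all-windows rescan.

## Synthetic data generator

Scope: the generator exists to exercise the inference stack, not to model
biology.  `random_pangenome` draws a panel of haplotypes as a shared random
backbone with independent substitution sites at a given density (one
bubble per site, distinct alleles per haplotype where drawn).
`simulate_mosaic_target` builds a target as a mosaic of panel haplotypes
with a chosen number of donor switches at variant-segment boundaries, so
the true recombination count is known by construction.
`simulate_reads` tiles the target (and its reverse complement, alternating)
with fixed-length reads at a given coverage, with optional uniform
substitution errors.  `random_small_instance` draws tiny graphs plus query
strings for oracle-vs-solver comparisons.  All generators are driven by a
single integer seed through `numpy.random.default_rng`; byte-identical
fixture directories are regenerated from equal configurations.

## Parameters

- `c` (recombination penalty, default 100): calibrated to whole-read-set
  sketches; for the ~2 kb test simulations the acceptance suite uses
  `c = 2`, below the matched-minimizer mass contributed by any real switch
  but high enough that a spurious switch has positive net cost.
- `w`, `k` (sketch, defaults 25/31): the recovery tests use `w = 5`,
  `k = 21` so that every variant site of the small simulated instances is
  covered by some selected minimizer.
- `--hits {restricted,graph}`: restricted is the scalable default; graph
  hits make breakpoint-spanning minimizers matchable and are used where
  exactness matters (tests, small instances).
- `--formulation {ilp,iqp}`, `--relax/--no-relax`, `--threads`,
  `--time-limit`: solver controls; defaults reproduce the relaxed IQP
  pipeline.  Exit codes: 0 optimal, 2 non-optimal solver status, 3 invalid
  input.

## Numerical choices

- All objective comparisons in tests use absolute tolerance `1e-6`; model
  coefficients are integers or exact halves, and HiGHS proves optimality on
  these instance sizes, so observed deviations are at machine precision.
- Flow conservation is checked at tolerance `1e-5` before integralization.
- Determinism: single-threaded HiGHS, seeded NumPy generators, fixed hash
  constants, sorted iteration orders everywhere a set is materialised.

## Limitations

- Exact IP solving does not scale to chromosome-scale graphs; instance
  sizes here are test-scale (the design goal is correctness and
  verifiability, with the optimized expansion as the main size lever).
- Restricted hits undercount matches spanning breakpoints, which can bias
  `γ` downward at small `c`; graph hits are exact but enumerative.
- The generator produces substitution bubbles only (no indels or nested
  variation), uniform base composition, and error-free or
  uniform-substitution reads.
- VCF input supports phased diploid genotypes with non-overlapping,
  non-symbolic records only.
- Query strings shorter than 2 characters are rejected; `k ≤ 31`.
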