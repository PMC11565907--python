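# haplopath

Pangenome-based haplotype inference by integer programming.

Given a pangenome graph (a DAG of labelled vertices with known haplotype
walks) and sequencing reads from a new sample, `haplopath` infers the
sample's sequence as a path through the graph that may *recombine* — switch
between haplotypes — where the read evidence demands it.  Reads are sketched
into window minimizers; the inferred path minimises

```
c · (number of recombinations) + (number of sketch strings absent from the path's sequence)
```

so the penalty `c` trades off recombination against unexplained read
evidence.  The optimum is found exactly: the problem is encoded as a
minimum-cost unit flow with string-matching side constraints on an
*expanded graph* (one chain of vertex copies per haplotype, plus weighted
recombination edges at exactly the positions where leaving a haplotype is
useful) and solved as an integer program with HiGHS.  The underlying
decision problem is NP-hard — the package includes the reduction from
directed Hamiltonian path as a testable construction — which is why an
exact solver rather than a heuristic is the honest choice at test scale.

See [docs/methods.md](docs/methods.md) for the model, the naive vs
optimized graph constructions, hit semantics, the hardness gadget, and
limitations.

## Worked example

Simulate a 3-haplotype, ~2 kb pangenome and a mosaic sample that switches
donor haplotype once, with error-free 100 bp reads at 10× (every number
below is reproducible from the seed):

```console
$ haplopath simulate --seed 42 -o fixture
{
  ...
  "donors": [2, 1],
  "n_reads": 200,
  "switch_segments": [8],
  "target_length": 2002,
  "true_recombinations": 1
}
```

Infer the sample sequence from the graph and the reads (sketch with
`w=5, k=21`, penalty `c=2`, full-text hit semantics):

```console
$ haplopath infer --gfa fixture/graph.gfa --reads fixture/reads.fq \
      -w 5 -k 21 -c 2 --hits graph -o estimate.fa --log-level WARNING
{
  ...
  "matched_strings": 659,
  "n_hits": 2102,
  "n_strings": 659,
  "objective": 2.0,
  "recombinations": 1,
  "schema_version": 1,
  "sequence_length": 2002,
  "solver_status": "optimal",
  "unmatched_strings": 0
}
```

The solver finds a path with exactly one recombination (objective
`2.0 = c · 1`) that explains all 659 distinct minimizers.  Compare against
the simulated truth:

```console
$ haplopath eval estimate.fa fixture/target.fa
{
  "edit_distance": 0,
  "estimated_length": 2002,
  "identity": 1.0,
  "truth_length": 2002
}
```

The inferred sequence is identical to the hidden mosaic target, and the
inferred recombination count matches the simulated one.

Real graphs can be supplied as GFA 1 (`S`/`L` lines with `P` or `W`
haplotype walks, forward orientation) via `--gfa`, or built from a phased
diploid VCF plus reference with `--vcf sample.vcf.gz --ref ref.fa --region
chr1:10000-12000`.

## Python API

```python
import haplopath as hp
from haplopath.graph_model import StringSet

graph = hp.load_gfa("fixture/graph.gfa")
S = StringSet(strings=frozenset({"GTGTGTGATC", "TAGACGTGT"}))
pre = hp.preprocess(graph, min_query_length=S.min_length())
eg = hp.build_optimized(pre, c=2.0)
hits = hp.find_graph_hits(S, eg)
sol = hp.solve(hp.build_ilp(eg, hits, c=2.0))
path = hp.extract_inferred_path(sol, eg, pre)
```

## Reproduction

All randomness in the package flows from explicit integer seeds.

- **Test suite** (unit, property-based, and the eight acceptance tests —
  solver-vs-oracle equivalence, formulation equivalence, expanded-graph
  equivalence, the Hamiltonian-path gadget, mosaic recovery, penalty
  monotonicity, minimizer correctness, and structural invariants):

  ```sh
  python -m pytest -o addopts= -p no:cacheprovider -q tests/
  ```

- **Acceptance metrics** — recomputes the headline quantities (oracle and
  formulation agreement rates, gadget classification accuracy, mosaic
  recovery rate, mean edit distance/identity, minimizer reference-scan
  agreement) on freshly seeded instances and writes them as JSON:

  ```sh
  python scripts/acceptance.py --seed 1 --out acceptance.json
  ```

Everything runs single-threaded; the solver (HiGHS via
`scipy.optimize.milp`) and the fixed-constant minimizer hashing are
deterministic, so repeated runs with the same seed are byte-identical.
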