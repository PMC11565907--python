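"""Synthetic fixture generators.

Three families of inputs are produced:

* random haplotype panels — an ancestral sequence with SNP/indel variant
  sites, a set of haplotypes drawn over those sites, and the corresponding
  bubble-chain pangenome graph;
* mosaic targets — a sample genome simulated as a recombinant of the panel
  haplotypes, with ground-truth switch positions, plus error-bearing
  uniform-coverage reads;
* Hamiltonian-path reduction instances — the gadget that maps a digraph to a
  path-inference instance whose optimal cost is c·(n+1) exactly when the
  digraph has a Hamiltonian path.  Vertex labels are binary codes separated
  by 0^b 1 padding blocks so that no query string can match across label
  boundaries; the binary alphabet is mapped to {A, C} for DNA-typed
  pipelines.
"""

from __future__ import annotations

import itertools
import json
import math
import os
from dataclasses import dataclass, asdict

import numpy as np

from .graph_model import HaplotypePath, PangenomeGraph, StringSet, reverse_complement
from .readers import VariantSite, build_bubble_graph, write_gfa

DNA = "ACGT"


@dataclass
class SimulationConfig:
    """Conditions for the random-panel / mosaic / read simulation.

    ``variant_density`` is sites per bp; ``coverage`` is mean sequencing
    depth; ``error_rate`` is the per-base substitution rate.  ``seed`` is
    mandatory: all randomness flows from it.
    """

    seed: int
    n_haplotypes: int = 3
    haplotype_length: int = 2000
    variant_density: float = 0.02
    n_recombinations: int = 1
    read_length: int = 100
    coverage: float = 10.0
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_haplotypes < 1 or self.haplotype_length < 1:
            raise ValueError("need at least one haplotype and positive length")
        if min(self.variant_density, self.coverage, self.error_rate) < 0:
            raise ValueError("rates must be non-negative")
        if self.error_rate > 1:
            raise ValueError("error_rate is a per-base probability (<= 1)")
        if self.n_recombinations < 0 or self.read_length < 1:
            raise ValueError("bad recombination count or read length")
        if self.haplotype_length < self.read_length:
            raise ValueError("haplotype_length must be >= read_length")


@dataclass
class HaplotypePanel:
    """A simulated panel: graph plus the aligned per-haplotype segments.

    ``segments[h]`` is the haplotype's sequence cut at variant-site
    boundaries: flank, allele, flank, allele, ..., flank (flanks shared by
    all haplotypes).  ``sequences[h]`` is the concatenation."""

    graph: PangenomeGraph
    sequences: list[str]
    segments: list[list[str]]
    sites: list[VariantSite]
    alleles: list[list[int]]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(DNA), size=n))


def random_pangenome(config: SimulationConfig) -> HaplotypePanel:
    """Simulate an ancestral sequence, place variant sites, draw haplotypes.

    Sites are mostly SNPs with a minority of short indels; every alternate
    allele is carried by at least one haplotype so the bubble graph has no
    unsupported branches.  The spelled haplotype paths reproduce the
    simulated sequences byte-exactly.
    """
    rng = np.random.default_rng(config.seed)
    L = config.haplotype_length
    ref = _random_seq(rng, L)

    n_sites = int(round(config.variant_density * L))
    sites: list[VariantSite] = []
    if n_sites:
        # keep >= 8 bp between sites so indel anchors never overlap
        candidates = np.arange(1, L - 8)
        rng.shuffle(candidates)
        chosen: list[int] = []
        for p in candidates:
            if all(abs(p - q) >= 8 for q in chosen):
                chosen.append(int(p))
            if len(chosen) == n_sites:
                break
        for p in sorted(chosen):
            kind = rng.random()
            ref_allele = ref[p]
            if kind < 0.7:  # SNP
                alt = rng.choice([b for b in DNA if b != ref_allele])
                alleles = (ref_allele, str(alt))
            elif kind < 0.85:  # short insertion after anchor base
                ins = _random_seq(rng, int(rng.integers(1, 5)))
                alleles = (ref_allele, ref_allele + ins)
            else:  # short deletion with anchor base
                dl = int(rng.integers(1, 5))
                alleles = (ref[p : p + dl + 1], ref_allele)
            sites.append(VariantSite(pos=p, alleles=alleles))

    n_hap = config.n_haplotypes
    alleles: list[list[int]] = [[0] * len(sites) for _ in range(n_hap)]
    for si in range(len(sites)):
        # allele frequency of the alternate allele, at least one carrier
        freq = rng.uniform(0.2, 0.8)
        carriers = [h for h in range(n_hap) if rng.random() < freq]
        if not carriers:
            carriers = [int(rng.integers(0, n_hap))]
        for h in carriers:
            alleles[h][si] = 1

    graph = build_bubble_graph(
        ref_seq=ref,
        sites=sites,
        haplotype_alleles=alleles,
        names=[f"sim{h}" for h in range(n_hap)],
        include_reference_path=False,
    )

    segments: list[list[str]] = []
    sequences: list[str] = []
    for h in range(n_hap):
        segs: list[str] = []
        prev = 0
        for si, s in enumerate(sites):
            segs.append(ref[prev : s.pos])
            segs.append(s.alleles[alleles[h][si]])
            prev = s.pos + s.ref_len
        segs.append(ref[prev:])
        segments.append(segs)
        sequences.append("".join(segs))

    from .graph_model import spell

    for h in range(n_hap):
        assert spell(graph.haplotype(h), graph) == sequences[h]
    return HaplotypePanel(
        graph=graph, sequences=sequences, segments=segments, sites=sites,
        alleles=alleles,
    )


@dataclass
class MosaicTarget:
    sequence: str
    donors: list[int]  # donor haplotype per inter-switch block
    switch_segments: list[int]  # aligned segment boundary index per switch
    true_recombinations: int


def simulate_mosaic_target(
    panel: HaplotypePanel,
    n_recombinations: int,
    seed: int,
) -> MosaicTarget:
    """Concatenate haplotype blocks switching at shared segment boundaries.

    Switch points are restricted to boundaries entering a shared flank
    segment, so the mosaic is spelled exactly by an inferred path through the
    panel graph and the true recombination count is well defined.  Each
    switch changes donor to a haplotype that differs from the current donor
    somewhere in the upcoming block, so switches are effective.
    """
    rng = np.random.default_rng(seed)
    n_hap = len(panel.sequences)
    n_seg = len(panel.segments[0])
    if n_recombinations and n_hap < 2:
        raise ValueError("need >= 2 haplotypes to recombine")
    # candidate boundaries: start of each flank segment (even indices > 0)
    boundaries = [i for i in range(2, n_seg - 1, 2)]
    if n_recombinations > len(boundaries):
        raise ValueError(
            f"{n_recombinations} switches requested but only "
            f"{len(boundaries)} shared boundaries available"
        )
    cuts = sorted(
        int(b) for b in rng.choice(boundaries, size=n_recombinations, replace=False)
    )
    blocks = list(zip([0] + cuts, cuts + [n_seg]))

    donors: list[int] = []
    for lo, hi in blocks:
        if not donors:
            donors.append(int(rng.integers(0, n_hap)))
            continue
        prev = donors[-1]
        choices = [
            h for h in range(n_hap)
            if h != prev and panel.segments[h][lo:hi] != panel.segments[prev][lo:hi]
        ]
        if not choices:  # all other haplotypes identical here: take any other
            choices = [h for h in range(n_hap) if h != prev]
        donors.append(int(rng.choice(choices)))

    seq = "".join(
        "".join(panel.segments[d][lo:hi]) for d, (lo, hi) in zip(donors, blocks)
    )
    return MosaicTarget(
        sequence=seq,
        donors=donors,
        switch_segments=cuts,
        true_recombinations=n_recombinations,
    )


def simulate_reads(
    target: str,
    config: SimulationConfig,
) -> list[tuple[str, str]]:
    """Uniform fixed-length reads with substitution errors, both strands.

    The expected read count is coverage * len(target) / read_length."""
    rng = np.random.default_rng(config.seed + 1)
    L, rl = len(target), config.read_length
    n_reads = int(round(config.coverage * L / rl))
    reads: list[tuple[str, str]] = []
    for i in range(n_reads):
        start = int(rng.integers(0, L - rl + 1))
        seq = target[start : start + rl]
        if config.error_rate > 0:
            chars = list(seq)
            errs = np.nonzero(rng.random(rl) < config.error_rate)[0]
            for p in errs:
                chars[p] = rng.choice([b for b in DNA if b != chars[p]])
            seq = "".join(chars)
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        reads.append((f"read{i}", seq))
    return reads


def write_fastq(reads: list[tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_fasta(records: list[tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_fixture_dir(config: SimulationConfig, outdir: str) -> dict:
    """Materialise a full fixture: graph, haplotypes, target, reads, manifest."""
    os.makedirs(outdir, exist_ok=True)
    panel = random_pangenome(config)
    mosaic = simulate_mosaic_target(panel, config.n_recombinations, config.seed)
    reads = simulate_reads(mosaic.sequence, config)
    write_gfa(panel.graph, os.path.join(outdir, "graph.gfa"))
    write_fasta(
        [(f"sim{h}", s) for h, s in enumerate(panel.sequences)],
        os.path.join(outdir, "haplotypes.fa"),
    )
    write_fasta([("target", mosaic.sequence)], os.path.join(outdir, "target.fa"))
    write_fastq(reads, os.path.join(outdir, "reads.fq"))
    manifest = {
        "config": asdict(config),
        "true_recombinations": mosaic.true_recombinations,
        "donors": mosaic.donors,
        "switch_segments": mosaic.switch_segments,
        "n_reads": len(reads),
        "target_length": len(mosaic.sequence),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


@dataclass
class SmallInstance:
    """A small random problem instance for exhaustive cross-validation."""

    graph: PangenomeGraph
    string_set: StringSet
    c: int
    seed: int


def random_small_instance(seed: int) -> SmallInstance:
    """Tiny random panel + query set, sized for exhaustive path enumeration.

    At most 12 graph vertices (before preprocessing), at most 4 haplotypes
    and at most 20 query strings; the penalty is drawn from {0, 1, 2, 5}.
    Query strings are short substrings of a random mosaic of the haplotypes
    plus a few random (usually absent) strings, so instances mix matched,
    unmatched and recombination-requiring queries.
    """
    from .graph_model import spell

    rng = np.random.default_rng(seed)
    n_hap = int(rng.integers(2, 5))
    L = int(rng.integers(24, 40))
    ref = _random_seq(rng, L)
    n_sites = int(rng.integers(1, 4))
    positions = sorted(rng.choice(np.arange(2, L - 2, 2), size=n_sites,
                                  replace=False))
    # enforce spacing >= 2 so SNP sites never collide
    sites = []
    prev = -10
    for p in positions:
        p = int(p)
        if p - prev < 2:
            continue
        prev = p
        ref_allele = ref[p]
        alt = str(rng.choice([b for b in DNA if b != ref_allele]))
        sites.append(VariantSite(pos=p, alleles=(ref_allele, alt)))
    alleles = [[0] * len(sites) for _ in range(n_hap)]
    for si in range(len(sites)):
        carriers = [h for h in range(n_hap) if rng.random() < 0.5]
        if not carriers:
            carriers = [int(rng.integers(0, n_hap))]
        for h in carriers:
            alleles[h][si] = 1
    graph = build_bubble_graph(
        ref_seq=ref, sites=sites, haplotype_alleles=alleles,
        names=[f"s{h}" for h in range(n_hap)], include_reference_path=False,
    )
    assert len(graph.labels) <= 12

    # query strings: substrings of a random mosaic + random decoys
    texts = [spell(graph.haplotype(h), graph) for h in range(n_hap)]
    cut = int(rng.integers(5, L - 5))
    h1, h2 = rng.integers(0, n_hap, size=2)
    mosaic = texts[int(h1)][:cut] + texts[int(h2)][cut:]
    n_q = int(rng.integers(3, 21))
    strings: set[str] = set()
    for _ in range(n_q):
        if rng.random() < 0.8 and len(mosaic) > 8:
            ln = int(rng.integers(4, 7))
            a = int(rng.integers(0, len(mosaic) - ln))
            strings.add(mosaic[a : a + ln])
        else:
            strings.add(_random_seq(rng, int(rng.integers(4, 7))))
    strings = set(list(strings)[:20])
    c = int(rng.choice([0, 1, 2, 5]))
    return SmallInstance(
        graph=graph,
        string_set=StringSet(strings=frozenset(strings)),
        c=c,
        seed=seed,
    )


# ---------------------------------------------------------------------- #
# NP-hardness gadget


@dataclass
class ReductionInstance:
    """Path-inference instance encoding a Hamiltonian-path question.

    ``graph`` is the layered gadget graph with one haplotype per edge;
    ``strings`` must all be matched (together with the s/t padding labels)
    for the cost to drop to c·n, which happens exactly when the digraph has
    a Hamiltonian path."""

    n: int
    c: int
    b: int
    edges: tuple[tuple[int, int], ...]
    graph: PangenomeGraph
    strings: frozenset[str]
    has_hamiltonian: bool
    alphabet: str = "dna"  # "dna" maps 0->A, 1->C; "binary" keeps 0/1


def _bin_block(x: int, b: int, alphabet: str) -> str:
    code = format(x, f"0{b}b") + "0" * b + "1"
    if alphabet == "binary":
        return code
    return code.replace("0", "A").replace("1", "C")


def has_hamiltonian_path(n: int, edges: set[tuple[int, int]]) -> bool:
    """Exhaustive Hamiltonian-path check on vertices 1..n (directed)."""
    if n > 8:
        raise ValueError("exhaustive check limited to n <= 8")
    for perm in itertools.permutations(range(1, n + 1)):
        if all((a, b) in edges for a, b in zip(perm, perm[1:])):
            return True
    return False


def build_reduction(
    edges: list[tuple[int, int]] | set[tuple[int, int]],
    n: int,
    c: int,
    alphabet: str = "dna",
) -> ReductionInstance:
    """Layered gadget for a digraph on vertices 1..n with penalty c >= 1.

    The gadget has n layers of vertex copies u_k^i between terminals s and t.
    Labels are b-bit binary codes padded with 0^b 1 blocks (b chosen so all
    code values fit); the terminals spell long runs of padding-coded values
    that force any low-cost path to include them.  One haplotype path is
    created per gadget edge, supporting only that edge, so after the first
    edge (covered by the starting haplotype) every further edge of an s-t
    traversal costs one recombination: the optimal cost is c·n exactly when
    the digraph has a Hamiltonian path and is strictly larger otherwise.
    Vertex copies with no incident edge are pruned.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if c < 1:
        raise ValueError("need penalty c >= 1")
    eset = {(int(a), int(b)) for a, b in edges}
    for a, b in eset:
        if not (1 <= a <= n and 1 <= b <= n) or a == b:
            raise ValueError(f"bad digraph edge {(a, b)}")

    m = n + 2 * (c * (n + 1) + 1)  # number of query strings / code values
    b = math.ceil(math.log2(m)) + 1

    labels: dict[str, str] = {}
    gedges: set[tuple[str, str]] = set()
    for k in range(1, n + 1):
        for i in range(1, n + 1):
            labels[f"u{k}.{i}"] = _bin_block(k, b, alphabet)
    half = c * (n + 1) + 1
    labels["s"] = "".join(_bin_block(x, b, alphabet) for x in range(n + 1, n + half + 1))
    labels["t"] = "".join(
        _bin_block(x, b, alphabet) for x in range(n + half + 1, m + 1)
    )

    for k in range(1, n + 1):
        gedges.add(("s", f"u{k}.1"))
        gedges.add((f"u{k}.{n}", "t"))
    for (a, bb) in sorted(eset):
        for i in range(1, n):
            gedges.add((f"u{a}.{i}", f"u{bb}.{i+1}"))

    used = {v for e in gedges for v in e}
    labels = {v: lab for v, lab in labels.items() if v in used}
    haplotypes = [
        HaplotypePath(index=i, vertices=e, name=f"e{i}")
        for i, e in enumerate(sorted(gedges))
    ]
    graph = PangenomeGraph(labels=labels, edges=gedges, haplotypes=haplotypes)
    graph.validate()

    strings = frozenset(_bin_block(x, b, alphabet) for x in range(1, m + 1))
    return ReductionInstance(
        n=n, c=c, b=b, edges=tuple(sorted(eset)), graph=graph, strings=strings,
        has_hamiltonian=has_hamiltonian_path(n, eset), alphabet=alphabet,
    )
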