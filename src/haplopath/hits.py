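"""Window minimizers and hit finding in the expanded graph.

The query string set S is built from (w, k) window minimizers of the reads:
within every window of ``w`` consecutive k-mers the k-mer with the smallest
hash is selected (leftmost on ties).  A *hit* for a query string r is a
subpath of the expanded graph whose spelled sequence — allowing a suffix of
the first label and a prefix of the last — equals r.

Two hit finders are provided:

* :func:`find_restricted_hits` — exact string search of each query against
  the spelled haplotype sequences; hits never cross recombination edges.
  This is the scalable mode used by the command-line pipeline.
* :func:`find_graph_hits` — complete enumeration of matching subpaths by
  depth-first search from every (vertex, offset) anchor, including subpaths
  crossing recombination edges.  Intended for small graphs and for tests
  whose ground truth is the exact Problem-1 cost.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .graph_model import StringSet, reverse_complement
from .expanded_graph import ExpandedGraph


class HitEnumerationError(RuntimeError):
    """Raised when hit enumeration exceeds its configured size guard."""


@dataclass(frozen=True)
class MinimizerParams:
    """(w, k) window-minimizer parameters; defaults w=25, k=31."""

    w: int = 25
    k: int = 31
    canonical: bool = True
    hash_name: str = "splitmix"  # or "lexicographic" for debugging

    def __post_init__(self) -> None:
        if self.w < 1:
            raise ValueError("window size w must be >= 1")
        if not 2 <= self.k <= 31:
            raise ValueError("k must be in 2..31 (2-bit packed into 64 bits)")


@dataclass(frozen=True)
class Hit:
    """One matching subpath omega for query ``r``.

    ``haplotype`` is the haplotype index for restricted hits and None for
    graph-wide hits; ``interval`` is the 0-based half-open occurrence window
    on that haplotype's spelled sequence (None for graph-wide hits).
    ``edges`` is the ordered edge list of the subpath in the expanded graph.
    """

    r: str
    edges: tuple[tuple[str, str], ...]
    haplotype: int | None = None
    interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.edges:
            raise ValueError("a hit must cover at least one edge")

    def spelled(self, eg: ExpandedGraph) -> str:
        """Reconstruct the matched graph substring with suffix/prefix
        trimming.  For a canonical hit whose occurrence is on the opposite
        strand this is the reverse complement of the query string."""
        vs = [self.edges[0][0]] + [v for _, v in self.edges]
        inner = "".join(eg.labels[v] for v in vs[1:-1])
        first, last = eg.labels[vs[0]], eg.labels[vs[-1]]
        for target in (self.r, reverse_complement(self.r)):
            # first label contributes a suffix, last label a prefix
            for flen in range(1, len(first) + 1):
                suffix = first[-flen:]
                if not target.startswith(suffix):
                    continue
                remain = target[flen:]
                if not remain.startswith(inner):
                    continue
                tail = remain[len(inner):]
                if 1 <= len(tail) <= len(last) and last.startswith(tail):
                    return suffix + inner + tail
        raise ValueError("hit does not spell its query string")


@dataclass
class HitIndex:
    """Map query string -> list of hits; strand policy recorded."""

    hits: dict[str, list[Hit]]
    canonical: bool = False

    def __getitem__(self, r: str) -> list[Hit]:
        return self.hits.get(r, [])

    def total_hits(self) -> int:
        return sum(len(v) for v in self.hits.values())

    def to_tsv(self) -> str:
        rows = ["r\thaplotype\tstart\tend\tn_edges"]
        for r in sorted(self.hits):
            for h in self.hits[r]:
                hap = "" if h.haplotype is None else h.haplotype
                s, e = h.interval if h.interval else ("", "")
                rows.append(f"{r}\t{hap}\t{s}\t{e}\t{len(h.edges)}")
        return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------- #
# minimizers

_ENC = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_MASK64 = np.uint64(0xFFFFFFFFFFFFFFFF)


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """Fixed 64-bit invertible mixer (splitmix64 finalizer), seed 0."""
    x = x.astype(np.uint64)
    with np.errstate(over="ignore"):
        x = (x + np.uint64(0x9E3779B97F4A7C15)) & _MASK64
        x = ((x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & _MASK64
        x = ((x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & _MASK64
        x = x ^ (x >> np.uint64(31))
    return x


def _kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit packed codes for every k-mer start and a validity mask."""
    arr = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(arr, k)
    valid = (windows >= 0).all(axis=1)
    weights = (4 ** np.arange(k - 1, -1, -1, dtype=np.uint64)).astype(np.uint64)
    codes = (np.where(windows < 0, 0, windows).astype(np.uint64) * weights).sum(
        axis=1, dtype=np.uint64
    )
    return codes, valid


def _rc_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Codes of the reverse complements (complement = 3 - base, reversed)."""
    comp = np.zeros_like(codes)
    x = codes.copy()
    for _ in range(k):
        comp = (comp << np.uint64(2)) | (np.uint64(3) - (x & np.uint64(3)))
        x = x >> np.uint64(2)
    return comp


def window_minimizers(seq: str, params: MinimizerParams) -> set[str]:
    """(w, k) window minimizers of ``seq`` as a set of k-mer strings.

    k-mers containing non-ACGT characters are excluded; windows without any
    valid k-mer select nothing.  With canonical=True each k-mer is replaced
    by the lexicographic strand representative before hashing and reporting.
    """
    k, w = params.k, params.w
    if len(seq) < k:
        return set()
    codes, valid = _kmer_codes(seq, k)
    if params.canonical:
        rc = _rc_codes(codes, k)
        use_rc = rc < codes
        codes = np.where(use_rc, rc, codes)
    if params.hash_name == "lexicographic":
        hashes = codes.copy()
    else:
        hashes = _splitmix64(codes)
    big = np.uint64(0xFFFFFFFFFFFFFFFF)
    hashes = np.where(valid, hashes, big)

    n = len(codes)
    chosen: set[int] = set()
    if n <= w:
        wins = [(0, n)]
    else:
        wins = [(i, i + w) for i in range(n - w + 1)]
    for a, b in wins:
        window = hashes[a:b]
        pos = int(np.argmin(window))  # argmin returns the leftmost minimum
        if window[pos] != big:
            chosen.add(a + pos)

    out = set()
    for pos in chosen:
        code = int(codes[pos])
        kmer = "".join("ACGT"[(code >> (2 * (k - 1 - j))) & 3] for j in range(k))
        out.add(kmer)
    return out


def collect_read_minimizers(
    reads: Iterable[tuple[str, str]] | str,
    params: MinimizerParams,
) -> StringSet:
    """Union of window minimizers over reads, with multiplicity bookkeeping.

    ``reads`` is either an iterable of (name, sequence) pairs or a path to a
    FASTA/FASTQ file (plain or gzipped).  Unreadable records are skipped with
    a warning counted in the log summary.
    """
    import logging

    log = logging.getLogger(__name__)
    if isinstance(reads, str):
        reads = iter_reads(reads)

    mult: dict[str, int] = {}
    skipped = 0
    for name, seq in reads:
        try:
            mins = window_minimizers(seq, params)
        except Exception:  # defensive: a bad record must not kill the run
            skipped += 1
            log.warning("skipping unreadable read %r", name)
            continue
        for m in mins:
            mult[m] = mult.get(m, 0) + 1
    if skipped:
        log.warning("skipped %d unreadable reads", skipped)
    return StringSet(
        strings=frozenset(mult), multiplicity=mult, canonical=params.canonical
    )


def iter_reads(path: str) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) from FASTA/FASTQ, plain or gzip-compressed."""
    import gzip

    from Bio import SeqIO

    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        head = fh.read(1)
        fh.seek(0)
        fmt = "fastq" if head == "@" else "fasta"
        for rec in SeqIO.parse(fh, fmt):
            yield rec.id, str(rec.seq).upper()


# ---------------------------------------------------------------------- #
# hit finding

def _check_label_bound(eg: ExpandedGraph, string_set: StringSet) -> None:
    if not string_set.strings:
        return
    min_r = string_set.min_length()
    max_label = max(len(lab) for lab in eg.labels.values())
    if max_label >= min_r:
        raise ValueError(
            f"vertex label length {max_label} >= shortest query {min_r}; "
            "run split_long_labels on the input graph first"
        )


def _chain_occurrence_edges(
    eg: ExpandedGraph, j: int, start: int, end: int
) -> tuple[tuple[str, str], ...]:
    """Map an occurrence interval on spell(h_j) to chain edges of GE."""
    chain = eg.chains[j]
    # cumulative start offset of each chain vertex's label
    offsets = []
    p = 0
    for cv in chain:
        offsets.append(p)
        p += len(eg.labels[cv])
    first = last = None
    for idx, cv in enumerate(chain):
        ln = len(eg.labels[cv])
        if ln == 0:
            continue
        if offsets[idx] <= start < offsets[idx] + ln:
            first = idx
        if offsets[idx] <= end - 1 < offsets[idx] + ln:
            last = idx
    assert first is not None and last is not None and last > first
    return tuple((chain[i], chain[i + 1]) for i in range(first, last))


def find_restricted_hits(
    string_set: StringSet,
    eg: ExpandedGraph,
    max_hits_per_string: int = 10_000,
) -> HitIndex:
    """Haplotype-restricted hits: exact occurrences within spelled haplotypes.

    Every exact occurrence of r (and of its reverse complement when the
    string set is strand-canonical) in any spelled haplotype yields one hit
    whose edges lie on that haplotype's chain.  Output is independent of
    haplotype processing order.
    """
    _check_label_bound(eg, string_set)
    spelled = ["".join(eg.labels[cv] for cv in chain) for chain in eg.chains]

    index: dict[str, list[Hit]] = {r: [] for r in string_set.strings}
    for r in sorted(string_set.strings):
        queries = {r}
        if string_set.canonical:
            queries.add(reverse_complement(r))
        for j, text in enumerate(spelled):
            for q in sorted(queries):
                pos = text.find(q)
                while pos != -1:
                    edges = _chain_occurrence_edges(eg, j, pos, pos + len(q))
                    index[r].append(
                        Hit(r=r, edges=edges, haplotype=j, interval=(pos, pos + len(q)))
                    )
                    if len(index[r]) > max_hits_per_string:
                        raise HitEnumerationError(
                            f"more than {max_hits_per_string} hits for {r!r}"
                        )
                    pos = text.find(q, pos + 1)
    return HitIndex(hits=index, canonical=string_set.canonical)


def find_graph_hits(
    string_set: StringSet,
    eg: ExpandedGraph,
    max_states: int = 2_000_000,
    max_hits_per_string: int = 10_000,
) -> HitIndex:
    """Complete hit enumeration over the expanded graph (Definition-2 semantics).

    A matching subpath may cross recombination edges.  Hits are canonical:
    the first vertex contributes a non-empty suffix of its label and the last
    a non-empty prefix, so epsilon vertices never terminate a hit.  DFS from
    every (vertex, label-suffix) anchor; a configurable state cap guards
    against enumeration explosion (explicit error, never silent truncation).
    """
    _check_label_bound(eg, string_set)
    index: dict[str, list[Hit]] = {r: [] for r in string_set.strings}
    states = 0

    order = sorted(v for v in eg.labels if v not in (eg.source, eg.sink))

    for r in sorted(string_set.strings):
        queries = {r}
        if string_set.canonical:
            queries.add(reverse_complement(r))
        found: set[tuple[tuple[str, str], ...]] = set()
        for q in sorted(queries):
            for v0 in order:
                lab = eg.labels[v0]
                for flen in range(1, len(lab) + 1):
                    if lab[-flen:] != q[:flen]:
                        continue
                    if flen >= len(q):
                        continue  # whole query inside one label is impossible
                    # DFS: (current vertex, chars consumed, vertex trail)
                    stack = [(v0, flen, (v0,))]
                    while stack:
                        states += 1
                        if states > max_states:
                            raise HitEnumerationError(
                                f"graph-hit enumeration exceeded {max_states} states"
                            )
                        u, consumed, trail = stack.pop()
                        for nxt in eg.out_neighbors(u):
                            if nxt == eg.sink:
                                continue
                            nlab = eg.labels[nxt]
                            remain = len(q) - consumed
                            if not nlab:
                                stack.append((nxt, consumed, trail + (nxt,)))
                                continue
                            take = min(len(nlab), remain)
                            if q[consumed : consumed + take] != nlab[:take]:
                                continue
                            if take == remain:
                                path = trail + (nxt,)
                                edges = tuple(zip(path, path[1:]))
                                if edges not in found:
                                    found.add(edges)
                                    index[r].append(Hit(r=r, edges=edges))
                                    if len(index[r]) > max_hits_per_string:
                                        raise HitEnumerationError(
                                            f"more than {max_hits_per_string} "
                                            f"hits for {r!r}"
                                        )
                            elif take == len(nlab):
                                stack.append((nxt, consumed + take, trail + (nxt,)))
    return HitIndex(hits=index, canonical=string_set.canonical)
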