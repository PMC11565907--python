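"""Unit tests for minimizer sketching and hit finding."""

import gzip

import pytest

import numpy as np

from haplopath.expanded_graph import build_optimized, preprocess
from haplopath.graph_model import StringSet, reverse_complement
from haplopath.hits import (
    HitEnumerationError,
    MinimizerParams,
    collect_read_minimizers,
    find_graph_hits,
    find_restricted_hits,
    iter_reads,
    window_minimizers,
)

from conftest import toy_graph


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def naive_minimizers(seq: str, params: MinimizerParams) -> set[str]:
    """All-windows reference scan mirroring the documented semantics."""
    k, w = params.k, params.w

    def canon(kmer):
        if not params.canonical:
            return kmer
        return min(kmer, reverse_complement(kmer))

    def h(kmer):
        if params.hash_name == "lexicographic":
            code = 0
            for ch in kmer:
                code = code * 4 + "ACGT".index(ch)
            return code
        # mirror the packed-code + splitmix64 pipeline
        from haplopath.hits import _splitmix64

        code = 0
        for ch in kmer:
            code = code * 4 + "ACGT".index(ch)
        return int(_splitmix64(np.array([code], dtype=np.uint64))[0])

    kmers = [seq[i : i + k] for i in range(len(seq) - k + 1)]
    out = set()
    n = len(kmers)
    if n <= 0:
        return out
    windows = [(0, n)] if n <= w else [(i, i + w) for i in range(n - w + 1)]
    for a, b in windows:
        best = None
        for pos in range(a, b):
            kmer = kmers[pos]
            if any(ch not in "ACGT" for ch in kmer):
                continue
            val = h(canon(kmer))
            if best is None or val < best[0]:
                best = (val, canon(kmer))
        if best is not None:
            out.add(best[1])
    return out


def test_w1_equals_all_kmers():
    rng = np.random.default_rng(0)
    seq = _random_seq(rng, 200)
    params = MinimizerParams(w=1, k=5, canonical=False)
    got = window_minimizers(seq, params)
    assert got == {seq[i : i + 5] for i in range(len(seq) - 4)}


def test_matches_naive_scan():
    rng = np.random.default_rng(1)
    for w, k in [(1, 3), (4, 5), (10, 21), (25, 31)]:
        for canonical in (False, True):
            seq = _random_seq(rng, 150)
            params = MinimizerParams(w=w, k=k, canonical=canonical)
            assert window_minimizers(seq, params) == naive_minimizers(seq, params)


def test_canonical_strand_symmetry():
    rng = np.random.default_rng(2)
    seq = _random_seq(rng, 120)
    params = MinimizerParams(w=7, k=11, canonical=True)
    assert window_minimizers(seq, params) == window_minimizers(
        reverse_complement(seq), params
    )


def test_n_bases_excluded():
    seq = "ACGTN" * 10
    params = MinimizerParams(w=3, k=5, canonical=False)
    out = window_minimizers(seq, params)
    assert all("N" not in kmer for kmer in out)
    assert window_minimizers("NNNNNNNN", params) == set()


def test_short_sequence_and_param_validation():
    assert window_minimizers("ACG", MinimizerParams(w=5, k=7)) == set()
    with pytest.raises(ValueError):
        MinimizerParams(w=0, k=5)
    with pytest.raises(ValueError):
        MinimizerParams(w=2, k=1)
    with pytest.raises(ValueError):
        MinimizerParams(w=2, k=32)


def test_collect_read_minimizers_multiplicity_and_files(tmp_path):
    params = MinimizerParams(w=2, k=4, canonical=False)
    reads = [("r1", "ACGTACGT"), ("r2", "ACGTACGT")]
    ss = collect_read_minimizers(reads, params)
    assert ss.strings
    assert all(ss.multiplicity[r] == 2 for r in ss.strings)

    fq = tmp_path / "r.fq"
    fq.write_text("@r1\nACGTACGT\n+\nIIIIIIII\n@r2\nACGTACGT\n+\nIIIIIIII\n")
    assert collect_read_minimizers(str(fq), params).strings == ss.strings

    fa_gz = tmp_path / "r.fa.gz"
    with gzip.open(fa_gz, "wt") as fh:
        fh.write(">r1\nACGTACGT\n>r2\nACGTACGT\n")
    assert collect_read_minimizers(str(fa_gz), params).strings == ss.strings


def test_iter_reads_sniffs_format(tmp_path):
    fa = tmp_path / "x.fa"
    fa.write_text(">a\nACGT\n")
    fq = tmp_path / "x.fq"
    fq.write_text("@a\nACGT\n+\nIIII\n")
    assert list(iter_reads(str(fa))) == [("a", "ACGT")]
    assert list(iter_reads(str(fq))) == [("a", "ACGT")]


def _toy_eg(c=1.0, min_q=3):
    g = toy_graph()
    pre = preprocess(g, min_query_length=min_q)
    return pre, build_optimized(pre, c)


def test_restricted_hits_on_toy():
    # spell(h0) = ACGCA, spell(h1) = ACTCA
    pre, eg = _toy_eg()
    S = StringSet(strings=frozenset({"CGC", "CTC", "GGG"}))
    idx = find_restricted_hits(S, eg)
    assert len(idx["CGC"]) == 1 and idx["CGC"][0].haplotype == 0
    assert idx["CGC"][0].interval == (1, 4)
    assert len(idx["CTC"]) == 1 and idx["CTC"][0].haplotype == 1
    assert idx["GGG"] == []
    for r in ("CGC", "CTC"):
        for hit in idx[r]:
            assert hit.spelled(eg) == r


def test_restricted_hits_canonical_strand():
    pre, eg = _toy_eg()
    # revcomp("GCG") = "CGC" occurs in h0
    S = StringSet(strings=frozenset({"GCG"}), canonical=True)
    idx = find_restricted_hits(S, eg)
    assert len(idx["GCG"]) == 1
    assert idx["GCG"][0].spelled(eg) == "CGC"
    S2 = StringSet(strings=frozenset({"GCG"}), canonical=False)
    assert find_restricted_hits(S2, eg)["GCG"] == []


def test_graph_hits_superset_of_restricted():
    pre, eg = _toy_eg()
    S = StringSet(strings=frozenset({"CGC", "CTC", "ACG", "GGG"}))
    restricted = find_restricted_hits(S, eg)
    graphwide = find_graph_hits(S, eg)
    for r in S.strings:
        assert len(graphwide[r]) >= len(restricted[r])
        for hit in graphwide[r]:
            assert hit.spelled(eg) == r


def test_graph_hits_cross_recombination():
    # the query "CGAT" occurs in neither spelled haplotype (AGCGACAG /
    # AGTGATAG) but is spelled by switching from the C allele of the first
    # bubble to the T allele of the second
    from conftest import two_bubble_graph

    g = two_bubble_graph()
    pre = preprocess(g, min_query_length=4)
    eg = build_optimized(pre, 1.0)
    S = StringSet(strings=frozenset({"CGAT"}))
    assert find_restricted_hits(S, eg)["CGAT"] == []
    hits = find_graph_hits(S, eg)["CGAT"]
    assert hits, "expected a recombination-crossing hit"
    rec_edges = set(eg.recombination_edges())
    assert all(set(h.edges) & rec_edges for h in hits)
    for h in hits:
        assert h.spelled(eg) == "CGAT"


def test_label_bound_enforced():
    g = toy_graph()
    pre = preprocess(g, min_query_length=None)  # labels up to 2 chars survive
    eg = build_optimized(pre, 1.0)
    S = StringSet(strings=frozenset({"AC"}))
    with pytest.raises(ValueError, match="split_long_labels"):
        find_restricted_hits(S, eg)
    with pytest.raises(ValueError, match="split_long_labels"):
        find_graph_hits(S, eg)


def test_graph_hits_state_guard():
    pre, eg = _toy_eg()
    S = StringSet(strings=frozenset({"ACGCA"[:4]}))
    with pytest.raises(HitEnumerationError):
        find_graph_hits(S, eg, max_states=1)
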