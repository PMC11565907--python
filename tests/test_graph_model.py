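"""Unit tests for the core data model and cost function."""

import pytest

from haplopath.graph_model import (
    GraphValidationError,
    HaplotypePath,
    InferredPath,
    PangenomeGraph,
    StringSet,
    cost,
    recombination_count,
    reverse_complement,
    spell,
    string_matched,
)


def test_haplotype_path_one_based_access():
    h = HaplotypePath(index=0, vertices=("a", "b", "c"))
    assert h.at(1) == "a" and h.at(3) == "c"
    assert len(h) == 3
    with pytest.raises(IndexError):
        h.at(0)
    with pytest.raises(IndexError):
        h.at(4)


def test_empty_haplotype_rejected():
    with pytest.raises(GraphValidationError):
        HaplotypePath(index=0, vertices=())


def test_spell_haplotype_and_inferred_path(toy):
    assert spell(toy.haplotype(0), toy) == "ACGCA"
    assert spell(toy.haplotype(1), toy) == "ACTCA"
    p = InferredPath(steps=(("f0", 0), ("a1", 1), ("f1", 1)))
    assert spell(p, toy) == "ACTCA"


def test_recombination_count_counts_switches_not_steps():
    p = InferredPath(steps=(("f0", 0), ("a0", 0), ("f1", 1)))
    assert recombination_count(p) == 1
    q = InferredPath(steps=(("f0", 0), ("a0", 0), ("f1", 0)))
    assert recombination_count(q) == 0


def test_inferred_path_validation_rejects_bad_steps(toy):
    with pytest.raises(GraphValidationError):
        InferredPath(steps=()).validate(toy)
    # haplotype 0 does not cover a1
    with pytest.raises(GraphValidationError):
        InferredPath(steps=(("a1", 0),)).validate(toy)
    # (a0, a1) is not an edge
    with pytest.raises(GraphValidationError):
        InferredPath(steps=(("a0", 0), ("a1", 1))).validate(toy)
    # staying on a haplotype requires consecutive vertices on it: haplotype 0
    # covers both a and c but only via b, while the edge (a, c) exists
    labels = {"a": "A", "b": "C", "c": "G"}
    edges = {("a", "b"), ("b", "c"), ("a", "c")}
    haps = [
        HaplotypePath(index=0, vertices=("a", "b", "c")),
        HaplotypePath(index=1, vertices=("a", "c")),
    ]
    g = PangenomeGraph(labels=labels, edges=edges, haplotypes=haps)
    g.validate()
    InferredPath(steps=(("a", 1), ("c", 1))).validate(g)  # fine on hap 1
    with pytest.raises(GraphValidationError):
        InferredPath(steps=(("a", 0), ("c", 0))).validate(g)


def test_graph_validate_rejects_cycle():
    labels = {"a": "A", "b": "C"}
    edges = {("a", "b"), ("b", "a")}
    haps = [HaplotypePath(index=0, vertices=("a", "b", "a"))]
    with pytest.raises(GraphValidationError):
        PangenomeGraph(labels=labels, edges=edges, haplotypes=haps).validate()


def test_graph_validate_rejects_unsupported_edge(toy):
    g = PangenomeGraph(labels=dict(toy.labels),
                       edges=set(toy.edges) | {("a0", "a1")},
                       haplotypes=list(toy.haplotypes))
    # a0 -> a1 exists as an edge but is not an edge of the DAG spelled by
    # any haplotype -> creates a cycle-free but unsupported edge
    with pytest.raises(GraphValidationError):
        g.validate()


def test_graph_validate_rejects_uncovered_vertex(toy):
    labels = dict(toy.labels)
    labels["orphan"] = "GG"
    g = PangenomeGraph(labels=labels, edges=set(toy.edges),
                       haplotypes=list(toy.haplotypes))
    with pytest.raises(GraphValidationError):
        g.validate()


def test_graph_validate_rejects_bad_haplotype_indices(toy):
    haps = [HaplotypePath(index=1, vertices=("f0", "a0", "f1"))]
    g = PangenomeGraph(labels=dict(toy.labels), edges=set(toy.edges),
                       haplotypes=haps)
    with pytest.raises(GraphValidationError):
        g.validate()


def test_graph_validate_rejects_empty_label_outside_epsilon(toy):
    labels = dict(toy.labels)
    labels["a0"] = ""
    g = PangenomeGraph(labels=labels, edges=set(toy.edges),
                       haplotypes=list(toy.haplotypes))
    with pytest.raises(GraphValidationError):
        g.validate()


def test_haps_and_out_neighbors(toy):
    assert toy.haps("f0") == frozenset({0, 1})
    assert toy.haps("a0") == frozenset({0})
    assert toy.out_neighbors("f0") == ("a0", "a1")
    assert toy.out_neighbors("f1") == ()


def test_string_set_invariants():
    s = StringSet(strings=frozenset({"ACG", "TT"}))
    assert len(s) == 2
    assert s.min_length() == 2
    with pytest.raises(ValueError):
        StringSet(strings=frozenset({"A"}))
    with pytest.raises(ValueError):
        StringSet(strings=frozenset()).min_length()


def test_reverse_complement():
    assert reverse_complement("ACGT") == "ACGT"
    assert reverse_complement("AAC") == "GTT"
    assert reverse_complement(reverse_complement("GATTACA")) == "GATTACA"


def test_string_matched_canonical():
    assert string_matched("AC", "TTACTT")
    assert not string_matched("GT", "TTACTT", canonical=False)
    # revcomp(GT) = AC occurs
    assert string_matched("GT", "TTACTT", canonical=True)


def test_cost_combines_switches_and_unmatched(toy):
    # path through the G allele; "TC" occurs only on the T-allele path
    p = InferredPath(steps=(("f0", 0), ("a0", 0), ("f1", 0)))
    S = StringSet(strings=frozenset({"CG", "TC"}))
    assert cost(p, S, 5.0, toy) == 1.0  # 0 switches + 1 unmatched
    q = InferredPath(steps=(("f0", 0), ("a1", 1), ("f1", 0)))
    assert cost(q, S, 5.0, toy) == 10.0 + 1.0  # 2 switches, "CG" unmatched
    with pytest.raises(ValueError):
        cost(p, S, -1.0, toy)


def test_cost_canonical_flag(toy):
    p = InferredPath(steps=(("f0", 0), ("a0", 0), ("f1", 0)))
    # revcomp("CG") = "CG"; revcomp("GC") = "GC" absent; revcomp("TG")="CA"
    S = StringSet(strings=frozenset({"TG"}), canonical=True)
    assert cost(p, S, 1.0, toy) == 0.0  # CA occurs in ACGCA via revcomp
    S2 = StringSet(strings=frozenset({"TG"}), canonical=False)
    assert cost(p, S2, 1.0, toy) == 1.0
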