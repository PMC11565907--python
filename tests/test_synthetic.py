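"""Unit tests for the synthetic data generators and the reduction gadget."""

import itertools
import json

import pytest

from haplopath.graph_model import reverse_complement, spell
from haplopath.synthetic import (
    SimulationConfig,
    build_reduction,
    has_hamiltonian_path,
    random_pangenome,
    random_small_instance,
    simulate_mosaic_target,
    simulate_reads,
    write_fixture_dir,
)


def _cfg(**kw):
    base = dict(seed=1, n_haplotypes=3, haplotype_length=400,
                variant_density=0.02, n_recombinations=1,
                read_length=50, coverage=5, error_rate=0.0)
    base.update(kw)
    return SimulationConfig(**base)


def test_random_pangenome_deterministic():
    a = random_pangenome(_cfg())
    b = random_pangenome(_cfg())
    assert a.sequences == b.sequences
    assert a.graph.labels == b.graph.labels
    c = random_pangenome(_cfg(seed=2))
    assert c.sequences != a.sequences


def test_random_pangenome_spells_sequences():
    panel = random_pangenome(_cfg())
    for h, seq in enumerate(panel.sequences):
        assert spell(panel.graph.haplotype(h), panel.graph) == seq


def test_zero_density_single_chain():
    panel = random_pangenome(_cfg(variant_density=0.0))
    assert len(set(panel.sequences)) == 1
    # all haplotypes share every vertex
    g = panel.graph
    for v in g.labels:
        assert g.haps(v) == frozenset(range(len(panel.sequences)))


def test_mosaic_target_zero_switches_is_a_haplotype():
    panel = random_pangenome(_cfg())
    t = simulate_mosaic_target(panel, 0, seed=3)
    assert t.true_recombinations == 0
    assert t.sequence in panel.sequences


def test_mosaic_target_switches_change_effective_donor():
    panel = random_pangenome(_cfg(seed=4))
    t = simulate_mosaic_target(panel, 2, seed=5)
    assert t.true_recombinations == 2
    assert len(t.donors) == 3
    assert all(a != b for a, b in zip(t.donors, t.donors[1:]))
    # the mosaic is the concatenation of donor segments at the cut points
    segs = panel.segments
    n_seg = len(segs[0])
    blocks = list(zip([0] + t.switch_segments, t.switch_segments + [n_seg]))
    manual = "".join("".join(segs[d][lo:hi])
                     for d, (lo, hi) in zip(t.donors, blocks))
    assert manual == t.sequence


def test_mosaic_requires_enough_boundaries():
    panel = random_pangenome(_cfg(haplotype_length=60, variant_density=0.02))
    with pytest.raises(ValueError):
        simulate_mosaic_target(panel, 50, seed=1)


def test_simulate_reads_exact_and_counted():
    cfg = _cfg(error_rate=0.0, coverage=8)
    panel = random_pangenome(cfg)
    target = panel.sequences[0]
    reads = simulate_reads(target, cfg)
    assert len(reads) == round(cfg.coverage * len(target) / cfg.read_length)
    for _, seq in reads:
        assert seq in target or reverse_complement(seq) in target


def test_simulate_reads_errors_change_bases():
    cfg = _cfg(error_rate=0.5, coverage=2)
    panel = random_pangenome(cfg)
    target = panel.sequences[0]
    reads = simulate_reads(target, cfg)
    exact = sum(1 for _, s in reads
                if s in target or reverse_complement(s) in target)
    assert exact < len(reads)


def test_write_fixture_dir_deterministic(tmp_path):
    cfg = _cfg()
    d1, d2 = tmp_path / "a", tmp_path / "b"
    m1 = write_fixture_dir(cfg, str(d1))
    m2 = write_fixture_dir(cfg, str(d2))
    assert m1 == m2
    for name in ("graph.gfa", "haplotypes.fa", "target.fa", "reads.fq",
                 "manifest.json"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
    man = json.loads((d1 / "manifest.json").read_text())
    assert man["true_recombinations"] == cfg.n_recombinations


def test_config_validation():
    with pytest.raises(TypeError):
        SimulationConfig()  # seed is mandatory
    with pytest.raises(ValueError):
        _cfg(n_haplotypes=0)
    with pytest.raises(ValueError):
        _cfg(error_rate=2.0)


def test_random_small_instance_bounds():
    for seed in range(10):
        inst = random_small_instance(seed)
        assert len(inst.graph.labels) <= 12
        assert 2 <= len(inst.graph.haplotypes) <= 4
        assert 0 < len(inst.string_set) <= 20
        assert inst.c in (0, 1, 2, 5)
        inst.graph.validate()


def test_has_hamiltonian_path_small_cases():
    assert has_hamiltonian_path(2, {(1, 2)})
    assert not has_hamiltonian_path(2, set())
    assert has_hamiltonian_path(3, {(1, 2), (2, 3)})
    assert not has_hamiltonian_path(3, {(1, 2), (1, 3)})
    assert has_hamiltonian_path(4, {(2, 1), (1, 3), (3, 4)})


def test_build_reduction_structure():
    inst = build_reduction({(1, 2)}, n=2, c=1)
    g = inst.graph
    # one haplotype per edge, each supporting exactly that edge
    assert len(g.haplotypes) == len(g.edges)
    assert {h.vertices for h in g.haplotypes} == set(g.edges)
    # the query strings are the b-bit padded codes of 1..m over {A, C}
    m = inst.n + 2 * (inst.c * (inst.n + 1) + 1)
    assert len(inst.strings) == m
    for r in inst.strings:
        assert set(r) <= {"A", "C"}
        assert len(r) == 2 * inst.b + 1
    assert inst.has_hamiltonian


def test_build_reduction_binary_alphabet_and_pruning():
    inst = build_reduction({(1, 2)}, n=3, c=1, alphabet="binary")
    assert all(set(r) <= {"0", "1"} for r in inst.strings)
    # vertex u3.2 (value 3, layer 2) has no incident edge and is pruned
    assert "u3.2" not in inst.graph.labels


def test_build_reduction_validation():
    with pytest.raises(ValueError):
        build_reduction(set(), n=1, c=1)
    with pytest.raises(ValueError):
        build_reduction(set(), n=2, c=0)
    with pytest.raises(ValueError):
        build_reduction({(1, 1)}, n=2, c=1)
    with pytest.raises(ValueError):
        build_reduction({(0, 5)}, n=2, c=1)


def test_has_hamiltonian_matches_exhaustive_n3():
    pairs = [(a, b) for a in range(1, 4) for b in range(1, 4) if a != b]
    for bits in itertools.product([0, 1], repeat=len(pairs)):
        edges = {p for p, use in zip(pairs, bits) if use}
        # reference check: try all vertex permutations
        ref = any(
            all((p[i], p[i + 1]) in edges for i in range(2))
            for p in itertools.permutations(range(1, 4))
        )
        assert has_hamiltonian_path(3, edges) == ref
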