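"""Input readers: GFA 1.x graphs and phased-VCF + FASTA bubble graphs.

Both readers produce a validated :class:`~haplopath.graph_model.PangenomeGraph`
in which every haplotype is embedded as a forward-oriented path.  Reverse
orientation steps are rejected: the inference model has no notion of
reverse-complement traversal, so a graph that needs them is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph_model import (
    GFAParseError,
    GraphValidationError,
    HaplotypePath,
    PangenomeGraph,
)

__all__ = [
    "load_gfa",
    "write_gfa",
    "load_vcf",
    "VariantSite",
    "build_bubble_graph",
]


# ---------------------------------------------------------------------- #
# GFA


def load_gfa(path: str) -> PangenomeGraph:
    """Read a GFA 1.x file with S-lines and P- or W-line haplotype paths.

    Segment names become vertex ids.  Every path step must be forward
    oriented; links must be end-to-start with 0M/"*" overlap.
    """
    labels: dict[str, str] = {}
    edges: set[tuple[str, str]] = set()
    paths: list[tuple[str, list[str]]] = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            tag = fields[0]
            if tag == "H":
                continue
            if tag == "S":
                if len(fields) < 3:
                    raise GFAParseError(f"line {lineno}: S-line needs name and sequence")
                name, seq = fields[1], fields[2]
                if seq == "*":
                    raise GFAParseError(f"line {lineno}: segment {name!r} has no sequence")
                if name in labels:
                    raise GFAParseError(f"line {lineno}: duplicate segment {name!r}")
                labels[name] = seq.upper()
            elif tag == "L":
                if len(fields) < 6:
                    raise GFAParseError(f"line {lineno}: truncated L-line")
                u, uo, v, vo, overlap = fields[1:6]
                if uo != "+" or vo != "+":
                    raise GFAParseError(
                        f"line {lineno}: reverse-orientation link not supported"
                    )
                if overlap not in ("*", "0M"):
                    raise GFAParseError(
                        f"line {lineno}: only 0M/'*' overlaps supported, got {overlap!r}"
                    )
                edges.add((u, v))
            elif tag == "P":
                if len(fields) < 3:
                    raise GFAParseError(f"line {lineno}: truncated P-line")
                name, steps = fields[1], fields[2]
                vs = []
                for step in steps.split(","):
                    if not step:
                        raise GFAParseError(f"line {lineno}: empty path step")
                    seg, orient = step[:-1], step[-1]
                    if orient == "-":
                        raise GFAParseError(
                            f"line {lineno}: reverse-orientation step {step!r} "
                            "not supported"
                        )
                    if orient != "+":
                        raise GFAParseError(f"line {lineno}: malformed step {step!r}")
                    vs.append(seg)
                paths.append((name, vs))
            elif tag == "W":
                if len(fields) < 7:
                    raise GFAParseError(f"line {lineno}: truncated W-line")
                sample, hap_ix, seqid = fields[1], fields[2], fields[3]
                walk = fields[6]
                if "<" in walk:
                    raise GFAParseError(
                        f"line {lineno}: reverse-orientation walk step not supported"
                    )
                vs = [s for s in walk.split(">") if s]
                if not vs:
                    raise GFAParseError(f"line {lineno}: empty walk")
                paths.append((f"{sample}#{hap_ix}#{seqid}", vs))
            # other record types ignored

    if not paths:
        raise GFAParseError("GFA contains no P- or W-line haplotype paths")
    for name, vs in paths:
        for seg in vs:
            if seg not in labels:
                raise GFAParseError(f"path {name!r} references unknown segment {seg!r}")

    graph = PangenomeGraph(
        labels=labels,
        edges=edges,
        haplotypes=[
            HaplotypePath(index=i, vertices=tuple(vs), name=name)
            for i, (name, vs) in enumerate(paths)
        ],
    )
    graph.validate()
    return graph


def write_gfa(graph: PangenomeGraph, path: str) -> None:
    """Write a graph as GFA 1.0 (S/L/P lines, forward orientation only)."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for v in sorted(graph.labels):
            fh.write(f"S\t{v}\t{graph.labels[v]}\n")
        for u, v in sorted(graph.edges):
            fh.write(f"L\t{u}\t+\t{v}\t+\t0M\n")
        for h in graph.haplotypes:
            steps = ",".join(f"{v}+" for v in h.vertices)
            fh.write(f"P\t{h.name or f'hap{h.index}'}\t{steps}\t*\n")


# ---------------------------------------------------------------------- #
# bubble-chain construction (shared by the VCF reader and the simulator)


@dataclass(frozen=True)
class VariantSite:
    """One non-overlapping variant site on a reference segment.

    ``pos`` is 0-based on the reference segment; ``alleles[0]`` is the
    reference allele (as spelled by the reference), further entries are
    alternates.  All alleles must be non-empty (VCF anchor-base convention).
    """

    pos: int
    alleles: tuple[str, ...]

    @property
    def ref_len(self) -> int:
        return len(self.alleles[0])


def build_bubble_graph(
    ref_seq: str,
    sites: list[VariantSite],
    haplotype_alleles: list[list[int]],
    names: list[str],
    ref_name: str = "REF",
    include_reference_path: bool = True,
) -> PangenomeGraph:
    """Build a bubble-chain DAG from a reference and non-overlapping sites.

    Reference segments between sites become shared vertices; each allele used
    by at least one haplotype becomes its own vertex.  ``haplotype_alleles``
    gives, per haplotype, one allele index per site.  Edges are exactly the
    consecutive pairs of the resulting paths, so every edge is supported by
    construction.
    """
    if len(haplotype_alleles) != len(names):
        raise ValueError("one name per haplotype required")
    prev_end = 0
    for s in sites:
        if s.pos < prev_end:
            raise GraphValidationError(
                f"overlapping variant sites at reference position {s.pos}"
            )
        if any(a == "" for a in s.alleles):
            raise GraphValidationError(f"empty allele at position {s.pos}")
        if ref_seq[s.pos : s.pos + s.ref_len] != s.alleles[0]:
            raise GraphValidationError(
                f"reference allele {s.alleles[0]!r} at position {s.pos} does not "
                f"match reference sequence"
            )
        prev_end = s.pos + s.ref_len

    rows: list[list[int]] = []
    if include_reference_path:
        rows.append([0] * len(sites))
        names = [ref_name] + list(names)
    rows.extend(haplotype_alleles)
    for row in rows:
        if len(row) != len(sites):
            raise ValueError("each haplotype needs one allele index per site")

    labels: dict[str, str] = {}
    # flank i spans [end of site i-1, start of site i); flank len(sites) is the tail
    flank_id: dict[int, str | None] = {}
    prev_end = 0
    for i, s in enumerate(sites):
        seq = ref_seq[prev_end : s.pos]
        flank_id[i] = None
        if seq:
            flank_id[i] = f"F{i}"
            labels[f"F{i}"] = seq
        prev_end = s.pos + s.ref_len
    tail = ref_seq[prev_end:]
    flank_id[len(sites)] = None
    if tail:
        flank_id[len(sites)] = f"F{len(sites)}"
        labels[f"F{len(sites)}"] = tail

    used_alleles = {(i, a) for row in rows for i, a in enumerate(row)}
    for i, s in enumerate(sites):
        for a, allele in enumerate(s.alleles):
            if (i, a) in used_alleles:
                labels[f"S{i}A{a}"] = allele

    haplotypes: list[HaplotypePath] = []
    edges: set[tuple[str, str]] = set()
    for hap_ix, (row, name) in enumerate(zip(rows, names)):
        vs: list[str] = []
        for i, a in enumerate(row):
            if a >= len(sites[i].alleles):
                raise ValueError(f"allele index {a} out of range at site {i}")
            if flank_id[i] is not None:
                vs.append(flank_id[i])  # type: ignore[arg-type]
            vs.append(f"S{i}A{a}")
        if flank_id[len(sites)] is not None:
            vs.append(flank_id[len(sites)])  # type: ignore[arg-type]
        if not vs:
            # no sites and empty reference is degenerate
            raise GraphValidationError("empty reference segment")
        haplotypes.append(HaplotypePath(index=hap_ix, vertices=tuple(vs), name=name))
        edges.update(zip(vs, vs[1:]))

    graph = PangenomeGraph(labels=labels, edges=edges, haplotypes=haplotypes)
    graph.validate()
    return graph


# ---------------------------------------------------------------------- #
# VCF


def load_vcf(
    vcf: str,
    ref_fasta: str,
    region: tuple[str, int, int],
) -> PangenomeGraph:
    """Build a bubble-chain graph from fully phased VCF records.

    ``region`` is (contig, start, end), 0-based half-open.  One haplotype
    path is created per sample haplotype, plus one for the reference.
    Overlapping/nested records, unphased genotypes, symbolic alleles and
    records extending past the region are rejected.
    """
    import pysam
    from pyfaidx import Fasta

    contig, start, end = region
    if not 0 <= start < end:
        raise ValueError(f"bad region {region!r}")
    fa = Fasta(ref_fasta, as_raw=True, sequence_always_upper=True)
    if contig not in fa:
        raise GraphValidationError(f"contig {contig!r} absent from {ref_fasta!r}")
    ref_seq = str(fa[contig][start:end])
    if len(ref_seq) < end - start:
        raise GraphValidationError(f"reference does not cover region {region!r}")

    sites: list[VariantSite] = []
    rows_alleles: list[list[int]] = []  # transposed later
    sample_names: list[str] = []
    per_site_gt: list[list[int]] = []

    with pysam.VariantFile(vcf) as vf:
        samples = list(vf.header.samples)
        prev_end = -1
        for rec in vf:
            if rec.contig != contig:
                continue
            pos0 = rec.start  # 0-based
            if pos0 < start or pos0 >= end:
                continue
            ref_allele = rec.ref.upper()
            if pos0 + len(ref_allele) > end:
                raise GraphValidationError(
                    f"record at {contig}:{rec.pos} extends past region end"
                )
            alts = tuple((a or "").upper() for a in (rec.alts or ()))
            if any(a.startswith("<") or "[" in a or "]" in a or a in (".", "*", "")
                   for a in alts):
                raise GraphValidationError(
                    f"symbolic/breakend allele at {contig}:{rec.pos} not supported"
                )
            if pos0 < prev_end:
                raise GraphValidationError(
                    f"overlapping variant records at {contig}:{rec.pos}"
                )
            prev_end = pos0 + len(ref_allele)

            gts: list[int] = []
            for s in samples:
                call = rec.samples[s]
                alleles = call["GT"]
                if alleles is None or any(a is None for a in alleles):
                    raise GraphValidationError(
                        f"missing genotype for sample {s!r} at {contig}:{rec.pos}"
                    )
                if len(alleles) > 1 and not call.phased:
                    raise GraphValidationError(
                        f"unphased genotype for sample {s!r} at {contig}:{rec.pos}"
                    )
                gts.extend(int(a) for a in alleles)
            if not sample_names:
                # enumerate sample haplotypes once, from the first record
                sample_names = _sample_haplotype_names(vf, samples, rec)
            sites.append(
                VariantSite(pos=pos0 - start, alleles=(ref_allele,) + alts)
            )
            per_site_gt.append(gts)

    if sites and any(len(g) != len(per_site_gt[0]) for g in per_site_gt):
        raise GraphValidationError("inconsistent ploidy across records")

    if not sites:
        # no variants: one chain vertex, every sample spells the reference
        with pysam.VariantFile(vcf) as vf:
            samples = list(vf.header.samples)
        names = ["REF"] + [f"{s}#1" for s in samples]
        labels = {"F0": ref_seq}
        haplotypes = [
            HaplotypePath(index=i, vertices=("F0",), name=n)
            for i, n in enumerate(names)
        ]
        graph = PangenomeGraph(labels=labels, edges=set(), haplotypes=haplotypes)
        graph.validate()
        return graph

    n_hap = len(per_site_gt[0])
    rows_alleles = [[per_site_gt[s][h] for s in range(len(sites))] for h in range(n_hap)]
    return build_bubble_graph(
        ref_seq=ref_seq,
        sites=sites,
        haplotype_alleles=rows_alleles,
        names=sample_names,
    )


def _sample_haplotype_names(vf, samples, rec) -> list[str]:
    names = []
    for s in samples:
        ploidy = len(rec.samples[s]["GT"])
        for h in range(ploidy):
            names.append(f"{s}#{h + 1}")
    return names
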