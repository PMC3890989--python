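"""Host/nested gene discovery by strict intron containment.

A gene is *nested* when it lies entirely inside an intron of another
(*host*) gene: its start coordinate is strictly greater than the intron's
start and its end strictly smaller than the intron's end.  Boundary-touching
genes are not nested.  Containment is evaluated on gene spans against the
deduplicated union of the host's introns over all isoforms, on either
strand of the same chromosome.

The search is accelerated with one interval tree of gene spans per
chromosome; a brute-force all-pairs check with identical semantics is kept
in the test suite as an independent oracle.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from intronpas.annotation_io import GenomeAnnotation, GenomicInterval

RELATIONS = ("same_strand", "opposite_strand")
HOST_GROUPS = ("all_same", "all_opposite", "mixed")


@dataclass(frozen=True)
class NestedPair:
    """One host-gene / nested-gene containment record."""

    host_gene_id: str
    host_intron: GenomicInterval
    nested_gene_id: str
    relation: str

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")
        if self.host_gene_id == self.nested_gene_id:
            raise ValueError("a gene cannot be nested in itself")


@dataclass
class NestedSummary:
    n_host_genes: int
    n_nested_genes: int
    n_same_direction: int
    host_strand_groups: dict[str, int]
    affected_gene_fraction: float = 0.0
    total_genes: int = 0

    def __post_init__(self) -> None:
        if self.n_same_direction > self.n_nested_genes:
            raise ValueError("same-direction count exceeds nested-gene count")
        if sum(self.host_strand_groups.values()) != self.n_host_genes:
            raise ValueError("host strand groups must sum to the host count")


def _relation(host_strand: str, nested_strand: str) -> str:
    return "same_strand" if host_strand == nested_strand else "opposite_strand"


def find_nested(a: GenomeAnnotation) -> list[NestedPair]:
    """All (host gene, host intron, nested gene) strict containments.

    A gene nested in introns of several hosts yields one pair per host;
    within one host a nested gene is counted once even when several
    isoforms' introns contain it (the smallest containing intron, ties
    broken by coordinate, is the one reported).  Genes on strand ``.`` are
    skipped for the strand relation and excluded (logged upstream).
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for gene in a:
        trees[gene.interval.chrom].addi(gene.interval.start, gene.interval.end, gene)

    pairs: dict[tuple[str, str], NestedPair] = {}
    for host in a.sorted_genes():
        tree = trees.get(host.interval.chrom)
        if tree is None:
            continue
        for intron in host.introns():
            if intron.length < 3:
                continue
            # candidate genes overlapping the intron's strict interior
            for hit in tree.overlap(intron.start + 1, intron.end - 1):
                cand = hit.data
                if cand.id == host.id:
                    continue
                if not (
                    cand.interval.start > intron.start
                    and cand.interval.end < intron.end
                ):
                    continue
                if cand.strand == "." or host.strand == ".":
                    continue
                key = (host.id, cand.id)
                pair = NestedPair(
                    host_gene_id=host.id,
                    host_intron=intron,
                    nested_gene_id=cand.id,
                    relation=_relation(host.strand, cand.strand),
                )
                prev = pairs.get(key)
                if prev is None or (intron.length, intron) < (
                    prev.host_intron.length,
                    prev.host_intron,
                ):
                    pairs[key] = pair
    return sorted(
        pairs.values(),
        key=lambda p: (p.host_intron.chrom, p.host_intron.start, p.host_gene_id, p.nested_gene_id),
    )


def summarize_nested(pairs: list[NestedPair], a: GenomeAnnotation) -> NestedSummary:
    """Distinct host/nested counts, strand statistics, and affected fraction.

    ``n_same_direction`` counts distinct nested genes transcribed in the
    same direction as (at least one of) their hosts.  Each host is grouped
    by the strands of its nested genes: all on the host's strand, all
    opposite, or mixed.
    """
    hosts: dict[str, list[str]] = defaultdict(list)
    nested_ids: set[str] = set()
    same_direction: set[str] = set()
    for p in pairs:
        hosts[p.host_gene_id].append(p.relation)
        nested_ids.add(p.nested_gene_id)
        if p.relation == "same_strand":
            same_direction.add(p.nested_gene_id)

    groups = {g: 0 for g in HOST_GROUPS}
    for relations in hosts.values():
        kinds = set(relations)
        if kinds == {"same_strand"}:
            groups["all_same"] += 1
        elif kinds == {"opposite_strand"}:
            groups["all_opposite"] += 1
        else:
            groups["mixed"] += 1

    total_genes = len(a)
    affected = len(hosts) + len(nested_ids)
    return NestedSummary(
        n_host_genes=len(hosts),
        n_nested_genes=len(nested_ids),
        n_same_direction=len(same_direction),
        host_strand_groups=groups,
        affected_gene_fraction=(affected / total_genes if total_genes else 0.0),
        total_genes=total_genes,
    )
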