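"""Catalogue of genes with an intron-terminated transcript isoform.

A gene enters the catalogue when one of its isoforms (the *terminated*
form) ends inside an intron of a sibling isoform (the *spliced* form):
the terminated isoform's 3' end lies strictly between the donor (5')
and acceptor (3') splice sites of one specific intron of the spliced
isoform, and its last exon starts strictly upstream of that donor.  All
comparisons are in transcription direction and mirror on the minus strand.

Two exclusion filters follow the catalogue:

1. genes whose span overlaps any other gene's span are dropped — reads in
   the overlap cannot be attributed to one gene;
2. only genes with exactly two annotated transcripts forming the
   spliced/terminated pattern are retained, so the downstream two-isoform
   read-density model applies cleanly.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from intronpas.annotation_io import (
    GenomeAnnotation,
    GenomicInterval,
    Transcript,
    derive_introns,
)


@dataclass(frozen=True)
class IntronTerminatedCandidate:
    """One (spliced isoform, intron-terminated isoform) event in a gene.

    ``donor_site`` and ``acceptor_site`` are the genomic positions of the
    containing intron's 5' and 3' splice sites; on the minus strand the
    donor is the genomically larger coordinate.  ``termination_point`` is
    the terminated isoform's 3' end.
    """

    gene_id: str
    spliced_transcript_id: str
    terminated_transcript_id: str
    donor_site: int
    acceptor_site: int
    termination_point: int
    intron: GenomicInterval


@dataclass
class CatalogReport:
    n_candidates: int
    n_excluded_overlap: int
    n_two_form: int
    retained: list[IntronTerminatedCandidate] = field(default_factory=list)
    n_candidate_events: int = 0


def _terminates_within(spliced: Transcript, other: Transcript) -> IntronTerminatedCandidate | None:
    """Check one ordered isoform pair; return the candidate event or None."""
    term = other.three_prime_end()
    last_exon = other.last_exon()
    for intron in derive_introns(spliced):
        if spliced.strand != "-":
            donor, acceptor = intron.start, intron.end
            inside = donor < term < acceptor
            upstream = last_exon.start < donor
        else:
            donor, acceptor = intron.end, intron.start
            inside = acceptor < term < donor
            upstream = last_exon.end > donor
        if inside and upstream:
            return IntronTerminatedCandidate(
                gene_id=spliced.gene_id,
                spliced_transcript_id=spliced.id,
                terminated_transcript_id=other.id,
                donor_site=donor,
                acceptor_site=acceptor,
                termination_point=term,
                intron=intron,
            )
    return None


def find_intron_terminated(a: GenomeAnnotation) -> list[IntronTerminatedCandidate]:
    """All isoform pairs where one isoform ends inside an intron of the other.

    Strict betweenness on both splice sites: an isoform ending exactly at a
    donor or acceptor is not a candidate.  The donor and acceptor must
    belong to the same intron of one spliced isoform.
    """
    events: list[IntronTerminatedCandidate] = []
    for gene in a.sorted_genes():
        for spliced in gene.transcripts:
            if len(spliced.exons) < 2:
                continue
            for other in gene.transcripts:
                if other.id == spliced.id or not other.exons:
                    continue
                event = _terminates_within(spliced, other)
                if event is not None:
                    events.append(event)
    return events


def candidate_genes(events: list[IntronTerminatedCandidate]) -> list[str]:
    return sorted({e.gene_id for e in events})


def exclude_boundary_overlaps(
    candidates: list[IntronTerminatedCandidate],
    a: GenomeAnnotation,
    same_strand_only: bool = False,
) -> tuple[list[IntronTerminatedCandidate], int]:
    """Drop candidate genes whose span overlaps any other gene's span.

    With ``same_strand_only`` the overlap test is restricted to genes on the
    same strand; the default drops on any-strand overlap (the strictest
    reading of boundary ambiguity).  Returns the filtered events and the
    number of candidate *genes* excluded.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for gene in a:
        trees[gene.interval.chrom].addi(gene.interval.start, gene.interval.end, gene)

    overlapping: set[str] = set()
    for gid in {e.gene_id for e in candidates}:
        gene = a.genes[gid]
        for hit in trees[gene.interval.chrom].overlap(
            gene.interval.start, gene.interval.end
        ):
            other = hit.data
            if other.id == gid:
                continue
            if same_strand_only and other.strand != gene.strand:
                continue
            overlapping.add(gid)
            break
    kept = [e for e in candidates if e.gene_id not in overlapping]
    return kept, len(overlapping)


def select_two_form(
    candidates: list[IntronTerminatedCandidate],
    a: GenomeAnnotation,
) -> list[IntronTerminatedCandidate]:
    """Keep genes with exactly two annotated transcripts in the pattern.

    A gene qualifies when it has exactly two transcripts and they form a
    spliced/terminated candidate pair; genes with three or more isoforms
    are dropped regardless of pattern.
    """
    kept = []
    for e in candidates:
        gene = a.genes[e.gene_id]
        if len(gene.transcripts) == 2:
            kept.append(e)
    return kept


def build_catalog(
    a: GenomeAnnotation, same_strand_only: bool = False
) -> CatalogReport:
    """Run the full candidate → overlap-filter → two-form funnel."""
    events = find_intron_terminated(a)
    n_candidates = len(candidate_genes(events))
    filtered, n_excluded = exclude_boundary_overlaps(events, a, same_strand_only)
    retained = select_two_form(filtered, a)
    return CatalogReport(
        n_candidates=n_candidates,
        n_excluded_overlap=n_excluded,
        n_two_form=len({e.gene_id for e in retained}),
        retained=retained,
        n_candidate_events=len(events),
    )
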