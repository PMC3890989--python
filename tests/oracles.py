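"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the library's accelerated code paths: nested-gene
search is an all-pairs containment scan, intron-terminated search works on
mirrored coordinates instead of strand-conditional logic, motif scanning
re-checks every position against every motif, and depth is a per-base
pileup dictionary.
"""

from __future__ import annotations

from collections import defaultdict

import pysam


def naive_intron_gaps(exons):
    """Sorted exon gaps computed from scratch on (start, end) tuples."""
    exons = sorted(exons)
    return [
        (exons[i][1], exons[i + 1][0])
        for i in range(len(exons) - 1)
    ]


def brute_force_nested(a):
    """All (host, nested, relation) triples by exhaustive containment."""
    triples = set()
    genes = list(a)
    for host in genes:
        if host.strand not in "+-":
            continue
        introns = set()
        for t in host.transcripts:
            for s, e in naive_intron_gaps([(x.start, x.end) for x in t.exons]):
                introns.add((s, e))
        for s, e in introns:
            for other in genes:
                if other.id == host.id or other.strand not in "+-":
                    continue
                if (
                    other.interval.chrom == host.interval.chrom
                    and other.interval.start > s
                    and other.interval.end < e
                ):
                    rel = (
                        "same_strand"
                        if other.strand == host.strand
                        else "opposite_strand"
                    )
                    triples.add((host.id, other.id, rel))
    return triples


def _mirror(a):
    """Coordinates mirrored around a large constant, strands flipped."""
    M = 1 << 40
    mirrored = {}
    for gene in a:
        txs = []
        for t in gene.transcripts:
            exons = sorted((M - e.end, M - e.start) for e in t.exons)
            txs.append((t.id, (M - t.interval.end, M - t.interval.start), exons))
        mirrored[gene.id] = txs
    return mirrored


def brute_force_intron_terminated(a):
    """(gene, spliced tx, terminated tx) triples by exhaustive pair scan.

    Minus-strand genes are handled by mirroring all coordinates so that
    transcription always runs left-to-right, then applying the plus-strand
    rule — a different mechanism from the implementation's strand
    conditionals.
    """
    results = set()
    for gene in a:
        plus = gene.strand != "-"
        if plus:
            txs = [
                (t.id, (t.interval.start, t.interval.end),
                 sorted((e.start, e.end) for e in t.exons))
                for t in gene.transcripts
            ]
        else:
            M = 1 << 40
            txs = [
                (t.id, (M - t.interval.end, M - t.interval.start),
                 sorted((M - e.end, M - e.start) for e in t.exons))
                for t in gene.transcripts
            ]
        for sid, _sivl, sexons in txs:
            for tid, tivl, texons in txs:
                if sid == tid or not texons:
                    continue
                term = tivl[1]
                last_exon_start = texons[-1][0]
                for d, acc in naive_intron_gaps(sexons):
                    if d < term < acc and last_exon_start < d:
                        results.add((gene.id, sid, tid))
                        break
    return results


def brute_force_scan(seq, table, threshold):
    """All-positions, all-motifs rescan."""
    seq = seq.upper()
    hits = []
    for pos in range(len(seq)):
        for motif, w in table.items():
            if w >= threshold and seq[pos : pos + len(motif)] == motif:
                hits.append((pos, motif, w))
    return sorted(hits)


def pileup_depths(sam_path):
    """Per-base coverage as a {chrom: {pos: depth}} dict from CIGAR walks."""
    depth = defaultdict(lambda: defaultdict(int))
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for read in sam.fetch(until_eof=True):
            if read.is_unmapped or read.cigartuples is None:
                continue
            pos = read.reference_start
            for op, n in read.cigartuples:
                if op in (0, 7, 8):
                    for p in range(pos, pos + n):
                        depth[read.reference_name][p] += 1
                    pos += n
                elif op in (2, 3):
                    pos += n
    return depth
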