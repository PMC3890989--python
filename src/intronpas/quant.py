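"""Read-density quantification of spliced vs intron-terminated isoforms.

Expression is measured as *read density*: mean aligned-read coverage per
base over a genomic region.  For a candidate gene with a spliced isoform S
and an isoform T terminating inside an intron of S:

* the **spliced level** is the mean depth over S's 3'-exon (the last exon
  in transcription direction);
* the **intronic level** is ``max(0, d1 - d2)`` where ``d1`` is the mean
  depth between the donor splice site and T's 3' end, and ``d2`` the mean
  depth between that 3' end and the acceptor — the subtracted term models
  the uniform background of unspliced pre-mRNA that covers the whole
  intron, which would otherwise be mistaken for the terminated isoform;
* the **proportion** of the intron-terminated form is
  ``intronic / (intronic + spliced)``, flagged undefined when both levels
  are zero.

Depth is CIGAR-aware: M/=/X operations contribute coverage, N (spliced
junction) and D consume reference without coverage, so junction reads from
the spliced isoform add nothing to the intron interior.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from intronpas.annotation_io import GenomicInterval
from intronpas.isoform_catalog import IntronTerminatedCandidate

# CIGAR operation codes: 0=M, 7==, 8=X add depth; 2=D, 3=N consume reference
_DEPTH_OPS = frozenset({0, 7, 8})
_REF_SKIP_OPS = frozenset({2, 3})


class DepthIndex:
    """Per-chromosome coverage arrays built from one pass over a SAM file.

    ``mode='base'`` (default) counts each CIGAR-aligned base of each
    alignment record once; ``mode='read'`` counts each record once at every
    reference position it aligns to — the two coincide except in how they
    weight partial overlaps, and both are exposed because coverage
    conventions differ between tools.  Multi-mapped reads count once per
    alignment record (no NH weighting).
    """

    def __init__(self, sam_path: str | Path, mode: str = "base"):
        if mode not in ("base", "read"):
            raise ValueError(f"unknown depth mode {mode!r}")
        self.mode = mode
        self.path = Path(sam_path)
        self.depth: dict[str, np.ndarray] = {}
        self.spans: dict[str, list[tuple[int, int]]] = {}
        with pysam.AlignmentFile(str(self.path), "r", check_sq=False) as sam:
            for ref, length in zip(sam.references, sam.lengths):
                self.depth[ref] = np.zeros(length, dtype=np.float64)
                self.spans[ref] = []
            for read in sam.fetch(until_eof=True):
                if read.is_unmapped or read.cigartuples is None:
                    continue
                arr = self.depth.get(read.reference_name)
                if arr is None:
                    raise KeyError(
                        f"alignment on {read.reference_name!r} absent from SAM header"
                    )
                pos = read.reference_start
                for op, n in read.cigartuples:
                    if op in _DEPTH_OPS:
                        arr[pos : pos + n] += 1.0
                        pos += n
                    elif op in _REF_SKIP_OPS:
                        pos += n
                if mode == "read":
                    self.spans[read.reference_name].append(
                        (read.reference_start, read.reference_end)
                    )

    def region_depth(self, region: GenomicInterval) -> float:
        if region.chrom not in self.depth:
            raise KeyError(f"chromosome {region.chrom!r} absent from SAM header")
        arr = self.depth[region.chrom]
        if region.end > arr.size:
            raise ValueError(
                f"region {region} extends past {region.chrom} length {arr.size}"
            )
        if self.mode == "read":
            n = sum(
                1
                for s, e in self.spans[region.chrom]
                if s < region.end and region.start < e
            )
            return n / region.length
        return float(arr[region.start : region.end].mean())


@dataclass
class RegionDensity:
    interval: GenomicInterval
    mean_depth: float

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be non-negative")


@dataclass
class IsoformPairQuant:
    """Per-gene, per-sample isoform levels in read-density units."""

    gene_id: str
    sample_id: str
    spliced_level: float
    intronic_level: float
    intronic_level_raw: float
    proportion: float | None

    @property
    def defined(self) -> bool:
        return self.proportion is not None


def mean_depth(reads: DepthIndex | str | Path, region: GenomicInterval) -> RegionDensity:
    """Mean per-base coverage depth of aligned reads over a region."""
    if region.length <= 0:
        raise ValueError("region length must be positive")
    if not isinstance(reads, DepthIndex):
        reads = DepthIndex(reads)
    return RegionDensity(interval=region, mean_depth=reads.region_depth(region))


def quantify_candidate(
    c: IntronTerminatedCandidate,
    reads: DepthIndex | str | Path,
    sample_id: str,
    three_prime_exon: GenomicInterval,
) -> IsoformPairQuant:
    """Spliced and intron-terminated levels for one candidate in one sample.

    ``three_prime_exon`` is the spliced isoform's last exon in
    transcription direction.  The intron is split at the termination point
    into a donor-side and an acceptor-side segment; the intronic level is
    the clamped difference of their mean depths (the raw difference is also
    kept so a strongly negative value can flag model violations).
    """
    if not isinstance(reads, DepthIndex):
        reads = DepthIndex(reads)
    chrom, strand = c.intron.chrom, c.intron.strand
    if strand != "-":
        donor_segment = GenomicInterval(chrom, c.donor_site, c.termination_point, strand)
        acceptor_segment = GenomicInterval(chrom, c.termination_point, c.acceptor_site, strand)
    else:
        donor_segment = GenomicInterval(chrom, c.termination_point, c.donor_site, strand)
        acceptor_segment = GenomicInterval(chrom, c.acceptor_site, c.termination_point, strand)

    spliced_level = reads.region_depth(three_prime_exon)
    d_donor = reads.region_depth(donor_segment)
    d_acceptor = reads.region_depth(acceptor_segment)
    raw = d_donor - d_acceptor
    intronic_level = max(0.0, raw)
    total = intronic_level + spliced_level
    proportion = (intronic_level / total) if total > 0 else None
    return IsoformPairQuant(
        gene_id=c.gene_id,
        sample_id=sample_id,
        spliced_level=spliced_level,
        intronic_level=intronic_level,
        intronic_level_raw=raw,
        proportion=proportion,
    )
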