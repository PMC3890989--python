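"""Genome-annotation model and GFF3 I/O.

The in-memory model is a plain gene → transcript → exon hierarchy with
introns derived as the gaps between consecutive exons.  All coordinates are
**0-based, half-open** internally, so ``length == end - start``; conversion
from the 1-based inclusive GFF3 convention happens only at the file
boundary.

Parsing is delegated to :mod:`gffutils`; the feature types that play the
gene / transcript / exon roles are configurable so that both FlyBase-style
and generic GFF3 dialects load with the same code path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gffutils

logger = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-", ".")

#: Default mapping of structural roles to GFF3 feature types.
DEFAULT_FEATURE_CONFIG: dict[str, tuple[str, ...]] = {
    "gene": ("gene",),
    "transcript": ("mRNA", "transcript"),
    "exon": ("exon",),
}


class AnnotationError(ValueError):
    """Raised for structurally invalid annotation input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware genomic interval, 0-based half-open.

    Ordering is lexicographic on (chrom, start, end, strand), which gives
    the deterministic sort used throughout the package.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise AnnotationError("interval chrom must be nonempty")
        if self.start < 0:
            raise AnnotationError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise AnnotationError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise AnnotationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one base (strand-blind)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_strictly(self, other: "GenomicInterval") -> bool:
        """True if *other* lies strictly inside this interval.

        Both boundaries must be strict: an interval sharing a start or end
        coordinate with its container is *not* strictly contained.
        """
        return (
            self.chrom == other.chrom
            and other.start > self.start
            and other.end < self.end
        )

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)


@dataclass
class Transcript:
    """A transcript with its ordered, non-overlapping exons."""

    id: str
    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        prev_end = None
        for exon in self.exons:
            if exon.chrom != self.interval.chrom or exon.strand != self.interval.strand:
                raise AnnotationError(
                    f"transcript {self.id}: exon {exon} not on transcript chrom/strand"
                )
            if exon.start < self.interval.start or exon.end > self.interval.end:
                raise AnnotationError(
                    f"transcript {self.id}: exon {exon} outside transcript interval"
                )
            if prev_end is not None and exon.start < prev_end:
                raise AnnotationError(f"transcript {self.id}: overlapping exons")
            prev_end = exon.end

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    def introns(self) -> list[GenomicInterval]:
        return derive_introns(self)

    def three_prime_end(self) -> int:
        """Position of the transcript 3' end in genomic coordinates.

        On ``+`` this is the half-open ``end``; on ``-`` it is ``start``.
        """
        return self.interval.end if self.strand != "-" else self.interval.start

    def last_exon(self) -> GenomicInterval:
        """The 3'-most exon in transcription direction."""
        if not self.exons:
            raise AnnotationError(f"transcript {self.id} has no exons")
        return self.exons[-1] if self.strand != "-" else self.exons[0]


@dataclass
class Gene:
    id: str
    interval: GenomicInterval
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self) -> None:
        for t in self.transcripts:
            if (
                t.interval.chrom != self.interval.chrom
                or t.interval.start < self.interval.start
                or t.interval.end > self.interval.end
            ):
                raise AnnotationError(
                    f"gene {self.id}: transcript {t.id} outside gene interval"
                )

    @property
    def strand(self) -> str:
        return self.interval.strand

    def introns(self) -> list[GenomicInterval]:
        """Deduplicated union of the introns of all isoforms of this gene."""
        seen: set[GenomicInterval] = set()
        for t in self.transcripts:
            seen.update(derive_introns(t))
        return sorted(seen)


@dataclass
class GenomeAnnotation:
    """A validated collection of genes keyed by id."""

    genes: dict[str, Gene] = field(default_factory=dict)
    source_label: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        tids: set[str] = set()
        for gene in self.genes.values():
            for t in gene.transcripts:
                if t.id in tids:
                    raise AnnotationError(f"duplicate transcript id {t.id}")
                tids.add(t.id)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes.values())

    def transcripts(self) -> Iterator[Transcript]:
        for gene in self:
            yield from gene.transcripts

    def sorted_genes(self) -> list[Gene]:
        return sorted(self.genes.values(), key=lambda g: (g.interval, g.id))


def derive_introns(t: Transcript) -> list[GenomicInterval]:
    """Gaps between consecutive exons of a transcript.

    Returns an empty list for single-exon transcripts.  Intron *i* runs from
    the end of exon *i* to the start of exon *i + 1*; together exons and
    introns tile the transcript interval exactly.
    """
    introns = []
    for left, right in zip(t.exons, t.exons[1:]):
        if right.start <= left.end:
            raise AnnotationError(f"transcript {t.id}: overlapping or abutting exons")
        introns.append(GenomicInterval(t.chrom, left.end, right.start, t.strand))
    return introns


def unique_introns(a: GenomeAnnotation) -> list[GenomicInterval]:
    """Genome-wide intron set, deduplicated by (chrom, start, end, strand).

    Isoforms frequently share introns; an intron borne by several
    transcripts appears once.  The result is sorted (chrom, start, end,
    strand) for determinism.
    """
    seen: set[GenomicInterval] = set()
    for t in a.transcripts():
        seen.update(derive_introns(t))
    return sorted(seen)


def count_introns_per_transcript(a: GenomeAnnotation) -> int:
    """Total intron count summed over transcripts (no deduplication).

    Provided for comparison with genome releases that report intron numbers
    per annotated transcript rather than as a deduplicated set.
    """
    return sum(len(derive_introns(t)) for t in a.transcripts())


def _resolve_types(feature_config: Mapping[str, Iterable[str]] | None) -> dict[str, tuple[str, ...]]:
    cfg = dict(DEFAULT_FEATURE_CONFIG)
    if feature_config:
        for role, types in feature_config.items():
            if role not in cfg:
                raise AnnotationError(f"unknown feature role {role!r}")
            if isinstance(types, str):
                types = (types,)
            cfg[role] = tuple(types)
    return cfg


def _prevalidate_gff(path: Path) -> None:
    # cheap structural check so malformed lines fail with a line number
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith(">"):
                if line.startswith(">"):
                    break  # embedded FASTA section
                continue
            if line.count("\t") != 8:
                raise AnnotationError(
                    f"{path}: malformed GFF line {lineno}: expected 9 tab-separated columns"
                )


def parse_gff(
    path: str | Path,
    feature_config: Mapping[str, Iterable[str]] | None = None,
    source_label: str | None = None,
) -> GenomeAnnotation:
    """Read a GFF3 file into a validated :class:`GenomeAnnotation`.

    Coordinates are converted from GFF3 1-based inclusive to the internal
    0-based half-open convention.  Exons whose parent transcript is missing
    are skipped with a warning; transcripts without a parent gene get a
    synthesized single-transcript gene.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cfg = _resolve_types(feature_config)
    _prevalidate_gff(path)

    warnings: list[str] = []
    if path.stat().st_size == 0 or not _has_features(path):
        return GenomeAnnotation(
            genes={}, source_label=source_label or path.name, warnings=warnings
        )

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )

    gene_types = set(cfg["gene"])
    tx_types = set(cfg["transcript"])
    exon_types = set(cfg["exon"])

    def as_interval(f: gffutils.Feature) -> GenomicInterval:
        strand = f.strand if f.strand in ("+", "-") else "."
        return GenomicInterval(f.seqid, f.start - 1, f.end, strand)

    # exons grouped by parent transcript id
    exons_by_tx: dict[str, list[GenomicInterval]] = {}
    known_tx_ids = {
        f.id for ft in tx_types for f in db.features_of_type(ft)
    }
    for ft in exon_types:
        for exon in db.features_of_type(ft):
            parents = exon.attributes.get("Parent", [])
            if not parents:
                warnings.append(f"exon at {exon.seqid}:{exon.start} has no Parent; skipped")
                continue
            for pid in parents:
                if pid not in known_tx_ids:
                    warnings.append(
                        f"exon at {exon.seqid}:{exon.start} names unknown parent {pid}; skipped"
                    )
                    continue
                exons_by_tx.setdefault(pid, []).append(as_interval(exon))

    genes: dict[str, Gene] = {}
    gene_features: dict[str, gffutils.Feature] = {}
    tx_by_gene: dict[str, list[Transcript]] = {}

    for ft in gene_types:
        for gf in db.features_of_type(ft):
            gene_features[gf.id] = gf
            tx_by_gene.setdefault(gf.id, [])

    n_synth = 0
    for ft in tx_types:
        for tf in db.features_of_type(ft):
            ivl = as_interval(tf)
            exons = exons_by_tx.get(tf.id, [])
            # strand-normalise exons to the transcript's call
            exons = [
                GenomicInterval(e.chrom, e.start, e.end, ivl.strand) for e in exons
            ]
            parents = [p for p in tf.attributes.get("Parent", []) if p in gene_features]
            if parents:
                gid = parents[0]
            else:
                gid = f"{tf.id}:gene"
                n_synth += 1
                warnings.append(
                    f"transcript {tf.id} has no parent gene; synthesized gene {gid}"
                )
                tx_by_gene.setdefault(gid, [])
            tx_by_gene[gid].append(
                Transcript(id=tf.id, gene_id=gid, interval=ivl, exons=exons)
            )

    for gid, txs in tx_by_gene.items():
        if gid in gene_features:
            ivl = as_interval(gene_features[gid])
        else:
            # synthesized gene spans its single transcript
            ivl = txs[0].interval
        genes[gid] = Gene(id=gid, interval=ivl, transcripts=txs)

    if warnings:
        logger.warning("parse_gff(%s): %d warnings", path, len(warnings))
    return GenomeAnnotation(
        genes=genes, source_label=source_label or path.name, warnings=warnings
    )


def _has_features(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return True
    return False


def write_gff(a: GenomeAnnotation, path: str | Path) -> None:
    """Serialize an annotation back to GFF3 (1-based inclusive on disk)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if a.source_label:
            fh.write(f"#!source-label {a.source_label}\n")
        for gene in a.sorted_genes():
            fh.write(_gff_line(gene.interval, "gene", f"ID={gene.id}"))
            for t in gene.transcripts:
                fh.write(_gff_line(t.interval, "mRNA", f"ID={t.id};Parent={gene.id}"))
                for i, exon in enumerate(t.exons, start=1):
                    fh.write(
                        _gff_line(exon, "exon", f"ID={t.id}.e{i};Parent={t.id}")
                    )


def _gff_line(ivl: GenomicInterval, ftype: str, attrs: str) -> str:
    return (
        f"{ivl.chrom}\tintronpas\t{ftype}\t{ivl.start + 1}\t{ivl.end}\t.\t"
        f"{ivl.strand}\t.\t{attrs}\n"
    )
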