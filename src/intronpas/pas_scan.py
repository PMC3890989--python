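"""Poly(A)-signal scanning of intron sequences.

A polyadenylation signal (PAS) is a short sequence element — canonically
the hexamer AATAAA — that directs cleavage and poly(A) addition at a
transcript's 3' end.  PAS-like hexamers inside introns are normally
silenced by splicing, but where used they truncate the transcript.

This module classifies every intron of an annotation into one of three
categories:

``too_short``
    the intron is below the minimum scannable length (default 120 bp);
``present``
    at least one PAS hexamer at or above the score threshold occurs on the
    intron's sense strand;
``not_found``
    the intron is long enough but carries no qualifying hexamer.

Scoring is a transparent weighted-hexamer lookup: the canonical AATAAA
variant set with fixed weights (configurable via a two-column TSV).  This
deliberately trades the sensitivity of trained PAS predictors for exact
reproducibility; weights and threshold are reported with every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from pyfaidx import Fasta

from intronpas.annotation_io import GenomeAnnotation, GenomicInterval, unique_introns

#: Canonical poly(A) hexamer and its common single-base variants.
DEFAULT_MOTIF_TABLE: dict[str, float] = {
    "AATAAA": 1.0,
    "ATTAAA": 0.9,
    "AGTAAA": 0.5,
    "TATAAA": 0.5,
    "CATAAA": 0.5,
    "GATAAA": 0.5,
    "AATATA": 0.5,
    "AATACA": 0.5,
    "AATAGA": 0.5,
    "AATGAA": 0.5,
    "ACTAAA": 0.5,
    "AAGAAA": 0.5,
}

DEFAULT_SCORE_THRESHOLD = 0.9
DEFAULT_MIN_LENGTH = 120

_VALID_BASES = frozenset("ACGTN")

CATEGORIES = ("present", "not_found", "too_short")


class SequenceError(ValueError):
    """Raised for sequences outside the {A, C, G, T, N} alphabet."""


@dataclass(frozen=True)
class PasHit:
    """One qualifying hexamer occurrence within a scanned sequence."""

    position: int  # 0-based offset of the hexamer start
    motif: str
    score: float

    def __post_init__(self) -> None:
        if self.score <= 0:
            raise ValueError("PasHit score must be positive")


@dataclass
class IntronPasReport:
    """Per-intron classification with the supporting hits."""

    intron: GenomicInterval
    category: str
    hits: list[PasHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def load_motif_table(path: str | Path) -> dict[str, float]:
    """Read a hexamer→weight table from a two-column TSV."""
    table: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            motif, weight = fields[0].upper(), float(fields[1])
            if len(motif) != 6 or set(motif) - set("ACGT"):
                raise ValueError(f"{path}: line {lineno}: {motif!r} is not a DNA hexamer")
            table[motif] = weight
    if not table:
        raise ValueError(f"{path}: empty motif table")
    return table


def scan_sequence(
    seq: str,
    motif_table: Mapping[str, float] | None = None,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> list[PasHit]:
    """Report every hexamer window matching the table at/above threshold.

    Hits are sorted by position.  Windows containing N never match.
    """
    table = dict(motif_table) if motif_table is not None else DEFAULT_MOTIF_TABLE
    if not table:
        raise ValueError("motif_table must be nonempty")
    seq = seq.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise SequenceError(f"invalid characters in sequence: {sorted(bad)}")
    hits = []
    for pos in range(len(seq) - 5):
        window = seq[pos : pos + 6]
        weight = table.get(window)
        if weight is not None and weight >= score_threshold:
            hits.append(PasHit(position=pos, motif=window, score=weight))
    return hits


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def fetch_intron_sequence(genome: Fasta, intron: GenomicInterval) -> str:
    """Sense-strand sequence of an intron from an indexed FASTA."""
    if intron.chrom not in genome:
        raise KeyError(f"chromosome {intron.chrom!r} absent from FASTA")
    seq = str(genome[intron.chrom][intron.start : intron.end]).upper()
    if intron.strand == "-":
        seq = reverse_complement(seq)
    return seq


def categorize_introns(
    a: GenomeAnnotation,
    genome: Fasta | str | Path,
    min_length: int = DEFAULT_MIN_LENGTH,
    motif_table: Mapping[str, float] | None = None,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    introns: Iterable[GenomicInterval] | None = None,
) -> tuple[list[IntronPasReport], dict]:
    """Classify every unique intron of an annotation into three categories.

    Sequence extraction is strand-aware (reverse complement on ``-``): PAS
    function is strand-specific, so scanning happens on the sense strand of
    the transcript carrying the intron.

    Returns the per-intron reports and a summary dict with absolute counts
    and proportions; the three counts always sum to the intron total.
    """
    if not isinstance(genome, Fasta):
        genome = Fasta(str(genome))
    intron_list = list(introns) if introns is not None else unique_introns(a)
    reports: list[IntronPasReport] = []
    for intron in intron_list:
        if intron.length < min_length:
            reports.append(IntronPasReport(intron=intron, category="too_short"))
            continue
        seq = fetch_intron_sequence(genome, intron)
        hits = scan_sequence(seq, motif_table, score_threshold)
        category = "present" if hits else "not_found"
        reports.append(IntronPasReport(intron=intron, category=category, hits=hits))

    counts = {c: 0 for c in CATEGORIES}
    for r in reports:
        counts[r.category] += 1
    total = len(reports)
    summary = {
        "total_introns": total,
        "counts": counts,
        "proportions": {
            c: (counts[c] / total if total else 0.0) for c in CATEGORIES
        },
        "min_length": min_length,
        "score_threshold": score_threshold,
    }
    return reports, summary
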