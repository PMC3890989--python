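"""Synthetic annotation / genome / read bundles with known ground truth.

The generator emulates the statistical structure this pipeline is built
for: a compact genome of multi-isoform gene models in which

* a configurable fraction of genes *host* another gene inside one of their
  introns (on the same or the opposite strand),
* a configurable fraction of genes carry an isoform pair where one isoform
  terminates inside an intron of the other (with planted overlap and
  multi-isoform confounders for the catalogue filters),
* intron lengths follow a short/long mixture so a realistic share of
  introns falls below the scannable minimum, and
* poly(A) hexamers are planted in an exact fraction of the long introns
  while all other intron sequence is scrubbed of scoring hexamers.

Reads are drawn per sample from a known per-gene mixture proportion θ of
the intron-terminated isoform, with spliced junction reads carrying N
CIGAR operations and a uniform low-level "unspliced pre-mRNA" background
across each gene locus.  Planted counts are allocated deterministically
(rounded fractions, not sampled), and all outputs are byte-reproducible
from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from intronpas.annotation_io import (
    Gene,
    GenomeAnnotation,
    GenomicInterval,
    Transcript,
    unique_introns,
    write_gff,
)
from intronpas.pas_scan import (
    DEFAULT_MIN_LENGTH,
    DEFAULT_MOTIF_TABLE,
    reverse_complement,
    scan_sequence,
)

GROUP_PROFILES = ("switching", "no_intronic_form", "no_splicing")


class SimConfigError(ValueError):
    """Raised when a simulation configuration is infeasible."""


@dataclass
class SimConfig:
    """Study conditions for one synthetic bundle.

    Defaults emulate the target genome's architecture: ~55% of introns
    below the 120-bp scannable minimum, poly(A) hexamers planted in 40% of
    long introns, ~44% of nested genes co-directional with their host
    (the genome-wide share among annotated nested genes), and a sample
    panel of 4 cell lines plus 30 developmental stages at 50× depth.
    """

    n_genes: int = 50
    fraction_nested_hosts: float = 0.10
    fraction_same_strand_nested: float = 0.44
    fraction_intron_terminated_genes: float = 0.20
    fraction_candidate_overlap: float = 0.20
    fraction_candidate_multiform: float = 0.20
    short_intron_fraction: float = 0.55
    short_intron_range: tuple[int, int] = (60, 119)
    long_intron_range: tuple[int, int] = (300, 900)
    exon_length_range: tuple[int, int] = (150, 300)
    pas_plant_rate: float = 0.40
    candidate_group_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "switching": 0.4,
            "no_intronic_form": 0.4,
            "no_splicing": 0.2,
        }
    )
    samples: tuple[str, ...] = tuple(
        [f"CL{i}" for i in range(1, 5)] + [f"DS{i:02d}" for i in range(1, 31)]
    )
    depth: float = 50.0
    background_depth: float = 0.25
    read_length: int = 75
    chrom: str = "chrSim"
    intergenic_gap: tuple[int, int] = (200, 500)
    seed: int = 0
    #: explicit per-sample mixture proportion applied to every retained
    #: candidate gene, overriding the group profiles (for dose-response
    #: experiments on the quantifier)
    theta_by_sample: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for name in (
            "fraction_nested_hosts",
            "fraction_same_strand_nested",
            "fraction_intron_terminated_genes",
            "fraction_candidate_overlap",
            "fraction_candidate_multiform",
            "short_intron_fraction",
            "pas_plant_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1], got {v}")
        if self.depth <= 0:
            raise SimConfigError("depth must be positive")
        if self.n_genes < 1:
            raise SimConfigError("n_genes must be >= 1")
        if self.read_length < 20:
            raise SimConfigError("read_length must be >= 20")
        n_special = round(self.fraction_nested_hosts * self.n_genes) + round(
            self.fraction_intron_terminated_genes * self.n_genes
        )
        if n_special > self.n_genes:
            raise SimConfigError("nested + intron-terminated fractions exceed 1")
        if abs(sum(self.candidate_group_fractions.values()) - 1.0) > 1e-9:
            raise SimConfigError("candidate_group_fractions must sum to 1")
        if self.theta_by_sample is not None:
            missing = set(self.samples) - set(self.theta_by_sample)
            if missing:
                raise SimConfigError(f"theta_by_sample missing samples: {sorted(missing)}")
            bad = {s: v for s, v in self.theta_by_sample.items() if not 0 <= v <= 1}
            if bad:
                raise SimConfigError(f"theta_by_sample values outside [0, 1]: {bad}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["samples"] = list(self.samples)
        return d


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a generated bundle."""

    seed: int
    config: dict
    chrom: str
    genome_length: int = 0
    gene_roles: dict[str, str] = field(default_factory=dict)
    nested_pairs: list[dict] = field(default_factory=list)
    candidates: dict[str, dict] = field(default_factory=dict)
    planted_pas: list[list] = field(default_factory=list)
    n_long_introns: int = 0
    n_short_introns: int = 0
    n_unique_introns: int = 0
    samples: list[str] = field(default_factory=list)

    @property
    def n_hosts(self) -> int:
        return sum(1 for r in self.gene_roles.values() if r == "host")

    def retained_candidates(self) -> dict[str, dict]:
        return {g: c for g, c in self.candidates.items() if c["retained"]}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _alloc(fraction: float, n: int) -> int:
    return int(round(fraction * n))


def _switching_theta(i: int, n: int) -> float:
    # monotone developmental ramp from 0.1 to 0.8
    return 0.1 + 0.7 * (i / max(n - 1, 1))


def simulate_annotation(cfg: SimConfig) -> tuple[GenomeAnnotation, SyntheticTruth]:
    """Build the gene models and the structural part of the ground truth.

    Counts of hosts, candidate genes and their confounder subtypes are
    deterministic rounded fractions of ``n_genes``; positions, strands and
    length draws come from the seeded generator.  Nested genes and
    overlap-neighbor genes are additional loci on top of ``n_genes``.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    n_hosts = _alloc(cfg.fraction_nested_hosts, cfg.n_genes)
    n_cand = _alloc(cfg.fraction_intron_terminated_genes, cfg.n_genes)
    roles = ["host"] * n_hosts + ["candidate"] * n_cand
    roles += ["plain"] * (cfg.n_genes - len(roles))
    rng.shuffle(roles)

    n_same = _alloc(cfg.fraction_same_strand_nested, n_hosts)
    n_overlap = _alloc(cfg.fraction_candidate_overlap, n_cand)
    n_multi = min(_alloc(cfg.fraction_candidate_multiform, n_cand), n_cand - n_overlap)
    n_retained = n_cand - n_overlap - n_multi
    n_sw = _alloc(cfg.candidate_group_fractions.get("switching", 0.0), n_retained)
    n_ni = min(
        _alloc(cfg.candidate_group_fractions.get("no_intronic_form", 0.0), n_retained),
        n_retained - n_sw,
    )
    group_seq = (
        ["switching"] * n_sw
        + ["no_intronic_form"] * n_ni
        + ["no_splicing"] * (n_retained - n_sw - n_ni)
    )

    truth = SyntheticTruth(
        seed=cfg.seed, config=cfg.to_dict(), chrom=cfg.chrom, samples=list(cfg.samples)
    )
    genes: dict[str, Gene] = {}
    cursor = 1000
    host_i = cand_i = ret_i = 0
    n_samples = len(cfg.samples)

    def rint(lo: int, hi: int) -> int:
        return int(rng.integers(lo, hi + 1))

    def exon_len() -> int:
        return rint(*cfg.exon_length_range)

    def intron_len() -> int:
        if rng.random() < cfg.short_intron_fraction:
            return rint(*cfg.short_intron_range)
        return rint(*cfg.long_intron_range)

    def sense_to_genomic(
        g0: int, glen: int, strand: str, a: int, b: int
    ) -> tuple[int, int]:
        if strand == "+":
            return g0 + a, g0 + b
        return g0 + glen - b, g0 + glen - a

    for gi, role in enumerate(roles):
        gid = f"g{gi + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        neighbor_gene: Gene | None = None
        nested_gene: Gene | None = None

        if role == "plain":
            n_exons = rint(1, 4)
            parts: list[tuple[str, int]] = []
            for e in range(n_exons):
                parts.append(("exon", exon_len()))
                if e < n_exons - 1:
                    parts.append(("intron", intron_len()))
            glen = sum(n for _, n in parts)
            exons_sense = []
            off = 0
            for kind, n in parts:
                if kind == "exon":
                    exons_sense.append((off, off + n))
                off += n
            exon_ivls = [
                GenomicInterval(cfg.chrom, *sense_to_genomic(cursor, glen, strand, a, b), strand)
                for a, b in exons_sense
            ]
            gene_ivl = GenomicInterval(cfg.chrom, cursor, cursor + glen, strand)
            txs = [
                Transcript(f"{gid}.t1", gid, gene_ivl, exons=list(exon_ivls))
            ]
            # a second, structurally identical isoform on some genes
            # exercises intron deduplication downstream
            if n_exons >= 2 and rng.random() < 0.4:
                txs.append(
                    Transcript(f"{gid}.t2", gid, gene_ivl, exons=list(exon_ivls))
                )
            genes[gid] = Gene(gid, gene_ivl, txs)

        elif role == "host":
            same_strand = host_i < n_same
            host_i += 1
            e1, e2 = exon_len(), exon_len()
            nested_len = rint(150, 400)
            margin = 40
            ilen = nested_len + 2 * margin
            glen = e1 + ilen + e2
            gene_ivl = GenomicInterval(cfg.chrom, cursor, cursor + glen, strand)
            exons_sense = [(0, e1), (e1 + ilen, glen)]
            exon_ivls = [
                GenomicInterval(cfg.chrom, *sense_to_genomic(cursor, glen, strand, a, b), strand)
                for a, b in exons_sense
            ]
            genes[gid] = Gene(
                gid,
                gene_ivl,
                [Transcript(f"{gid}.t1", gid, gene_ivl, exons=exon_ivls)],
            )
            intron_g = sorted(
                sense_to_genomic(cursor, glen, strand, e1, e1 + ilen)
            )
            nid = f"{gid}n"
            nstrand = strand if same_strand else ("-" if strand == "+" else "+")
            n0 = intron_g[0] + margin
            nested_ivl = GenomicInterval(cfg.chrom, n0, n0 + nested_len, nstrand)
            nested_gene = Gene(
                nid,
                nested_ivl,
                [Transcript(f"{nid}.t1", nid, nested_ivl, exons=[nested_ivl])],
            )
            truth.nested_pairs.append(
                {
                    "host": gid,
                    "nested": nid,
                    "intron": [cfg.chrom, intron_g[0], intron_g[1], strand],
                    "relation": "same_strand" if same_strand else "opposite_strand",
                }
            )

        else:  # candidate
            subtype_idx = cand_i
            cand_i += 1
            has_overlap = subtype_idx < n_overlap
            has_multiform = n_overlap <= subtype_idx < n_overlap + n_multi
            retained = not has_overlap and not has_multiform
            e1, e2 = exon_len(), exon_len()
            ilen = rint(*cfg.long_intron_range)
            term_off = max(120, int(round(0.4 * ilen)))
            glen = e1 + ilen + e2
            gene_ivl = GenomicInterval(cfg.chrom, cursor, cursor + glen, strand)
            exons_sense = [(0, e1), (e1 + ilen, glen)]
            exon_ivls = [
                GenomicInterval(cfg.chrom, *sense_to_genomic(cursor, glen, strand, a, b), strand)
                for a, b in exons_sense
            ]
            spliced = Transcript(f"{gid}.t1", gid, gene_ivl, exons=exon_ivls)
            t_a, t_b = sense_to_genomic(cursor, glen, strand, 0, e1 + term_off)
            t_ivl = GenomicInterval(cfg.chrom, min(t_a, t_b), max(t_a, t_b), strand)
            terminated = Transcript(f"{gid}.t2", gid, t_ivl, exons=[t_ivl])
            txs = [spliced, terminated]
            if has_multiform:
                # third isoform: same intron, 3'-exon trimmed by 30 bp
                if strand == "+":
                    ex3 = [
                        exon_ivls[0],
                        GenomicInterval(
                            cfg.chrom, exon_ivls[1].start, exon_ivls[1].end - 30, strand
                        ),
                    ]
                    span3 = GenomicInterval(cfg.chrom, gene_ivl.start, gene_ivl.end - 30, strand)
                else:
                    # genomic-low exon is the 3' exon on the minus strand
                    ex3 = [
                        GenomicInterval(
                            cfg.chrom, exon_ivls[1].start + 30, exon_ivls[1].end, strand
                        ),
                        exon_ivls[0],
                    ]
                    span3 = GenomicInterval(cfg.chrom, gene_ivl.start + 30, gene_ivl.end, strand)
                txs.append(Transcript(f"{gid}.t3", gid, span3, exons=ex3))
            genes[gid] = Gene(gid, gene_ivl, txs)

            ia, ib = sorted(sense_to_genomic(cursor, glen, strand, e1, e1 + ilen))
            donor = ia if strand == "+" else ib
            acceptor = ib if strand == "+" else ia
            term = t_ivl.end if strand == "+" else t_ivl.start
            group = None
            if retained:
                group = group_seq[ret_i]
                ret_i += 1
            if retained and cfg.theta_by_sample is not None:
                theta = {s: float(cfg.theta_by_sample[s]) for s in cfg.samples}
            elif group == "switching":
                theta = {
                    s: round(_switching_theta(i, n_samples), 4)
                    for i, s in enumerate(cfg.samples)
                }
            elif group == "no_intronic_form":
                theta = {s: 0.0 for s in cfg.samples}
            elif group == "no_splicing":
                theta = {s: 1.0 for s in cfg.samples}
            else:
                theta = {s: 0.5 for s in cfg.samples}
            truth.candidates[gid] = {
                "spliced": spliced.id,
                "terminated": terminated.id,
                "donor": int(donor),
                "acceptor": int(acceptor),
                "termination": int(term),
                "intron": [cfg.chrom, int(ia), int(ib), strand],
                "three_prime_exon": [
                    cfg.chrom,
                    int(spliced.last_exon().start),
                    int(spliced.last_exon().end),
                    strand,
                ],
                "overlap_neighbor": bool(has_overlap),
                "multiform": bool(has_multiform),
                "retained": bool(retained),
                "group": group,
                "theta": theta,
            }
            if has_overlap:
                # neighbor gene overlapping the candidate's downstream end
                nb_id = f"{gid}o"
                nb0 = gene_ivl.end - 50
                nb_ivl = GenomicInterval(cfg.chrom, nb0, nb0 + 200, "+")
                neighbor_gene = Gene(
                    nb_id,
                    nb_ivl,
                    [Transcript(f"{nb_id}.t1", nb_id, nb_ivl, exons=[nb_ivl])],
                )

        truth.gene_roles[gid] = role
        cursor = genes[gid].interval.end
        if nested_gene is not None:
            genes[nested_gene.id] = nested_gene
            truth.gene_roles[nested_gene.id] = "nested"
        if neighbor_gene is not None:
            genes[neighbor_gene.id] = neighbor_gene
            truth.gene_roles[neighbor_gene.id] = "neighbor"
            cursor = neighbor_gene.interval.end
        cursor += rint(*cfg.intergenic_gap)

    truth.genome_length = cursor + 1000
    annotation = GenomeAnnotation(
        genes=genes, source_label=f"intronpas-sim seed={cfg.seed}"
    )
    return annotation, truth


def _extract_sense(genome: list[str], ivl: GenomicInterval) -> str:
    seq = "".join(genome[ivl.start : ivl.end])
    return reverse_complement(seq) if ivl.strand == "-" else seq


def _write_sense(genome: list[str], ivl: GenomicInterval, seq: str) -> None:
    if ivl.strand == "-":
        seq = reverse_complement(seq)
    genome[ivl.start : ivl.end] = list(seq)


def _scrub_motifs(genome: list[str], ivl: GenomicInterval, motifs: frozenset[str]) -> None:
    # mutating position 2 of each hexamer kills every motif in the default
    # table; iterate in case a mutation creates a fresh window
    for _ in range(30):
        sense = _extract_sense(genome, ivl)
        hits = [
            p for p in range(len(sense) - 5) if sense[p : p + 6] in motifs
        ]
        if not hits:
            return
        sense_l = list(sense)
        for p in hits:
            sense_l[p + 2] = "C"
        _write_sense(genome, ivl, "".join(sense_l))
    raise RuntimeError(f"could not scrub motifs from intron {ivl}")


def simulate_genome(
    annotation: GenomeAnnotation,
    truth: SyntheticTruth,
    cfg: SimConfig,
    min_length: int = DEFAULT_MIN_LENGTH,
    self_check: bool = True,
) -> dict[str, str]:
    """Random genome sequence with exact PAS planting in long introns.

    Every intron at or above ``min_length`` is scrubbed of scoring
    hexamers, then ``round(pas_plant_rate * n_long)`` of them (chosen by a
    seeded permutation) get one planted AATAAA on their sense strand.
    With ``self_check`` the planted truth is re-verified with the scanner.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    genome = list(rng.choice(list("ACGT"), size=truth.genome_length))
    motifs = frozenset(DEFAULT_MOTIF_TABLE)

    introns = unique_introns(annotation)
    long_introns = [i for i in introns if i.length >= min_length]
    truth.n_unique_introns = len(introns)
    truth.n_long_introns = len(long_introns)
    truth.n_short_introns = len(introns) - len(long_introns)

    for intron in long_introns:
        _scrub_motifs(genome, intron, motifs)

    n_plant = _alloc(cfg.pas_plant_rate, len(long_introns))
    order = rng.permutation(len(long_introns))
    planted = sorted(long_introns[i] for i in order[:n_plant])
    nested_starts = {
        tuple(p["intron"][:3]): annotation.genes[p["nested"]].interval
        for p in truth.nested_pairs
    }
    for intron in planted:
        key = (intron.chrom, intron.start, intron.end)
        if key in nested_starts:
            gpos = intron.start + 10  # inside the margin before the nested gene
        else:
            gpos = intron.start + (intron.length - 6) // 2
        motif = "AATAAA" if intron.strand != "-" else reverse_complement("AATAAA")
        genome[gpos : gpos + 6] = list(motif)
    truth.planted_pas = [
        [i.chrom, int(i.start), int(i.end), i.strand] for i in planted
    ]

    genome_str = "".join(genome)
    if self_check:
        planted_set = {tuple(p) for p in truth.planted_pas}
        for intron in long_introns:
            sense = genome_str[intron.start : intron.end]
            if intron.strand == "-":
                sense = reverse_complement(sense)
            has_hit = bool(scan_sequence(sense))
            expected = (intron.chrom, intron.start, intron.end, intron.strand) in planted_set
            if has_hit != expected:
                raise RuntimeError(f"self-check failed for intron {intron}")
    return {cfg.chrom: genome_str}


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _transcript_blocks(
    t: Transcript, s: int, e: int
) -> list[tuple[int, int]]:
    """Genomic blocks (ascending) for transcript-coordinate slice [s, e)."""
    exons = t.exons if t.strand != "-" else list(reversed(t.exons))
    blocks = []
    c0 = 0
    for exon in exons:
        c1 = c0 + exon.length
        a, b = max(s, c0), min(e, c1)
        if a < b:
            if t.strand != "-":
                blocks.append((exon.start + (a - c0), exon.start + (b - c0)))
            else:
                blocks.append((exon.end - (b - c0), exon.end - (a - c0)))
        c0 = c1
    return sorted(blocks)


def simulate_reads(
    annotation: GenomeAnnotation,
    truth: SyntheticTruth,
    sample_id: str,
    cfg: SimConfig,
    out_path: str | Path,
    genome: dict[str, str] | None = None,
) -> Path:
    """Write one sample's reads as a coordinate-sorted SAM file.

    For candidate genes the isoform of each read is drawn from the sample's
    true θ; all other genes express their first isoform.  Read starts are
    uniform along the transcript with reads truncated at the 3' end, so
    coverage is flat except for a ramp over the first ``read_length``
    bases.  A uniform unspliced pre-mRNA background covers each whole gene
    locus at ``background_depth``.
    """
    if sample_id not in cfg.samples:
        raise SimConfigError(f"unknown sample {sample_id!r}")
    sidx = cfg.samples.index(sample_id)
    rng = np.random.default_rng([cfg.seed, 3, sidx])
    rl = cfg.read_length
    chrom_seq = genome.get(cfg.chrom) if genome else None

    records: list[tuple[int, str, str, list[tuple[int, int]]]] = []
    counter = 0

    def emit(t_like: Transcript, n_reads: int, tag: str) -> None:
        nonlocal counter
        L = sum(e.length for e in t_like.exons)
        if L < 2 or n_reads <= 0:
            return
        starts = rng.integers(0, L - 1, size=n_reads)
        for s in sorted(starts.tolist()):
            e = min(s + rl, L)
            blocks = _transcript_blocks(t_like, s, e)
            if not blocks:
                continue
            counter += 1
            records.append((blocks[0][0], f"{tag}.{counter}", cfg.chrom, blocks))

    for gene in annotation.sorted_genes():
        cand = truth.candidates.get(gene.id)
        tx_by_id = {t.id: t for t in gene.transcripts}
        if cand is not None:
            theta = cand["theta"][sample_id]
            spliced = tx_by_id[cand["spliced"]]
            terminated = tx_by_id[cand["terminated"]]
            for t_like, weight in ((spliced, 1.0 - theta), (terminated, theta)):
                L = sum(e.length for e in t_like.exons)
                lam = cfg.depth * weight * L / rl
                emit(t_like, int(rng.poisson(lam)), f"{gene.id}.{t_like.id.split('.')[-1]}.{sample_id}")
        else:
            t0 = gene.transcripts[0]
            L = sum(e.length for e in t0.exons)
            emit(t0, int(rng.poisson(cfg.depth * L / rl)), f"{gene.id}.m.{sample_id}")
        # unspliced pre-mRNA background across the whole locus
        pre = Transcript(
            f"{gene.id}.pre",
            gene.id,
            gene.interval,
            exons=[gene.interval],
        )
        lam_bg = cfg.background_depth * gene.interval.length / rl
        emit(pre, int(rng.poisson(lam_bg)), f"{gene.id}.bg.{sample_id}")

    records.sort(key=lambda r: (r[0], r[1]))
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": cfg.chrom, "LN": truth.genome_length}],
        "PG": [{"ID": "intronpas-sim", "PN": "intronpas"}],
    }
    out_path = Path(out_path)
    with pysam.AlignmentFile(str(out_path), "w", header=header) as sam:
        for pos, name, chrom, blocks in records:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = name
            a.flag = 0
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = 60
            cigar = []
            prev_end = None
            for bs, be in blocks:
                if prev_end is not None and bs > prev_end:
                    cigar.append((3, bs - prev_end))  # N: spliced junction
                cigar.append((0, be - bs))  # M
                prev_end = be
            a.cigartuples = cigar
            if chrom_seq is not None:
                a.query_sequence = "".join(
                    chrom_seq[bs:be] for bs, be in blocks
                )
            sam.write(a)
    return out_path


def simulate_bundle(
    cfg: SimConfig,
    outdir: str | Path,
    samples: list[str] | None = None,
) -> dict[str, Path]:
    """Generate and write a complete GFF + FASTA + SAM + truth bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation, truth = simulate_annotation(cfg)
    genome = simulate_genome(annotation, truth, cfg)
    paths: dict[str, Path] = {}
    paths["gff"] = outdir / "annotation.gff3"
    write_gff(annotation, paths["gff"])
    paths["fasta"] = outdir / "genome.fa"
    write_fasta(genome, paths["fasta"])
    for sample in samples if samples is not None else cfg.samples:
        p = outdir / f"reads_{sample}.sam"
        simulate_reads(annotation, truth, sample, cfg, p, genome=genome)
        paths[f"sam:{sample}"] = p
    paths["truth"] = outdir / "truth.json"
    truth.to_json(paths["truth"])
    return paths
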