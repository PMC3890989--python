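import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the shared oracles module

from intronpas.synthetic_data import (
    SimConfig,
    simulate_annotation,
    simulate_bundle,
    simulate_genome,
)


SMALL_SAMPLES = ("S1", "S2", "S3")


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(n_genes=30, seed=11, samples=SMALL_SAMPLES)


@pytest.fixture(scope="session")
def small_annotation(small_cfg):
    annotation, truth = simulate_annotation(small_cfg)
    return annotation, truth


@pytest.fixture(scope="session")
def small_bundle(small_cfg, tmp_path_factory):
    """A complete on-disk GFF/FASTA/SAM/truth bundle, generated once."""
    outdir = tmp_path_factory.mktemp("bundle")
    paths = simulate_bundle(small_cfg, outdir)
    return small_cfg, paths


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    annotation, truth = simulate_annotation(small_cfg)
    genome = simulate_genome(annotation, truth, small_cfg)
    return annotation, truth, genome


def make_random_annotations(n: int, n_genes: int = 30, seed0: int = 0):
    """Structured synthetic annotations over a seed range."""
    for s in range(seed0, seed0 + n):
        cfg = SimConfig(n_genes=n_genes, seed=s, samples=("S1",))
        yield simulate_annotation(cfg)


def make_chaotic_annotation(seed: int, n_genes: int = 25, span: int = 20000):
    """Unstructured annotation: random gene placements that may overlap,
    nest or abut by chance — a harsher oracle workload than the planted
    architectures."""
    import numpy as np

    from intronpas.annotation_io import (
        Gene,
        GenomeAnnotation,
        GenomicInterval,
        Transcript,
    )

    rng = np.random.default_rng(seed)
    genes = {}
    for gi in range(n_genes):
        chrom = f"c{int(rng.integers(1, 3))}"
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(0, span))
        n_exons = int(rng.integers(1, 5))
        pos = start
        exons = []
        for e in range(n_exons):
            elen = int(rng.integers(20, 400))
            exons.append(GenomicInterval(chrom, pos, pos + elen, strand))
            pos += elen + int(rng.integers(20, 1500))
        end = exons[-1].end
        ivl = GenomicInterval(chrom, start, end, strand)
        gid = f"x{gi:03d}"
        txs = [Transcript(f"{gid}.t1", gid, ivl, exons=exons)]
        if n_exons >= 2 and rng.random() < 0.5:
            # second isoform truncated at a random point inside the gene
            cut = int(rng.integers(start + 1, end))
            if strand == "+":
                sub = [
                    GenomicInterval(chrom, e.start, min(e.end, cut), strand)
                    for e in exons
                    if e.start < cut
                ]
                if sub:
                    t_ivl = GenomicInterval(chrom, sub[0].start, sub[-1].end, strand)
                    txs.append(Transcript(f"{gid}.t2", gid, t_ivl, exons=sub))
            else:
                sub = [
                    GenomicInterval(chrom, max(e.start, cut), e.end, strand)
                    for e in exons
                    if e.end > cut
                ]
                if sub:
                    t_ivl = GenomicInterval(chrom, sub[0].start, sub[-1].end, strand)
                    txs.append(Transcript(f"{gid}.t2", gid, t_ivl, exons=sub))
        genes[gid] = Gene(gid, ivl, txs)
    return GenomeAnnotation(genes=genes, source_label=f"chaotic-{seed}")
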