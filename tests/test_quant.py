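import numpy as np
import pysam
import pytest

from intronpas.annotation_io import GenomicInterval
from intronpas.isoform_catalog import IntronTerminatedCandidate, build_catalog
from intronpas.quant import DepthIndex, mean_depth, quantify_candidate
from intronpas.synthetic_data import (
    SimConfig,
    simulate_annotation,
    simulate_genome,
    simulate_reads,
)

from oracles import pileup_depths


def _write_sam(path, records, chrom="chrQ", length=5000):
    header = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": chrom, "LN": length}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for i, (pos, cigar) in enumerate(records):
            a = pysam.AlignedSegment(sam.header)
            a.query_name = f"r{i}"
            a.flag = 0
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigarstring = cigar
            sam.write(a)
    return path


class TestMeanDepth:
    def test_tiling_reads_give_unit_depth(self, tmp_path):
        p = _write_sam(tmp_path / "tile.sam",
                       [(i * 100, "100M") for i in range(10)])
        region = GenomicInterval("chrQ", 0, 1000, "+")
        assert mean_depth(p, region).mean_depth == pytest.approx(1.0)

    def test_empty_region_zero(self, tmp_path):
        p = _write_sam(tmp_path / "empty.sam", [(0, "50M")])
        region = GenomicInterval("chrQ", 2000, 3000, "+")
        assert mean_depth(p, region).mean_depth == 0.0

    def test_junction_reads_skip_intron(self, tmp_path):
        # 40M100N40M: the 100 skipped bases get no depth
        p = _write_sam(tmp_path / "junc.sam", [(100, "40M100N40M")] * 5)
        intron = GenomicInterval("chrQ", 140, 240, "+")
        exon_side = GenomicInterval("chrQ", 100, 140, "+")
        assert mean_depth(p, intron).mean_depth == 0.0
        assert mean_depth(p, exon_side).mean_depth == pytest.approx(5.0)

    def test_unknown_chrom_raises(self, tmp_path):
        p = _write_sam(tmp_path / "c.sam", [(0, "50M")])
        with pytest.raises(KeyError):
            mean_depth(p, GenomicInterval("nope", 0, 10, "+"))

    @pytest.mark.parametrize("seed", range(4))
    def test_conservation_against_pileup_oracle(self, tmp_path, seed):
        # mean_depth x region length == total aligned bases inside region
        rng = np.random.default_rng(seed)
        records = []
        for _ in range(200):
            pos = int(rng.integers(0, 4000))
            if rng.random() < 0.3:
                cigar = f"{int(rng.integers(10, 50))}M{int(rng.integers(50, 300))}N{int(rng.integers(10, 50))}M"
            else:
                cigar = f"{int(rng.integers(20, 120))}M"
            records.append((pos, cigar))
        records.sort()
        p = _write_sam(tmp_path / f"rand{seed}.sam", records)
        oracle = pileup_depths(p)["chrQ"]
        index = DepthIndex(p)
        for s, e in [(0, 5000), (100, 400), (2500, 2600), (4900, 5000)]:
            region = GenomicInterval("chrQ", s, e, "+")
            expected_total = sum(oracle.get(pos, 0) for pos in range(s, e))
            got = mean_depth(index, region).mean_depth * region.length
            assert got == pytest.approx(expected_total)

    def test_read_count_mode(self, tmp_path):
        p = _write_sam(tmp_path / "m.sam", [(0, "100M"), (50, "100M")])
        region = GenomicInterval("chrQ", 0, 100, "+")
        assert DepthIndex(p, mode="read").region_depth(region) == pytest.approx(2 / 100)


def _candidate(chrom="chrQ", strand="+"):
    return IntronTerminatedCandidate(
        gene_id="g", spliced_transcript_id="g.t1", terminated_transcript_id="g.t2",
        donor_site=1000 if strand == "+" else 2000,
        acceptor_site=2000 if strand == "+" else 1000,
        termination_point=1400,
        intron=GenomicInterval(chrom, 1000, 2000, strand),
    )


class TestQuantifyCandidate:
    def test_direct_formula(self, tmp_path):
        # depth 10 on donor->termination, 2 on termination->acceptor,
        # 12 on the 3'-exon => intronic 8, spliced 12, proportion 0.4
        records = []
        records += [(1000, "400M")] * 10
        records += [(1400, "600M")] * 2
        records += [(2000, "500M")] * 12
        p = _write_sam(tmp_path / "f.sam", sorted(records))
        exon3 = GenomicInterval("chrQ", 2000, 2500, "+")
        q = quantify_candidate(_candidate(), p, "s", exon3)
        assert q.intronic_level == pytest.approx(8.0)
        assert q.spliced_level == pytest.approx(12.0)
        assert q.proportion == pytest.approx(8 / 20)

    def test_equal_segments_clamp_to_zero(self, tmp_path):
        records = [(1000, "1000M")] * 5 + [(2000, "500M")] * 3
        p = _write_sam(tmp_path / "c.sam", sorted(records))
        exon3 = GenomicInterval("chrQ", 2000, 2500, "+")
        q = quantify_candidate(_candidate(), p, "s", exon3)
        assert q.intronic_level == 0.0
        assert q.proportion == pytest.approx(0.0)

    def test_zero_signal_flagged_undefined(self, tmp_path):
        p = _write_sam(tmp_path / "z.sam", [(4000, "50M")])
        exon3 = GenomicInterval("chrQ", 2000, 2500, "+")
        q = quantify_candidate(_candidate(), p, "s", exon3)
        assert q.proportion is None and not q.defined

    def test_duplicating_reads_preserves_proportion(self, tmp_path):
        records = [(1000, "400M")] * 6 + [(2000, "500M")] * 9
        p1 = _write_sam(tmp_path / "d1.sam", sorted(records))
        p2 = _write_sam(tmp_path / "d2.sam", sorted(records * 2))
        exon3 = GenomicInterval("chrQ", 2000, 2500, "+")
        q1 = quantify_candidate(_candidate(), p1, "s", exon3)
        q2 = quantify_candidate(_candidate(), p2, "s", exon3)
        assert q1.proportion == pytest.approx(q2.proportion)
        assert q2.spliced_level == pytest.approx(2 * q1.spliced_level)


class TestMixtureRecovery:
    def test_theta_recovered_within_tolerance(self, tmp_path):
        # reads simulated at 50x from theta=0.3 must recover 0.3 +/- 0.05
        theta = 0.3
        cfg = SimConfig(
            n_genes=30, seed=23, samples=("S1",),
            theta_by_sample={"S1": theta},
        )
        annotation, truth = simulate_annotation(cfg)
        genome = simulate_genome(annotation, truth, cfg)
        sam = simulate_reads(annotation, truth, "S1", cfg, tmp_path / "r.sam", genome=genome)
        index = DepthIndex(sam)
        rep = build_catalog(annotation)
        props = []
        for event in rep.retained:
            c = truth.candidates[event.gene_id]
            exon3 = GenomicInterval(*c["three_prime_exon"])
            q = quantify_candidate(event, index, "S1", exon3)
            assert q.proportion is not None and 0.0 <= q.proportion <= 1.0
            props.append(q.proportion)
        assert props
        assert abs(float(np.mean(props)) - theta) < 0.05
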