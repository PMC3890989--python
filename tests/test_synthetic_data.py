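import hashlib
import subprocess
from pathlib import Path

import numpy as np
import pysam
import pytest

from intronpas.annotation_io import parse_gff, unique_introns
from intronpas.nested import find_nested
from intronpas.synthetic_data import (
    SimConfig,
    SimConfigError,
    simulate_annotation,
    simulate_bundle,
    simulate_genome,
    simulate_reads,
)

from oracles import pileup_depths


class TestConfig:
    def test_deterministic_allocation_of_hosts(self):
        cfg = SimConfig(n_genes=10, fraction_nested_hosts=0.2, samples=("S1",))
        _, truth = simulate_annotation(cfg)
        assert truth.n_hosts == 2
        assert len(truth.nested_pairs) == 2

    def test_infeasible_fractions_rejected(self):
        with pytest.raises(SimConfigError):
            SimConfig(fraction_nested_hosts=0.8, fraction_intron_terminated_genes=0.5)
        with pytest.raises(SimConfigError):
            SimConfig(pas_plant_rate=1.5)
        with pytest.raises(SimConfigError):
            SimConfig(samples=("S1",), theta_by_sample={"S2": 0.5})

    def test_candidate_subtype_allocation(self):
        cfg = SimConfig(n_genes=50, fraction_intron_terminated_genes=0.2,
                        fraction_candidate_overlap=0.2,
                        fraction_candidate_multiform=0.2, samples=("S1",))
        _, truth = simulate_annotation(cfg)
        cands = truth.candidates
        assert len(cands) == 10
        assert sum(c["overlap_neighbor"] for c in cands.values()) == 2
        assert sum(c["multiform"] for c in cands.values()) == 2
        assert sum(c["retained"] for c in cands.values()) == 6


class TestDeterminism:
    def test_identical_seed_gives_identical_bytes(self, tmp_path):
        def digest(d):
            return {
                f.name: hashlib.sha256(f.read_bytes()).hexdigest()
                for f in sorted(Path(d).iterdir())
            }

        cfg_kwargs = dict(n_genes=15, seed=5, samples=("S1",))
        simulate_bundle(SimConfig(**cfg_kwargs), tmp_path / "a")
        simulate_bundle(SimConfig(**cfg_kwargs), tmp_path / "b")
        assert digest(tmp_path / "a") == digest(tmp_path / "b")

    def test_different_seed_changes_output(self, tmp_path):
        p1 = simulate_bundle(SimConfig(n_genes=15, seed=5, samples=("S1",)), tmp_path / "a")
        p2 = simulate_bundle(SimConfig(n_genes=15, seed=6, samples=("S1",)), tmp_path / "b")
        assert p1["gff"].read_bytes() != p2["gff"].read_bytes()


class TestClosure:
    @pytest.mark.parametrize("seed", range(0, 50, 10))
    def test_nested_pairs_recovered_across_seeds(self, seed):
        cfg = SimConfig(n_genes=25, seed=seed, samples=("S1",))
        annotation, truth = simulate_annotation(cfg)
        got = {(p.host_gene_id, p.nested_gene_id) for p in find_nested(annotation)}
        assert got == {(p["host"], p["nested"]) for p in truth.nested_pairs}

    def test_emitted_files_parse_with_own_readers(self, small_bundle):
        cfg, paths = small_bundle
        annotation = parse_gff(paths["gff"])
        assert len(annotation) >= cfg.n_genes
        assert not annotation.warnings
        with pysam.AlignmentFile(str(paths["sam:S1"]), "r") as sam:
            n = sum(1 for _ in sam.fetch(until_eof=True))
        assert n > 0

    def test_sam_passes_samtools_quickcheck(self, small_bundle):
        _, paths = small_bundle
        res = subprocess.run(
            ["samtools", "quickcheck", "-u", str(paths["sam:S1"])],
            capture_output=True,
        )
        assert res.returncode == 0

    def test_truth_pas_planting_consistent(self, small_genome):
        annotation, truth, _genome = small_genome
        introns = unique_introns(annotation)
        n_long = sum(1 for i in introns if i.length >= 120)
        assert truth.n_long_introns == n_long
        assert len(truth.planted_pas) == round(
            truth.config["pas_plant_rate"] * n_long
        )


class TestReads:
    def test_theta_one_gene_has_no_junction_reads(self, tmp_path):
        cfg = SimConfig(n_genes=20, seed=3, samples=("S1",),
                        theta_by_sample={"S1": 1.0}, background_depth=0.0)
        annotation, truth = simulate_annotation(cfg)
        genome = simulate_genome(annotation, truth, cfg)
        sam = simulate_reads(annotation, truth, "S1", cfg, tmp_path / "t1.sam", genome=genome)
        retained = set(truth.retained_candidates())
        with pysam.AlignmentFile(str(sam), "r") as fh:
            for read in fh.fetch(until_eof=True):
                gid = read.query_name.split(".")[0]
                if gid in retained:
                    assert "N" not in read.cigarstring

    def test_theta_zero_gene_reads_all_spliced(self, tmp_path):
        cfg = SimConfig(n_genes=20, seed=3, samples=("S1",),
                        theta_by_sample={"S1": 0.0}, background_depth=0.0)
        annotation, truth = simulate_annotation(cfg)
        genome = simulate_genome(annotation, truth, cfg)
        sam = simulate_reads(annotation, truth, "S1", cfg, tmp_path / "t0.sam", genome=genome)
        retained = set(truth.retained_candidates())
        with pysam.AlignmentFile(str(sam), "r") as fh:
            names = {
                read.query_name
                for read in fh.fetch(until_eof=True)
                if read.query_name.split(".")[0] in retained
            }
        # read names carry the emitting isoform tag: t2 = terminated form
        assert names
        assert not any(".t2." in n for n in names)
        assert all(".t1." in n for n in names)

    def test_total_aligned_bases_match_expected_depth(self, small_bundle):
        # conservation: aligned bases within a gene's span ~ depth x length
        cfg, paths = small_bundle
        from intronpas.synthetic_data import SyntheticTruth

        truth = SyntheticTruth.from_json(paths["truth"])
        depths = pileup_depths(paths["sam:S1"])[cfg.chrom]
        annotation = parse_gff(paths["gff"])
        # pick a plain single-isoform multi-exon gene
        for gid, role in truth.gene_roles.items():
            if role != "plain":
                continue
            gene = annotation.genes[gid]
            if len(gene.transcripts) != 1 or len(gene.transcripts[0].exons) < 2:
                continue
            exonic = [
                p
                for e in gene.transcripts[0].exons
                for p in range(e.start, e.end)
            ]
            total = sum(depths.get(p, 0) for p in exonic)
            expected = cfg.depth * len(exonic)
            sigma = np.sqrt(expected * cfg.read_length)
            assert abs(total - expected) < 5 * sigma + 0.1 * expected
            break
        else:
            pytest.fail("no plain multi-exon gene in fixture")
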