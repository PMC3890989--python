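# intronpas

Analysis of intronic polyadenylation signals, nested genes and
intron-terminated transcript isoforms in annotated genomes.

Polyadenylation signals (PAS, canonically AATAAA) occur frequently inside
introns but are normally silenced: recognition of the 5' splice site by
U1 snRNP suppresses nearby cleavage/polyadenylation.  When an intronic PAS
*is* used, the transcript is truncated inside the intron and an alternative
3'-exon isoform is produced.  `intronpas` is a toolkit for asking, on any
GFF3 genome annotation with optional genome FASTA and RNA-seq SAM files:

- **How many introns carry a PAS-like hexamer?**  Every intron is
  classified as *PAS present*, *PAS not found*, or *too short* to scan
  (< 120 bp by default), with strand-aware sequence extraction.
- **Which genes are nested inside another gene's intron?**  Strict
  containment of a gene span inside a host intron, classified by strand
  relationship — a nested gene's PAS lies within a host intron by
  construction.
- **Which genes have an isoform terminating inside an intron of a sibling
  isoform?**  Candidates where the terminated isoform's 3' end falls
  strictly between a donor and its acceptor, filtered by gene-overlap
  exclusion and two-isoform selection.
- **How strongly is each isoform expressed per sample?**  From aligned
  reads, the spliced level is the mean read density over the 3'-exon; the
  intron-terminated level is

  `I = max(0, density(donor → termination) − density(termination → acceptor))`

  where the subtracted term removes the uniform unspliced pre-mRNA
  background, and the reported proportion is `p = I / (I + S)`.  Genes are
  then grouped across samples (no intronic form / no splicing / switching)
  and rendered as a three-rows-per-gene heat map.

A fully deterministic synthetic-data generator (annotation + genome +
reads + ground truth) backs every stage with closed-loop tests, so the
whole pipeline is verifiable without any external download.

The intended audience is genome-annotation and RNA-processing researchers
who want reproducible, inspectable counts rather than a black box.

## Worked example

Generate a 30-gene synthetic genome with three RNA-seq samples and run the
stages:

```
$ intronpas simulate --seed 5 --n-genes 30 --samples S1,S2,S3 --outdir sim
wrote 6 files to sim

$ intronpas find-nested --gff sim/annotation.gff3 --out pairs.tsv --summary nested.json
hosts: 3  nested: 3  same-direction: 1

$ intronpas scan-pas --gff sim/annotation.gff3 --fasta sim/genome.fa \
      --out pas.tsv --summary pas.json
introns: 41  present: 11  not_found: 16  too_short: 14

$ intronpas find-intronic-isoforms --gff sim/annotation.gff3 \
      --out cand.tsv --report cat.json
candidates: 6  overlap-excluded: 1  two-form retained: 4

$ intronpas quantify --candidates cand.tsv \
      --sam sim/reads_S1.sam --sam sim/reads_S2.sam --sam sim/reads_S3.sam \
      --out quant.tsv
quantified 4 genes x 3 samples

$ intronpas classify --quant quant.tsv --out groups.tsv --heatmap heatmap.png
no_intronic_form: 2  switching: 2
```

Reading the output: of 41 unique introns, 14 are below the 120-bp scanning
minimum, 11 of the remaining 27 carry a qualifying PAS hexamer; 3 genes
host a nested gene (1 co-directional); 6 genes have an isoform terminating
inside an intron, of which 1 is discarded because its span overlaps a
neighboring gene and 1 more has a third isoform, leaving 4 two-form genes.
Per sample, `quant.tsv` lists the spliced level, the intron-terminated
level and its proportion, e.g.:

```
gene_id  sample_id  spliced_level  intronic_level  proportion
g0009    S1         42.5           4.62            0.098
g0029    S1         48.3           0.0             0.0
```

g0009's proportion rises across S1→S3 (a *switching* gene), while g0029
never expresses the intron-terminated form (*no_intronic_form*).
`intronpas run-all` chains all stages on one annotation and writes a
manifest with checksums, timings and warnings.

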