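"""Run manifests, TSV interchange and summary figures.

Every pipeline stage reads and writes headered TSV files so stages can be
run and inspected independently; the helpers here centralise the column
layouts.  ``RunManifest`` records tool version, configuration snapshot,
input checksums, stage timings and warnings so a finished output directory
is self-describing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from intronpas import __version__
from intronpas.annotation_io import GenomeAnnotation, GenomicInterval
from intronpas.classify import GeneGroup, HeatmapMatrix
from intronpas.isoform_catalog import CatalogReport, IntronTerminatedCandidate
from intronpas.nested import NestedPair, NestedSummary
from intronpas.pas_scan import IntronPasReport
from intronpas.quant import IsoformPairQuant


@dataclass
class RunManifest:
    version: str = __version__
    config: dict = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    timings: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        h = hashlib.sha256()
        with open(p, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
        self.inputs[str(p)] = h.hexdigest()

    def time_stage(self, name: str):
        manifest = self

        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                manifest.timings[name] = round(time.perf_counter() - self.t0, 4)
                return False

        return _Timer()

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------- TSV I/O

def write_pas_reports(reports: list[IntronPasReport], path: str | Path) -> None:
    rows = [
        {
            "chrom": r.intron.chrom,
            "start": r.intron.start,
            "end": r.intron.end,
            "strand": r.intron.strand,
            "length": r.intron.length,
            "category": r.category,
            "n_hits": len(r.hits),
            "hit_positions": ",".join(str(h.position) for h in r.hits),
            "hit_motifs": ",".join(h.motif for h in r.hits),
        }
        for r in reports
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_nested_pairs(pairs: list[NestedPair], path: str | Path) -> None:
    rows = [
        {
            "host_gene": p.host_gene_id,
            "intron_chrom": p.host_intron.chrom,
            "intron_start": p.host_intron.start,
            "intron_end": p.host_intron.end,
            "nested_gene": p.nested_gene_id,
            "relation": p.relation,
        }
        for p in pairs
    ]
    pd.DataFrame(
        rows,
        columns=[
            "host_gene",
            "intron_chrom",
            "intron_start",
            "intron_end",
            "nested_gene",
            "relation",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_candidates(
    events: list[IntronTerminatedCandidate],
    a: GenomeAnnotation,
    path: str | Path,
) -> None:
    rows = []
    for e in events:
        spliced = next(
            t for t in a.genes[e.gene_id].transcripts if t.id == e.spliced_transcript_id
        )
        exon3 = spliced.last_exon()
        rows.append(
            {
                "gene_id": e.gene_id,
                "spliced_transcript": e.spliced_transcript_id,
                "terminated_transcript": e.terminated_transcript_id,
                "chrom": e.intron.chrom,
                "strand": e.intron.strand,
                "donor": e.donor_site,
                "acceptor": e.acceptor_site,
                "termination": e.termination_point,
                "intron_start": e.intron.start,
                "intron_end": e.intron.end,
                "exon3_start": exon3.start,
                "exon3_end": exon3.end,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "spliced_transcript",
            "terminated_transcript",
            "chrom",
            "strand",
            "donor",
            "acceptor",
            "termination",
            "intron_start",
            "intron_end",
            "exon3_start",
            "exon3_end",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_candidates(path: str | Path) -> list[tuple[IntronTerminatedCandidate, GenomicInterval]]:
    """Candidates plus their spliced 3'-exon, as written by write_candidates."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        intron = GenomicInterval(
            row.chrom, int(row.intron_start), int(row.intron_end), row.strand
        )
        cand = IntronTerminatedCandidate(
            gene_id=row.gene_id,
            spliced_transcript_id=row.spliced_transcript,
            terminated_transcript_id=row.terminated_transcript,
            donor_site=int(row.donor),
            acceptor_site=int(row.acceptor),
            termination_point=int(row.termination),
            intron=intron,
        )
        exon3 = GenomicInterval(
            row.chrom, int(row.exon3_start), int(row.exon3_end), row.strand
        )
        out.append((cand, exon3))
    return out


def write_quants(quants: list[IsoformPairQuant], path: str | Path) -> None:
    rows = [
        {
            "gene_id": q.gene_id,
            "sample_id": q.sample_id,
            "spliced_level": q.spliced_level,
            "intronic_level": q.intronic_level,
            "intronic_level_raw": q.intronic_level_raw,
            "proportion": "" if q.proportion is None else q.proportion,
        }
        for q in quants
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_quants(path: str | Path) -> list[IsoformPairQuant]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        prop = row.proportion
        prop = None if pd.isna(prop) else float(prop)
        out.append(
            IsoformPairQuant(
                gene_id=row.gene_id,
                sample_id=str(row.sample_id),
                spliced_level=float(row.spliced_level),
                intronic_level=float(row.intronic_level),
                intronic_level_raw=float(row.intronic_level_raw),
                proportion=prop,
            )
        )
    return out


def write_groups(groups: list[GeneGroup], path: str | Path) -> None:
    rows = [{"gene_id": g.gene_id, "group": g.group} for g in groups]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def catalog_report_dict(rep: CatalogReport) -> dict:
    return {
        "n_candidate_genes": rep.n_candidates,
        "n_candidate_events": rep.n_candidate_events,
        "n_excluded_overlap": rep.n_excluded_overlap,
        "n_two_form": rep.n_two_form,
    }


def nested_summary_dict(s: NestedSummary) -> dict:
    return {
        "n_host_genes": s.n_host_genes,
        "n_nested_genes": s.n_nested_genes,
        "n_same_direction": s.n_same_direction,
        "host_strand_groups": s.host_strand_groups,
        "affected_gene_fraction": s.affected_gene_fraction,
        "total_genes": s.total_genes,
    }


# ----------------------------------------------------------------- figures

def plot_pas_pie(summary: dict, path: str | Path) -> None:
    """Pie of intron PAS categories (present / not found / too short)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts = summary["counts"]
    labels = ["PAS present", "PAS not found", "too short (<%d bp)" % summary["min_length"]]
    values = [counts["present"], counts["not_found"], counts["too_short"]]
    fig, ax = plt.subplots(figsize=(4, 4))
    if sum(values):
        ax.pie(values, labels=labels, autopct="%1.1f%%", startangle=90)
    ax.set_title("Intron poly(A)-signal categories")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_nested_pie(summary: NestedSummary, path: str | Path) -> None:
    """Pie of host genes by the strand composition of their nested genes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = summary.host_strand_groups
    fig, ax = plt.subplots(figsize=(4, 4))
    values = [groups[k] for k in ("all_same", "all_opposite", "mixed")]
    if sum(values):
        ax.pie(
            values,
            labels=["all same strand", "all opposite strand", "mixed"],
            autopct="%1.1f%%",
            startangle=90,
        )
    ax.set_title(
        f"{summary.n_host_genes} host genes / {summary.n_nested_genes} nested genes"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
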