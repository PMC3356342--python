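"""Evaluation of a pipeline run against the generator's ground truth.

Only meaningful for runs whose inputs came from :mod:`synthetic_data`
(the truth tables must be present in the run directory).  The recall
definitions:

* antisense recall — planted antisense genes that are present in the
  merged annotation AND flagged with the sense/antisense inversion in the
  antisense report, over planted genes present in the annotation (a gene
  missed by both predictors has no annotation to be antisense to);
* false antisense — genes with an antisense-classified contig that were
  not planted, as a fraction of all annotated genes;
* frameshift recall — planted split genes recovered as interrupted-ORF
  pairs, over planted split genes whose fragments carry homology evidence
  (the detector is defined on shared best homologs, so homolog-less genes
  are invisible to it by construction).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .core_model import PipelineConfig, read_fasta, read_gff3, revcomp
from . import tag_mapper


def end_to_end_metrics(outdir: str | Path) -> dict:
    """Score one synthetic run directory; returns a flat metrics dict."""
    outdir = Path(outdir)
    flags = pd.read_csv(outdir / "truth_genes.tsv", sep="\t",
                        keep_default_na=False)
    planted = set(flags.loc[flags.antisense_planted == 1, "gene_id"])
    fs_planted = set(flags.loc[flags.frameshift_planted == 1, "gene_id"])
    homolog = set(flags.loc[flags.homolog != "", "gene_id"])

    merged_ids = {g.gene_id for g in read_gff3(outdir / "genes_merged.gff3")}
    annotated_planted = {g for g in planted if g in merged_ids}

    rep = pd.read_csv(outdir / "antisense_report.tsv", sep="\t")
    flagged = set(rep.loc[rep.inverse_correlation, "gene_id"]) if len(rep) else set()
    with_antisense = set(rep.gene_id) if len(rep) else set()
    # a fragment of a split gene maps back to its source gene id
    src = lambda gid: str(gid).split(".")[0]
    false_antisense = {src(g) for g in with_antisense} - planted

    art = pd.read_csv(outdir / "artifacts.tsv", sep="\t")
    inter = art[art.kind == "interrupted"]
    found_fs = {src(g) for col in ("gene_1", "gene_2") for g in inter[col]}
    fs_detectable = fs_planted & homolog

    book = json.loads((outdir / "bookkeeping.json").read_text())
    cons = json.loads((outdir / "consensus_summary.json").read_text())

    summary = pd.read_csv(outdir / "mapping_summary.tsv", sep="\t")
    disc = pd.read_csv(outdir / "discovery_summary.tsv", sep="\t")

    n_genes = len({src(g) for g in merged_ids})
    return {
        "n_planted_antisense": len(planted),
        "n_annotated_planted": len(annotated_planted),
        "antisense_recalled": len(flagged & annotated_planted),
        "false_antisense_genes": len(false_antisense),
        "n_annotated_genes": n_genes,
        "fs_planted_detectable": len(fs_detectable),
        "fs_recalled": len(found_fs & fs_detectable),
        "common_count": cons["common"],
        "bookkeeping_common": book["common_count"],
        "rrna_filtered": int(summary.rrna_filtered_reads.sum()),
        "uniquely_aligned": int(summary.uniquely_aligned_reads.sum()),
        "total_reads": int(summary.total_reads.sum()),
        "coverage_percent_mean": float(disc.coverage_percent.mean()),
    }


def pool_metrics(per_seed: list[dict]) -> dict:
    """Pool per-seed end-to-end metrics into the headline rates."""
    tot = {k: sum(m[k] for m in per_seed) for k in per_seed[0]
           if not k.endswith("_mean")}
    return {
        "antisense_recall_percent":
            100.0 * tot["antisense_recalled"] / max(tot["n_annotated_planted"], 1),
        "false_antisense_percent":
            100.0 * tot["false_antisense_genes"] / max(tot["n_annotated_genes"], 1),
        "frameshift_recall_percent":
            100.0 * tot["fs_recalled"] / max(tot["fs_planted_detectable"], 1),
        "common_count_discrepancy":
            sum(abs(m["common_count"] - m["bookkeeping_common"])
                for m in per_seed),
        "rrna_filtered_percent":
            100.0 * tot["rrna_filtered"]
            / max(tot["uniquely_aligned"] + tot["rrna_filtered"], 1),
        "n_reads_pooled": tot["total_reads"],
    }


def mapping_origin_recovery(outdir: str | Path, config: PipelineConfig,
                            condition: str = "log",
                            max_reads: int = 5000) -> tuple[int, int]:
    """Re-map error-free simulated reads and count exact origin recovery.

    Returns (recovered, considered); reads whose 5'-half sequence occurs
    more than once genome-wide are excluded, since the unique-mapping
    contract rejects them by design.
    """
    outdir = Path(outdir)
    genome = read_fasta(outdir / "genome.fasta")
    index = tag_mapper.build_index(genome, config.half_len)
    table = pd.read_csv(outdir / f"truth_reads_{condition}.tsv", sep="\t")
    errorfree = {r.read_id: r for r in table.itertuples() if r.n_errors == 0}
    recovered = considered = 0
    for rec in read_fasta(outdir / f"reads_{condition}.fasta"):
        t = errorfree.get(rec.contig_id)
        if t is None:
            continue
        seq = rec.sequence
        half = seq[:25] if t.strand == "+" else revcomp(seq)[25:]
        if len(index.occurrences(half)) != 1:
            continue
        considered += 1
        res = tag_mapper.map_tag(rec.contig_id, seq, index, config)
        if isinstance(res, tag_mapper.Alignment) and \
                (res.contig_id, res.start, res.strand) == \
                (t.contig_id, t.start, t.strand):
            recovered += 1
        if considered >= max_reads:
            break
    return recovered, considered
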