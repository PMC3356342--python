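"""Stage orchestration: each stage reads its inputs from and writes its
outputs to a run directory, so stages can be run individually or end to
end.  All randomness derives from one root seed; a rerun with the same
seed and configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core_model import (
    PipelineConfig,
    PipelineError,
    StrandedCounts,
    genome_dict,
    read_bed,
    read_fasta,
    read_gff3,
    read_hits,
    read_pathways,
    write_contigs_gff3,
    write_fasta,
    write_gff3,
    write_hits,
    write_pathways,
)
from . import expression_quant, gene_consensus, protein_families
from . import synthetic_data as synth
from . import tag_mapper, transcript_discovery

log = logging.getLogger(__name__)

STAGES = ("simulate", "consensus", "families", "map", "quant", "discover")
CONDITIONS = synth.CONDITIONS


def _sub_seed(seed: int, offset: int) -> int:
    return (seed + offset) % (2 ** 31 - 1)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_simulate(outdir: Path, config: PipelineConfig, seed: int,
                 *, n_contigs: int = 1, contig_len_bp: int = 100_000,
                 n_genes: int = 200, depth_mean: float = 20.0,
                 miss_rate: float = 0.08, split_rate: Optional[float] = None,
                 jitter_bp: int = 15, **genome_kwargs) -> dict:
    """Generate the synthetic study and emit every downstream input."""
    outdir.mkdir(parents=True, exist_ok=True)
    truth = synth.make_genome(n_contigs, contig_len_bp, n_genes,
                              seed=_sub_seed(seed, 0), **genome_kwargs)
    synth.write_truth_set(truth, outdir)
    genes_a, genes_b, book = synth.corrupt_predictions(
        truth, miss_rate=miss_rate, split_rate=split_rate,
        jitter_bp=jitter_bp, seed=_sub_seed(seed, 1))
    write_gff3(genes_a, outdir / "predictor_a.gff3")
    write_gff3(genes_b, outdir / "predictor_b.gff3")
    models = {}
    for m in genes_a + genes_b:
        models.setdefault(m.gene_id, m)
    hits = synth.simulate_hits(truth, list(models.values()),
                               seed=_sub_seed(seed, 2))
    write_hits(hits, outdir / "hits.tsv")
    lengths = {}
    for h in hits:
        if h.query_length:
            lengths[h.query_id] = h.query_length
        if h.subject_length:
            lengths[h.subject_id] = h.subject_length
    pd.Series(lengths).sort_index().to_csv(
        outdir / "protein_lengths.tsv", sep="\t", header=False)
    n_reads = {}
    for i, cond in enumerate(CONDITIONS):
        reads, table = synth.simulate_tags(
            truth, cond, depth_mean=depth_mean, seed=_sub_seed(seed, 3 + i))
        write_fasta(reads, outdir / f"reads_{cond}.fasta")
        table.to_csv(outdir / f"truth_reads_{cond}.tsv", sep="\t", index=False)
        n_reads[cond] = len(reads)
    pathways = synth.make_pathways(truth, seed=_sub_seed(seed, 9))
    write_pathways(pathways, outdir / "pathways.tsv")
    book_json = {k: sorted(v) if isinstance(v, set) else v
                 for k, v in book.items() if k != "common_coords"}
    book_json["common_count"] = book["common_count"]
    (outdir / "bookkeeping.json").write_text(
        json.dumps(book_json, indent=1, sort_keys=True, default=str))
    return {"true_genes": len(truth.true_genes),
            "predictor_a": len(genes_a), "predictor_b": len(genes_b),
            "hits": len(hits), **{f"reads_{c}": n for c, n in n_reads.items()}}


def run_consensus(outdir: Path, config: PipelineConfig) -> dict:
    genome = genome_dict(read_fasta(outdir / "genome.fasta"))
    genes_a = read_gff3(outdir / "predictor_a.gff3")
    genes_b = read_gff3(outdir / "predictor_b.gff3")
    hits = read_hits(outdir / "hits.tsv", outdir / "protein_lengths.tsv")
    fa = gene_consensus.filter_candidates(genes_a, genome, config)
    fb = gene_consensus.filter_candidates(genes_b, genome, config)
    merge = gene_consensus.merge_predictions(fa, fb, config, hits)
    merged = merge.merged
    write_gff3(merged, outdir / "genes_merged.gff3")
    report = gene_consensus.detect_frameshift_artifacts(merged, hits, config)
    rows = []
    for kind, pairs in (("interrupted", report.interrupted_pairs),
                        ("overlapping", report.overlapping_pairs)):
        for a, b in pairs:
            rows.append({"kind": kind, "gene_1": a.gene_id, "gene_2": b.gene_id,
                         "subject": a.best_homolog[0]})
    pd.DataFrame(rows, columns=["kind", "gene_1", "gene_2", "subject"]).to_csv(
        outdir / "artifacts.tsv", sep="\t", index=False)
    usage = gene_consensus.codon_usage(
        [g for g in merged if g.length % 3 == 0], genome)
    usage.to_csv(outdir / "codon_usage.tsv", sep="\t")
    (outdir / "consensus_summary.json").write_text(json.dumps({
        "common": len(merge.common), "only_a": len(merge.only_a),
        "only_b": len(merge.only_b), "dropped": len(merge.dropped_overlaps),
        **report.rates,
    }, indent=1, sort_keys=True))
    return {"merged_genes": len(merged), "common": len(merge.common),
            "interrupted_pairs": len(report.interrupted_pairs),
            "overlapping_pairs": len(report.overlapping_pairs)}


def run_families(outdir: Path, config: PipelineConfig) -> dict:
    hits = read_hits(outdir / "hits.tsv", outdir / "protein_lengths.tsv")
    gene_ids = {g.gene_id for g in read_gff3(outdir / "genes_merged.gff3")} \
        if (outdir / "genes_merged.gff3").exists() else None
    own = [h for h in hits
           if not h.subject_id.startswith("SP")
           and (gene_ids is None or
                (h.query_id in gene_ids and h.subject_id in gene_ids))]
    edges = protein_families.qualifying_edges(own, config)
    families = protein_families.triangle_cluster(edges)
    rows = [{"family_id": f.family_id, "species_id": sp, "protein_id": p}
            for f in families for sp, p in sorted(f.members)]
    pd.DataFrame(rows, columns=["family_id", "species_id", "protein_id"]).to_csv(
        outdir / "families.tsv", sep="\t", index=False)
    return {"families": len(families),
            "clustered_proteins": sum(len(f.members) for f in families)}


def run_map(outdir: Path, config: PipelineConfig) -> dict:
    genome = read_fasta(outdir / "genome.fasta")
    genes = read_gff3(outdir / "genes_merged.gff3")
    rrna = read_bed(outdir / "rrna.bed") if (outdir / "rrna.bed").exists() else []
    index = tag_mapper.build_index(genome, config.half_len)
    contig_lengths = {g.contig_id: len(g) for g in genome}
    all_counts = []
    summary_rows = []
    for cond in CONDITIONS:
        reads = [(r.contig_id, r.sequence)
                 for r in read_fasta(outdir / f"reads_{cond}.fasta")]
        alignments, stats = tag_mapper.map_reads(reads, index, config)
        kept, n_rrna = tag_mapper.filter_rrna(alignments, rrna)
        counts, depth, unassigned = tag_mapper.coverage_and_counts(
            kept, genes, contig_lengths, config.read_len)
        counts = counts.rename(columns={"sense": f"sense_{cond}",
                                        "antisense": f"antisense_{cond}"})
        all_counts.append(counts)
        for strand, name in (("+", "plus"), ("-", "minus")):
            tag_mapper.depth_to_bedgraph(
                depth, strand, outdir / f"depth_{cond}_{name}.bedgraph")
        summary_rows.append({
            "sample": cond, "total_reads": stats.total,
            "aligned_reads": stats.aligned,
            "uniquely_aligned_reads": stats.uniquely_aligned,
            "rrna_filtered_reads": n_rrna,
            "unassigned_tags": unassigned,
        })
    wide = pd.concat(all_counts, axis=1)
    long_rows = []
    for cond in CONDITIONS:
        for gid in wide.index:
            long_rows.append({"gene_id": gid, "sample": cond,
                              "sense": int(wide.loc[gid, f"sense_{cond}"]),
                              "antisense": int(wide.loc[gid, f"antisense_{cond}"])})
    pd.DataFrame(long_rows).to_csv(outdir / "counts.tsv", sep="\t", index=False)
    pd.DataFrame(summary_rows).to_csv(outdir / "mapping_summary.tsv",
                                      sep="\t", index=False)
    return {f"uniquely_aligned_{r['sample']}": r["uniquely_aligned_reads"]
            for r in summary_rows}


def load_counts(outdir: Path) -> StrandedCounts:
    df = pd.read_csv(outdir / "counts.tsv", sep="\t")
    sense = df.pivot(index="gene_id", columns="sample", values="sense")
    anti = df.pivot(index="gene_id", columns="sample", values="antisense")
    summary = pd.read_csv(outdir / "mapping_summary.tsv", sep="\t")
    return StrandedCounts(sense, anti, summary)


def run_quant(outdir: Path, config: PipelineConfig) -> dict:
    counts = load_counts(outdir)
    norm = expression_quant.uq_normalize(counts)
    rows = []
    for sample in norm.sense.columns:
        for gid in norm.sense.index:
            for klass, raw_m, norm_m in (("sense", counts.sense, norm.sense),
                                         ("antisense", counts.antisense,
                                          norm.antisense)):
                rows.append({"gene_id": gid, "sample": sample,
                             "strand_class": klass,
                             "raw": int(raw_m.loc[gid, sample]),
                             "uq_value": float(norm_m.loc[gid, sample])})
    pd.DataFrame(rows).to_csv(outdir / "normalized.tsv", sep="\t", index=False)
    hegs = expression_quant.call_heg(norm, config)
    pd.DataFrame(
        [{"sample": s, "gene_id": g} for s in sorted(hegs)
         for g in sorted(hegs[s])]
    ).to_csv(outdir / "heg.tsv", sep="\t", index=False)
    if (outdir / "pathways.tsv").exists():
        pw = read_pathways(outdir / "pathways.tsv")
        expression_quant.pathway_heg_fraction(hegs, pw, config).to_csv(
            outdir / "pathway_heg.tsv", sep="\t", index=False)
    pairs = [(CONDITIONS[1], CONDITIONS[0])]
    expression_quant.fold_changes(norm, counts, pairs).to_csv(
        outdir / "folds.tsv", sep="\t", index=False, float_format="%.6g")
    return {"heg_" + s: len(g) for s, g in hegs.items()}


def load_normalized(outdir: Path):
    from .core_model import NormalizedCounts
    df = pd.read_csv(outdir / "normalized.tsv", sep="\t")
    sense = df[df.strand_class == "sense"].pivot(
        index="gene_id", columns="sample", values="uq_value")
    anti = df[df.strand_class == "antisense"].pivot(
        index="gene_id", columns="sample", values="uq_value")
    uq = None
    return NormalizedCounts(sense, anti, uq)


def run_discover(outdir: Path, config: PipelineConfig) -> dict:
    genome = read_fasta(outdir / "genome.fasta")
    genes = read_gff3(outdir / "genes_merged.gff3")
    contig_lengths = {g.contig_id: len(g) for g in genome}
    norm = load_normalized(outdir)
    contigs_by_phase = {}
    summary_rows = []
    for cond in CONDITIONS:
        plus = tag_mapper.bedgraph_to_depth(
            outdir / f"depth_{cond}_plus.bedgraph", contig_lengths)
        minus = tag_mapper.bedgraph_to_depth(
            outdir / f"depth_{cond}_minus.bedgraph", contig_lengths)
        depth = {c: {"+": plus[c], "-": minus[c]} for c in contig_lengths}
        contigs = transcript_discovery.expressed_contigs(depth, config)
        contigs, klass_counts = transcript_discovery.classify_contigs(
            contigs, genes)
        write_contigs_gff3(contigs, outdir / f"contigs_{cond}.gff3")
        contigs_by_phase[cond] = contigs
        coverage = transcript_discovery.genome_coverage(depth)
        summary_rows.append({"sample": cond, "contigs": len(contigs),
                             "coverage_percent": round(coverage, 1),
                             **klass_counts})
    pd.DataFrame(summary_rows).to_csv(outdir / "discovery_summary.tsv",
                                      sep="\t", index=False)
    report = transcript_discovery.antisense_report(
        contigs_by_phase, norm, genes, phase_pair=CONDITIONS)
    report.to_csv(outdir / "antisense_report.tsv", sep="\t", index=False,
                  float_format="%.6g")
    return {"antisense_reported_genes": len(report),
            **{f"contigs_{r['sample']}": r["contigs"] for r in summary_rows}}


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

_STAGE_FUNCS: dict[str, Callable] = {
    "consensus": run_consensus,
    "families": run_families,
    "map": run_map,
    "quant": run_quant,
    "discover": run_discover,
}

#: files each non-simulate stage requires before it can run
_STAGE_INPUTS = {
    "consensus": ("genome.fasta", "predictor_a.gff3", "predictor_b.gff3",
                  "hits.tsv"),
    "families": ("hits.tsv", "protein_lengths.tsv"),
    "map": ("genome.fasta", "genes_merged.gff3", "reads_log.fasta",
            "reads_stationary.fasta"),
    "quant": ("counts.tsv", "mapping_summary.tsv"),
    "discover": ("genome.fasta", "genes_merged.gff3", "normalized.tsv",
                 "depth_log_plus.bedgraph"),
}


def run_all(outdir: str | Path, config: PipelineConfig, seed: int,
            stages: Sequence[str] = STAGES, synthetic: bool = True,
            sim_kwargs: Optional[dict] = None) -> dict:
    """Run the requested stages in dependency order and write a manifest.

    Missing inputs are a hard error before any stage runs; a stage
    failure leaves a ``<stage>.partial`` marker and re-raises.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stages: {unknown}")
    ordered = [s for s in STAGES if s in stages]
    will_have = set()
    if "simulate" in ordered and synthetic:
        will_have.update(p for inputs in _STAGE_INPUTS.values() for p in inputs)
        will_have.update(("genes_merged.gff3", "counts.tsv", "normalized.tsv"))
    for stage in ordered:
        if stage == "simulate":
            continue
        for req in _STAGE_INPUTS[stage]:
            produced_earlier = req in will_have
            if not produced_earlier and not (outdir / req).exists():
                raise PipelineError(
                    f"stage {stage!r}: missing input {outdir / req}")
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": config.to_dict(),
        "stages": {},
    }
    manifest["config_sha256"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()).hexdigest()
    for stage in ordered:
        t0 = time.monotonic()
        marker = outdir / f"{stage}.partial"
        marker.write_text("")
        try:
            if stage == "simulate":
                info = run_simulate(outdir, config, seed, **(sim_kwargs or {}))
            else:
                info = _STAGE_FUNCS[stage](outdir, config)
        except Exception:
            log.error("stage %s failed; partial outputs retained", stage)
            raise
        marker.unlink()
        manifest["stages"][stage] = info
        log.info("stage %s done in %.1fs", stage, time.monotonic() - t0)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
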