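"""Synthetic study generator.

Builds a small intronless yeast-like genome with annotated genes on both
strands, then derives every input the downstream stages consume:

* two noisy gene-predictor outputs (missed genes, boundary jitter, and
  genes split in two by planted homopolymer indels — the classic
  pyrosequencing frame-shift artifact);
* a similarity-hit table against a fictitious reference proteome plus
  mutual hits inside planted paralog families;
* two-condition (log / stationary phase) strand-specific 50-bp tag
  samples, where a subset of genes carries antisense transcription in the
  stationary phase only (the ADH1-style inversion pattern), a configurable
  fraction of reads carries substitution errors, and a configurable
  fraction originates from designated rRNA loci.

Everything is deterministic under a fixed seed.  Expression follows a
per-gene Poisson model with log-normal means across genes (sigma 1.7 by
default, which puts roughly the top 2% of genes above ten times the
upper-quartile — the HEG regime).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core_model import (
    GeneModel,
    GenomeSequence,
    PipelineError,
    SimilarityHit,
    from_slice,
    gc_fraction,
    genome_dict,
    revcomp,
    to_slice,
    write_bed,
    write_fasta,
    write_gff3,
    write_hits,
    write_pathways,
)

CONDITIONS = ("log", "stationary")

STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
ALL_CODONS = ["".join(c) for c in itertools.product(_BASES, repeat=3)]
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]


def default_codon_weights() -> dict[str, float]:
    """Body-codon sampling weights: A/T-ending codons preferred 1.5:1.

    This yields a genome-wide codon bias strong enough for the codon-usage
    tabulator to recover (e.g. TTT over TTC for Phe), loosely emulating the
    AT-leaning third-position preference of the modelled yeast.
    """
    return {c: (1.5 if c[2] in "AT" else 1.0) for c in SENSE_CODONS}


@dataclass
class TruthSet:
    """Ground truth for one synthetic study."""

    genome: list[GenomeSequence]
    true_genes: list[GeneModel]
    antisense_genes: set[str]
    frameshift_genes: set[str]
    #: gene_id -> 1-based genomic position of the deleted homopolymer base
    frameshift_sites: dict[str, int]
    #: per (feature_id, condition, strand_class): expected tags per 1x depth
    expression_profile: pd.DataFrame
    rrna_intervals: list[tuple[str, int, int]]
    intergenic_transcripts: list[GeneModel]
    paralog_families: list[frozenset[str]]
    #: gene_id -> reference-proteome subject id (homolog-bearing genes only)
    homologs: dict[str, str]
    weak_homologs: set[str]
    codon_probs: dict[str, float]
    seed: int

    def gene_by_id(self, gene_id: str) -> GeneModel:
        return next(g for g in self.true_genes if g.gene_id == gene_id)


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def _random_noncoding(rng: np.random.Generator, n: int, p_gc: float) -> str:
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))


def _make_cds(rng: np.random.Generator, n_codons: int,
              codons: Sequence[str], probs: np.ndarray,
              force_homopolymer: bool) -> str:
    """ATG + body codons (no in-frame stop) + one stop codon."""
    body = list(rng.choice(codons, size=n_codons - 2, p=probs))
    if force_homopolymer and len(body) >= 4:
        mid = len(body) // 2
        body[mid] = "AAA"
        body[mid + 1] = "AAA"
    stop = STOP_CODONS[rng.integers(0, 3)]
    return "ATG" + "".join(body) + stop


def make_genome(
    n_contigs: int = 1,
    contig_len_bp: int = 100_000,
    n_genes: int = 200,
    seed: int = 0,
    *,
    antisense_fraction: float = 0.10,
    frameshift_rate: float = 0.10,
    gc_target: float = 0.45,
    homolog_fraction: float = 0.55,
    weak_homolog_fraction: float = 0.08,
    n_rrna: int = 2,
    rrna_len: int = 500,
    n_intergenic_transcripts: int = 3,
    intergenic_transcript_len: int = 300,
    min_gap: int = 200,
    gene_codon_range: tuple[int, int] = (60, 120),
    n_paralog_families: int = 8,
    expression_sigma: float = 1.7,
    codon_weights: Optional[Mapping[str, float]] = None,
) -> TruthSet:
    """Generate a toy genome and its complete ground truth.

    Genes are intronless, start with ATG, end with a single stop codon,
    have lengths that are multiples of 3 and at least 180 bp, and are
    separated by at least ``min_gap`` intergenic bases.  Non-coding GC is
    tuned so that whole-genome GC lands at ``gc_target`` (45% by default).
    A ``frameshift_rate`` fraction of genes receives a single-base deletion
    inside a homopolymer run, which breaks the reading frame exactly the
    way pyrosequencing homopolymer under-calls do in real assemblies.
    """
    if contig_len_bp < 10_000:
        raise PipelineError("contig_len_bp must be >= 10000")
    if n_contigs < 1 or n_genes < 1:
        raise PipelineError("n_contigs and n_genes must be positive")
    rng = np.random.default_rng(seed)

    weights = dict(codon_weights) if codon_weights else default_codon_weights()
    codons = sorted(weights)
    probs = np.array([weights[c] for c in codons], dtype=float)
    probs = probs / probs.sum()
    codon_probs = dict(zip(codons, probs))

    lo_c, hi_c = gene_codon_range
    gene_codons = rng.integers(lo_c, hi_c + 1, size=n_genes)
    gene_lens = gene_codons * 3

    # feature roster: genes, rRNA loci, always-on intergenic transcripts
    items: list[tuple[str, str, int]] = []  # (kind, feature_id, length)
    for i in range(n_genes):
        items.append(("gene", f"g{i:04d}", int(gene_lens[i])))
    for i in range(n_rrna):
        items.append(("rrna", f"rrna{i}", rrna_len))
    for i in range(n_intergenic_transcripts):
        items.append(("itx", f"itx{i}", intergenic_transcript_len))
    order = rng.permutation(len(items))
    items = [items[i] for i in order]

    # round-robin assignment to contigs, then feasibility per contig
    per_contig: list[list[tuple[str, str, int]]] = [[] for _ in range(n_contigs)]
    for i, item in enumerate(items):
        per_contig[i % n_contigs].append(item)
    for ci, contig_items in enumerate(per_contig):
        need = sum(ln for _, _, ln in contig_items) + (len(contig_items) + 1) * min_gap
        if need > contig_len_bp:
            raise PipelineError(
                f"infeasible packing on contig {ci}: {len(contig_items)} features "
                f"need {need} bp > contig_len_bp={contig_len_bp}; reduce n_genes "
                f"or gene lengths, or increase contig_len_bp"
            )

    # antisense / frameshift / homolog / family assignment
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    len_by_id = {f"g{i:04d}": int(gene_lens[i]) for i in range(n_genes)}
    n_anti = round(antisense_fraction * n_genes)
    eligible = [g for g in gene_ids if len_by_id[g] >= 300]
    if len(eligible) < n_anti:
        raise PipelineError(
            f"infeasible antisense planting: only {len(eligible)} genes are "
            f">=300 bp but antisense_fraction requests {n_anti}"
        )
    antisense_genes = set(rng.choice(eligible, size=n_anti, replace=False)) if n_anti else set()
    n_fs = round(frameshift_rate * n_genes)
    fs_pool = [g for g in gene_ids if g not in antisense_genes]
    if len(fs_pool) < n_fs:
        raise PipelineError("infeasible frameshift planting: not enough genes")
    frameshift_genes = set(rng.choice(fs_pool, size=n_fs, replace=False)) if n_fs else set()

    homologs: dict[str, str] = {}
    weak: set[str] = set()
    for i, g in enumerate(gene_ids):
        if rng.random() < homolog_fraction:
            homologs[g] = f"SP{i:05d}"
            if rng.random() < weak_homolog_fraction:
                weak.add(g)

    family_pool = [g for g in gene_ids
                   if g not in frameshift_genes and g not in antisense_genes]
    rng.shuffle(family_pool)
    paralog_families: list[frozenset[str]] = []
    cursor = 0
    for _ in range(n_paralog_families):
        size = int(rng.integers(3, 6))
        if cursor + size > len(family_pool):
            break
        paralog_families.append(frozenset(family_pool[cursor:cursor + size]))
        cursor += size

    # build coding sequences first so non-coding GC can be tuned afterwards
    cds: dict[str, str] = {}
    for g in gene_ids:
        cds[g] = _make_cds(rng, len_by_id[g] // 3, codons, probs,
                           force_homopolymer=g in frameshift_genes)
    coding_bases = "".join(cds.values())
    coding_len = len(coding_bases)
    coding_gc = gc_fraction(coding_bases) * coding_len
    total_len = n_contigs * contig_len_bp
    noncoding_len = total_len - coding_len
    p_nc = (gc_target * total_len - coding_gc) / max(noncoding_len, 1)
    p_nc = float(np.clip(p_nc, 0.2, 0.8))

    # lay features onto each contig, distributing slack among the gaps
    contigs: list[str] = []
    genes: list[GeneModel] = []
    rrna_intervals: list[tuple[str, int, int]] = []
    intergenic_tx: list[GeneModel] = []
    for ci in range(n_contigs):
        cid = f"chr{ci + 1}"
        contig_items = per_contig[ci]
        m = len(contig_items)
        slack = contig_len_bp - sum(ln for _, _, ln in contig_items) - (m + 1) * min_gap
        extra = rng.multinomial(slack, np.full(m + 1, 1.0 / (m + 1))) if m else [slack]
        parts: list[str] = []
        pos = 0  # 0-based cursor
        for j, (kind, fid, ln) in enumerate(contig_items):
            gap = min_gap + int(extra[j])
            parts.append(_random_noncoding(rng, gap, p_nc))
            pos += gap
            start, end = from_slice(pos, pos + ln)
            if kind == "gene":
                strand = "+" if rng.random() < 0.5 else "-"
                seq = cds[fid] if strand == "+" else revcomp(cds[fid])
                parts.append(seq)
                genes.append(GeneModel(fid, cid, start, end, strand))
            elif kind == "rrna":
                parts.append(_random_noncoding(rng, ln, 0.48))
                rrna_intervals.append((cid, start, end))
            else:  # planted intergenic transcript
                strand = "+" if rng.random() < 0.5 else "-"
                parts.append(_random_noncoding(rng, ln, p_nc))
                intergenic_tx.append(GeneModel(fid, cid, start, end, strand))
            pos += ln
        tail = contig_len_bp - pos - min_gap - int(extra[m]) if m else 0
        parts.append(_random_noncoding(rng, contig_len_bp - pos, p_nc))
        contigs.append("".join(parts))

    # plant the homopolymer single-base deletions (right-to-left per contig)
    frameshift_sites: dict[str, int] = {}
    seq_by_contig = {f"chr{i + 1}": list(contigs[i]) for i in range(n_contigs)}
    fs_genes_sorted = sorted(
        (g for g in genes if g.gene_id in frameshift_genes),
        key=lambda g: (g.contig_id, -g.start),
    )
    shifted: dict[str, list[GeneModel]] = {}
    for g in fs_genes_sorted:
        chars = seq_by_contig[g.contig_id]
        lo, hi = to_slice(g.start, g.end)
        span = "".join(chars[lo:hi])
        m = re.search(r"(A{4,}|C{4,}|G{4,}|T{4,})", span)
        if m is None:  # cannot happen: AAA-AAA codons were forced in
            raise PipelineError(f"no homopolymer in frameshift gene {g.gene_id}")
        del_at = lo + m.start() + len(m.group()) // 2
        del chars[del_at]
        frameshift_sites[g.gene_id] = del_at + 1
        # shift every feature to the right of the deletion on this contig
        for feat_list in (genes, intergenic_tx):
            for f in feat_list:
                if f.contig_id != g.contig_id:
                    continue
                if f.start > del_at + 1:
                    f.start -= 1
                    f.end -= 1
                elif f.end >= del_at + 1:
                    f.end -= 1  # the frameshifted gene itself
        rrna_shift = []
        for (c, s, e) in rrna_intervals:
            if c == g.contig_id and s > del_at + 1:
                rrna_shift.append((c, s - 1, e - 1))
            elif c == g.contig_id and e >= del_at + 1 >= s:
                rrna_shift.append((c, s, e - 1))
            else:
                rrna_shift.append((c, s, e))
        rrna_intervals = rrna_shift
    genome = [GenomeSequence(cid, "".join(chars))
              for cid, chars in seq_by_contig.items()]

    # expression profile: log-normal means across genes, condition factors,
    # and the planted ADH1-style sense/antisense inversion
    mu = -expression_sigma ** 2 / 2
    rows = []
    for g in genes:
        base = rng.lognormal(mu, expression_sigma)
        factors = {c: rng.lognormal(-0.125, 0.5) for c in CONDITIONS}
        per_bp = g.length / 50.0
        if g.gene_id in antisense_genes:
            sense_log = max(base * factors["log"], 0.5)
            sense = {"log": sense_log, "stationary": sense_log / 6.0}
            anti = {"log": 0.0, "stationary": rng.lognormal(0.4, 0.3)}
        else:
            sense = {c: base * factors[c] for c in CONDITIONS}
            anti = {c: 0.0 for c in CONDITIONS}
        for cond in CONDITIONS:
            rows.append((g.gene_id, cond, "sense", sense[cond] * per_bp))
            rows.append((g.gene_id, cond, "antisense", anti[cond] * per_bp))
    for t in intergenic_tx:
        level = rng.lognormal(0.4, 0.3)
        for cond in CONDITIONS:
            rows.append((t.gene_id, cond, "sense", level * t.length / 50.0))
    profile = pd.DataFrame(rows, columns=["feature_id", "condition",
                                          "strand_class", "rate"])

    return TruthSet(
        genome=genome,
        true_genes=genes,
        antisense_genes=set(map(str, antisense_genes)),
        frameshift_genes=set(map(str, frameshift_genes)),
        frameshift_sites=frameshift_sites,
        expression_profile=profile,
        rrna_intervals=rrna_intervals,
        intergenic_transcripts=intergenic_tx,
        paralog_families=paralog_families,
        homologs=homologs,
        weak_homologs=weak,
        codon_probs=codon_probs,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# noisy predictor outputs
# ---------------------------------------------------------------------------

def _split_fragments(g: GeneModel, min_gap: int,
                     rng: np.random.Generator) -> tuple[GeneModel, GeneModel]:
    """Emit a gene as two >=180 bp in-frame fragments separated by a short
    intergenic gap, mimicking an interrupted ORF."""
    ln = g.length
    l1 = max(180, 3 * ((ln // 2) // 3))
    l2 = max(180, 3 * -(-(ln - l1) // 3))
    avail = ln + min_gap - 10 - (l1 + l2)
    if avail < 4:
        raise PipelineError(f"gene {g.gene_id} too short to split")
    gap = int(rng.integers(4, min(60, avail) + 1))
    f1 = GeneModel(f"{g.gene_id}.1", g.contig_id, g.start, g.start + l1 - 1,
                   g.strand)
    s2 = g.start + l1 + gap
    f2 = GeneModel(f"{g.gene_id}.2", g.contig_id, s2, s2 + l2 - 1, g.strand)
    return f1, f2


def corrupt_predictions(
    truth: TruthSet,
    miss_rate: float = 0.08,
    split_rate: Optional[float] = None,
    jitter_bp: int = 15,
    jitter_rate: float = 0.2,
    seed: int = 0,
    min_gap: int = 200,
) -> tuple[list[GeneModel], list[GeneModel], dict]:
    """Derive two noisy predictor gene sets A and B from the truth.

    Genes carrying a planted homopolymer indel are emitted as an
    interrupted two-fragment pair by *both* predictors (the break lives in
    the assembly, so every predictor sees it); ``split_rate``, when given,
    tops the split set up with additional randomly chosen genes.  Each
    predictor independently misses genes at ``miss_rate`` and jitters the
    boundaries of a ``jitter_rate`` subset by up to ``jitter_bp`` (always
    a multiple of 3, preserving frame and the 60-aa minimum).

    Returns (genes_A, genes_B, bookkeeping); bookkeeping records the split
    set, per-predictor misses/jitters, and the exact common-coordinate
    count that consensus merging must reproduce.
    """
    for name, val in (("miss_rate", miss_rate), ("jitter_rate", jitter_rate)):
        if not 0 <= val <= 1:
            raise PipelineError(f"{name} must be in [0,1]")
    if split_rate is not None and not 0 <= split_rate <= 1:
        raise PipelineError("split_rate must be in [0,1]")
    rng = np.random.default_rng(seed)

    split_set = set(truth.frameshift_genes)
    n_target = 0 if split_rate is None else round(split_rate * len(truth.true_genes))
    if n_target > len(split_set):
        extra_pool = [g.gene_id for g in truth.true_genes
                      if g.gene_id not in split_set]
        extra = rng.choice(extra_pool, size=n_target - len(split_set),
                           replace=False)
        split_set |= set(map(str, extra))

    fragments: dict[str, tuple[GeneModel, GeneModel]] = {}
    for g in truth.true_genes:
        if g.gene_id in split_set:
            fragments[g.gene_id] = _split_fragments(g, min_gap, rng)

    book: dict = {"split_genes": set(split_set)}
    out: dict[str, list[GeneModel]] = {}
    for pred in ("A", "B"):
        models: list[GeneModel] = []
        missed: set[str] = set()
        jittered: set[str] = set()
        for g in truth.true_genes:
            if g.gene_id in split_set:
                for f in fragments[g.gene_id]:
                    models.append(GeneModel(f.gene_id, f.contig_id, f.start,
                                            f.end, f.strand,
                                            predictors=frozenset({pred})))
                continue
            if rng.random() < miss_rate:
                missed.add(g.gene_id)
                continue
            start, end = g.start, g.end
            if jitter_bp >= 3 and rng.random() < jitter_rate:
                delta = 3 * int(rng.integers(1, jitter_bp // 3 + 1))
                grow = rng.random() < 0.5
                if rng.random() < 0.5:  # move start
                    start = start - delta if grow else start + delta
                else:
                    end = end + delta if grow else end - delta
                if end - start + 1 >= 180 and start >= 1:
                    jittered.add(g.gene_id)
                else:
                    start, end = g.start, g.end
            models.append(GeneModel(g.gene_id, g.contig_id, start, end,
                                    g.strand, predictors=frozenset({pred})))
        out[pred] = models
        book[f"missed_{pred}"] = missed
        book[f"jittered_{pred}"] = jittered

    coords_a = {m.coords for m in out["A"]}
    coords_b = {m.coords for m in out["B"]}
    book["common_coords"] = coords_a & coords_b
    book["common_count"] = len(book["common_coords"])
    return out["A"], out["B"], book


# ---------------------------------------------------------------------------
# similarity hits against a fictitious reference proteome
# ---------------------------------------------------------------------------

def simulate_hits(truth: TruthSet, genes: Sequence[GeneModel],
                  seed: int = 0) -> list[SimilarityHit]:
    """Similarity hits for a set of (predicted) gene models.

    Every model whose source gene is homolog-bearing hits that gene's own
    reference subject — so the two fragments of a split gene share a
    best homolog while having no mutual hit, exactly the frame-shift
    artifact signature.  Members of planted paralog families additionally
    hit each other strongly.
    """
    rng = np.random.default_rng(seed)
    true_len = {g.gene_id: g.length for g in truth.true_genes}
    hits: list[SimilarityHit] = []
    present: dict[str, list[GeneModel]] = {}
    for m in sorted(genes, key=lambda m: m.gene_id):
        src = m.gene_id.split(".")[0]
        present.setdefault(src, []).append(m)
        subj = truth.homologs.get(src)
        if subj is None:
            continue
        if src in truth.weak_homologs:
            ev = 10.0 ** -rng.uniform(5.2, 9.8)
        else:
            ev = 10.0 ** -rng.uniform(12.0, 80.0)
        aa = m.length // 3
        hits.append(SimilarityHit(m.gene_id, subj, ev, aa, aa,
                                  true_len.get(src, m.length) // 3))
    fam_sorted = sorted(truth.paralog_families, key=sorted)
    for fam in fam_sorted:
        members = sorted(fam)
        for ga, gb in itertools.combinations(members, 2):
            for ma in present.get(ga, []):
                for mb in present.get(gb, []):
                    ev = 10.0 ** -rng.uniform(25.0, 60.0)
                    aa_a, aa_b = ma.length // 3, mb.length // 3
                    hsp = max(1, int(0.8 * min(aa_a, aa_b)))
                    hits.append(SimilarityHit(ma.gene_id, mb.gene_id, ev,
                                              hsp, aa_a, aa_b))
    return hits


# ---------------------------------------------------------------------------
# stranded tag samples
# ---------------------------------------------------------------------------

def simulate_tags(
    truth: TruthSet,
    condition: str,
    depth_mean: float = 20.0,
    seed: int = 0,
    *,
    error_fraction: float = 0.02,
    rrna_fraction: float = 0.02,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Draw stranded 50-bp tags for one growth condition.

    Per-feature read counts are Poisson with mean ``depth_mean`` times the
    feature's profile rate.  Sense reads carry the feature's strand,
    antisense reads the opposite strand; rRNA reads are drawn uniformly
    from the designated rRNA intervals.  A read sequence on the minus
    strand is the reverse complement of the plus-strand reference slice.

    Returns (reads, truth_table) where reads is a list of (read_id, seq)
    and the table records each read's origin and planted error count.
    """
    if condition not in CONDITIONS:
        raise PipelineError(
            f"condition must be one of {CONDITIONS}, got {condition!r}"
        )
    if depth_mean <= 0:
        raise PipelineError("depth_mean must be positive")
    rng = np.random.default_rng(seed)
    genome = genome_dict(truth.genome)
    feats = {g.gene_id: g for g in truth.true_genes}
    feats.update({t.gene_id: t for t in truth.intergenic_transcripts})

    prof = truth.expression_profile
    prof = prof[(prof["condition"] == condition) & (prof["rate"] > 0)]
    prof = prof.sort_values(["feature_id", "strand_class"])

    reads: list[tuple[str, str]] = []
    meta: list[tuple] = []

    def emit(contig_id: str, p0: int, strand: str, origin_class: str,
             origin_id: str) -> None:
        seq = genome[contig_id][p0:p0 + 50]
        if strand == "-":
            seq = revcomp(seq)
        n_err = 0
        if rng.random() < error_fraction:
            n_err = int(rng.integers(1, 4))
            pos = rng.choice(50, size=n_err, replace=False)
            chars = list(seq)
            for p in pos:
                alt = [b for b in "ACGT" if b != chars[p]]
                chars[p] = alt[rng.integers(0, 3)]
            seq = "".join(chars)
        rid = f"{condition}_{len(reads):07d}"
        reads.append((rid, seq))
        meta.append((rid, contig_id, p0 + 1, strand, origin_class,
                     origin_id, n_err))

    expected_total = 0.0
    for row in prof.itertuples(index=False):
        f = feats[row.feature_id]
        mean = depth_mean * row.rate
        expected_total += mean
        n = int(rng.poisson(mean))
        if n == 0:
            continue
        lo, hi = to_slice(f.start, f.end)
        if hi - lo < 50:
            continue
        if row.strand_class == "sense":
            read_strand = f.strand
        else:
            read_strand = "-" if f.strand == "+" else "+"
        origin_class = row.strand_class
        if f.gene_id.startswith("itx"):
            origin_class = "intergenic"
        starts = rng.integers(lo, hi - 49, size=n)
        for p0 in starts:
            emit(f.contig_id, int(p0), read_strand, origin_class, f.gene_id)

    if truth.rrna_intervals and rrna_fraction > 0:
        n_rrna = int(rng.poisson(expected_total * rrna_fraction
                                 / (1 - rrna_fraction)))
        for _ in range(n_rrna):
            idx = int(rng.integers(0, len(truth.rrna_intervals)))
            contig_id, s, e = truth.rrna_intervals[idx]
            lo, hi = to_slice(s, e)
            p0 = int(rng.integers(lo, hi - 49))
            emit(contig_id, p0, "+", "rrna", f"rrna{idx}")

    table = pd.DataFrame(meta, columns=["read_id", "contig_id", "start",
                                        "strand", "origin_class",
                                        "origin_id", "n_errors"])
    return reads, table


# ---------------------------------------------------------------------------
# expression-only simulation (for normalization calibration at scale)
# ---------------------------------------------------------------------------

def simulate_expression_counts(
    n_genes: int = 2000,
    depth: float = 100.0,
    seed: int = 0,
    sigma: float = 1.7,
    conditions: Sequence[str] = CONDITIONS,
) -> pd.DataFrame:
    """Genes x conditions raw sense counts from the Poisson/log-normal
    expression model, without building a genome.  Used to calibrate the
    upper-quartile / HEG machinery at realistic gene numbers."""
    rng = np.random.default_rng(seed)
    mu = -sigma ** 2 / 2
    base = rng.lognormal(mu, sigma, size=n_genes)
    data = {}
    for cond in conditions:
        factors = rng.lognormal(-0.125, 0.5, size=n_genes)
        data[cond] = rng.poisson(depth * base * factors)
    idx = [f"g{i:04d}" for i in range(n_genes)]
    return pd.DataFrame(data, index=pd.Index(idx, name="gene_id"))


def make_pathways(truth: TruthSet, n_pathways: int = 15,
                  member_fraction: float = 0.6, seed: int = 0,
                  ) -> dict[str, set[str]]:
    """Random pathway membership table over the true genes."""
    rng = np.random.default_rng(seed)
    ids = [g.gene_id for g in truth.true_genes]
    n_members = round(member_fraction * len(ids))
    chosen = rng.choice(ids, size=n_members, replace=False)
    out: dict[str, set[str]] = {f"pw{i:02d}": set() for i in range(n_pathways)}
    for g in chosen:
        out[f"pw{int(rng.integers(0, n_pathways)):02d}"].add(str(g))
    return {k: v for k, v in out.items() if v}


# ---------------------------------------------------------------------------
# on-disk emission
# ---------------------------------------------------------------------------

def write_truth_set(truth: TruthSet, outdir: str | Path) -> dict[str, Path]:
    """Emit genome FASTA, truth GFF3, rRNA BED, expression profile and
    per-gene truth flags; returns the mapping of artifact name to path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fasta",
        "truth_gff": outdir / "truth.gff3",
        "rrna_bed": outdir / "rrna.bed",
        "profile": outdir / "expression_profile.tsv",
        "gene_flags": outdir / "truth_genes.tsv",
    }
    write_fasta(truth.genome, paths["genome"])
    write_gff3(truth.true_genes, paths["truth_gff"])
    write_bed(truth.rrna_intervals, paths["rrna_bed"])
    truth.expression_profile.to_csv(paths["profile"], sep="\t", index=False)
    fam_of = {}
    for i, fam in enumerate(truth.paralog_families):
        for g in fam:
            fam_of[g] = f"fam{i:02d}"
    rows = []
    for g in truth.true_genes:
        rows.append({
            "gene_id": g.gene_id,
            "length": g.length,
            "strand": g.strand,
            "antisense_planted": int(g.gene_id in truth.antisense_genes),
            "frameshift_planted": int(g.gene_id in truth.frameshift_genes),
            "paralog_family": fam_of.get(g.gene_id, ""),
            "homolog": truth.homologs.get(g.gene_id, ""),
            "weak_homolog": int(g.gene_id in truth.weak_homologs),
        })
    pd.DataFrame(rows).to_csv(paths["gene_flags"], sep="\t", index=False)
    return paths
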