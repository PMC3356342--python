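"""Two-predictor gene-model consensus, annotation-accuracy classes,
frame-shift artifact detection, and codon-usage tabulation.

The consensus rules mirror the classic two-predictor merge for compact
fungal genomes: a model must span fewer than 10 consecutive assembly Ns
and encode at least 60 amino acids; models identical between the two
predictors (strand, start and end) become *common* genes; remaining
single-predictor models are kept unless they partially overlap a model
from the other predictor with a better annotation-accuracy class.

Frame-shift artifacts are the footprint of pyrosequencing homopolymer
over/under-calls in the assembly: a single real gene annotated as two
same-strand ORFs with the same best homolog, separated by under 600 bp of
intergenic sequence (interrupted) or overlapping each other, without a
genuine orthologous relationship between the two ORFs.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio.Data import CodonTable

from .core_model import (
    ACCURACY_RANK,
    GeneModel,
    PipelineConfig,
    PipelineError,
    SimilarityHit,
    to_slice,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# candidate filtering
# ---------------------------------------------------------------------------

def filter_candidates(genes: Sequence[GeneModel],
                      genome: Mapping[str, str],
                      config: PipelineConfig) -> list[GeneModel]:
    """Drop models shorter than the 60-aa minimum or spanning a run of 10
    or more consecutive Ns; everything else passes through unchanged."""
    n_run = "N" * config.max_internal_gap_nt
    kept: list[GeneModel] = []
    for g in genes:
        if g.contig_id not in genome:
            raise PipelineError(f"gene {g.gene_id}: unknown contig {g.contig_id}")
        if g.end > len(genome[g.contig_id]):
            raise PipelineError(
                f"gene {g.gene_id}: end {g.end} outside contig "
                f"{g.contig_id} (len {len(genome[g.contig_id])})"
            )
        if g.length < config.min_gene_nt:
            log.info("dropping %s: %d nt < %d-aa minimum", g.gene_id,
                     g.length, config.min_protein_aa)
            continue
        lo, hi = to_slice(g.start, g.end)
        if n_run in genome[g.contig_id][lo:hi]:
            log.info("dropping %s: >=%d consecutive Ns in span", g.gene_id,
                     config.max_internal_gap_nt)
            continue
        kept.append(g)
    return kept


# ---------------------------------------------------------------------------
# accuracy classification
# ---------------------------------------------------------------------------

def index_hits(hits: Iterable[SimilarityHit]) -> dict[str, list[SimilarityHit]]:
    by_query: dict[str, list[SimilarityHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    return by_query


def classify_accuracy(gene: GeneModel,
                      hits_by_query: Mapping[str, Sequence[SimilarityHit]],
                      config: PipelineConfig) -> str:
    """Four-category annotation accuracy.

    conserved           best e-value <= 1e-10
    slightly_conserved  1e-10 < best e-value <= 1e-5
    hypothetical        no qualifying hit, but both predictors agree
    predicted           no qualifying hit, single predictor
    """
    best: Optional[SimilarityHit] = None
    for h in hits_by_query.get(gene.gene_id, ()):
        if best is None or h.evalue < best.evalue:
            best = h
    if best is not None and best.evalue <= config.nonortholog_evalue:
        gene.best_homolog = (best.subject_id, best.evalue)
        if best.evalue <= config.homolog_evalue:
            return "conserved"
        return "slightly_conserved"
    if gene.predictors >= {"A", "B"}:
        return "hypothetical"
    return "predicted"


def annotate_genes(genes: Sequence[GeneModel], hits: Iterable[SimilarityHit],
                   config: PipelineConfig) -> None:
    """Set accuracy_class and best_homolog on every model in place."""
    by_query = index_hits(hits)
    for g in genes:
        g.accuracy_class = classify_accuracy(g, by_query, config)


# ---------------------------------------------------------------------------
# two-predictor merging
# ---------------------------------------------------------------------------

@dataclass
class MergeResult:
    common: list[GeneModel]
    only_a: list[GeneModel]
    only_b: list[GeneModel]
    dropped_overlaps: list[GeneModel] = field(default_factory=list)

    @property
    def merged(self) -> list[GeneModel]:
        out = self.common + self.only_a + self.only_b
        return sorted(out, key=lambda g: (g.contig_id, g.start, g.end, g.strand))


def _overlaps(a: GeneModel, b: GeneModel) -> bool:
    return a.start <= b.end and b.start <= a.end


def _resolution_key(g: GeneModel) -> tuple:
    # higher accuracy class wins; tie -> longer model; tie -> predictor A
    return (ACCURACY_RANK.get(g.accuracy_class or "predicted", 0),
            g.length,
            1 if "A" in g.predictors else 0)


def merge_predictions(genes_a: Sequence[GeneModel],
                      genes_b: Sequence[GeneModel],
                      config: PipelineConfig,
                      hits: Iterable[SimilarityHit] = (),
                      ) -> MergeResult:
    """Merge two predictors' filtered gene sets.

    Models identical in (contig, strand, start, end) are emitted once as
    common genes with both predictor tags.  A single-predictor model that
    partially overlaps a same-strand model from the other predictor is
    resolved by annotation-accuracy class (ties: longer model, then
    predictor A); the loser is dropped.
    """
    by_coords_b = {m.coords: m for m in genes_b}
    common: list[GeneModel] = []
    only_a: list[GeneModel] = []
    matched_b: set[tuple] = set()
    for m in genes_a:
        if m.coords in by_coords_b:
            matched_b.add(m.coords)
            common.append(GeneModel(m.gene_id, m.contig_id, m.start, m.end,
                                    m.strand, predictors=frozenset({"A", "B"})))
        else:
            only_a.append(m)
    only_b = [m for m in genes_b if m.coords not in matched_b]

    by_query = index_hits(hits)
    for g in common + only_a + only_b:
        g.accuracy_class = classify_accuracy(g, by_query, config)

    dropped: list[GeneModel] = []
    losers: set[int] = set()
    by_key: dict[tuple[str, str], tuple[list[GeneModel], list[GeneModel]]] = {}
    for m in only_a:
        by_key.setdefault((m.contig_id, m.strand), ([], []))[0].append(m)
    for m in only_b:
        by_key.setdefault((m.contig_id, m.strand), ([], []))[1].append(m)
    for a_models, b_models in by_key.values():
        for ma in a_models:
            for mb in b_models:
                if not _overlaps(ma, mb):
                    continue
                loser = min((ma, mb), key=_resolution_key)
                losers.add(id(loser))
                dropped.append(loser)
    only_a = [m for m in only_a if id(m) not in losers]
    only_b = [m for m in only_b if id(m) not in losers]
    return MergeResult(common, only_a, only_b, dropped)


# ---------------------------------------------------------------------------
# frame-shift artifact detection
# ---------------------------------------------------------------------------

@dataclass
class FrameshiftReport:
    interrupted_pairs: list[tuple[GeneModel, GeneModel]]
    overlapping_pairs: list[tuple[GeneModel, GeneModel]]
    n_homolog_genes: int

    @property
    def rates(self) -> dict[str, float]:
        inter = {g.gene_id for p in self.interrupted_pairs for g in p}
        over = {g.gene_id for p in self.overlapping_pairs for g in p}
        den = max(self.n_homolog_genes, 1)
        return {
            "interrupted_members": len(inter),
            "overlapping_members": len(over),
            "n_homolog_genes": self.n_homolog_genes,
            "interrupted_rate": len(inter) / den,
            "overlapping_rate": len(over) / den,
        }


def artifact_rate_percent(member_count: int, n_homolog_genes: int) -> float:
    """Percentage of homolog-bearing genes involved in an artifact class,
    rounded to the single decimal at which such rates are reported."""
    return round(100.0 * member_count / n_homolog_genes, 1)


def detect_frameshift_artifacts(genes: Sequence[GeneModel],
                                hits: Iterable[SimilarityHit],
                                config: PipelineConfig) -> FrameshiftReport:
    """Find interrupted and overlapping ORF pairs.

    Interrupted: two same-contig, same-strand genes with the same best
    homolog subject, separated by fewer than 600 intergenic bases (gap
    measured stop-of-upstream to start-of-downstream, exclusive), whose
    mutual e-value exceeds 1e-5 or which have no mutual hit at all.
    Overlapping: same best homolog, same contig and strand, intervals
    intersecting.  The denominator for rates is the number of
    homolog-bearing genes.
    """
    mutual: dict[tuple[str, str], float] = {}
    for h in hits:
        for key in ((h.query_id, h.subject_id), (h.subject_id, h.query_id)):
            if key not in mutual or h.evalue < mutual[key]:
                mutual[key] = h.evalue

    def truly_orthologous(a: GeneModel, b: GeneModel) -> bool:
        ev = mutual.get((a.gene_id, b.gene_id))
        return ev is not None and ev <= config.nonortholog_evalue

    with_hom = [g for g in genes if g.best_homolog is not None]
    groups: dict[tuple[str, str, str], list[GeneModel]] = {}
    for g in with_hom:
        groups.setdefault((g.contig_id, g.strand, g.best_homolog[0]), []).append(g)

    interrupted: list[tuple[GeneModel, GeneModel]] = []
    overlapping: list[tuple[GeneModel, GeneModel]] = []
    for members in groups.values():
        members = sorted(members, key=lambda g: (g.start, g.end))
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                if _overlaps(a, b):
                    overlapping.append((a, b))
                    continue
                gap = b.start - a.end - 1
                if gap < config.interrupted_max_gap_bp and not truly_orthologous(a, b):
                    interrupted.append((a, b))
    return FrameshiftReport(interrupted, overlapping, len(with_hom))


# ---------------------------------------------------------------------------
# codon usage
# ---------------------------------------------------------------------------

_TABLE = CodonTable.unambiguous_dna_by_id[1]


def codon_usage(genes: Sequence[GeneModel],
                genome: Mapping[str, str]) -> pd.DataFrame:
    """Tabulate the 64 codon counts over in-frame gene models and the
    relative synonymous frequency of each codon within its amino acid
    (stop codons grouped under '*').

    Genes whose length is not a multiple of 3 are skipped with a warning.
    """
    counts = {"".join(t): 0 for t in itertools.product("ACGT", repeat=3)}
    for g in genes:
        if g.length % 3:
            warnings.warn(
                f"gene {g.gene_id}: length {g.length} not a multiple of 3; "
                "skipped in codon usage"
            )
            continue
        seq = g.sequence(genome)
        for i in range(0, len(seq), 3):
            codon = seq[i:i + 3]
            if codon in counts:
                counts[codon] += 1
    aa_of = {c: _TABLE.forward_table.get(c, "*") for c in counts}
    aa_totals: dict[str, int] = {}
    for c, n in counts.items():
        aa_totals[aa_of[c]] = aa_totals.get(aa_of[c], 0) + n
    rows = []
    for c in sorted(counts):
        total = aa_totals[aa_of[c]]
        rows.append({
            "codon": c,
            "amino_acid": aa_of[c],
            "count": counts[c],
            "rel_freq": counts[c] / total if total else 0.0,
        })
    return pd.DataFrame(rows).set_index("codon")
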