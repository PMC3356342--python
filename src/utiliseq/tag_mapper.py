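"""Split-read mapping of stranded 50-bp tags, and the coverage/counting
machinery built on the resulting unique alignments.

Mapping contract
----------------
A 50-bp tag is divided into a former (5') and latter (3') 25-bp half.
Placement is decided by the 5' half alone: a candidate locus is any
genome offset (either strand) where the 5' half aligns with at most two
substitutions and no indels, and a tag is accepted only when exactly one
candidate exists genome-wide.  Whether the 3' half also matches
contiguously (zero mismatches) is recorded but not required.

Candidates are found by exact seeding: the 25-bp half is cut into three
seeds (8+9+8 bp), so any alignment with <= 2 mismatches leaves at least
one seed exact and is guaranteed to be enumerated.  Equivalence with an
exhaustive scan of every genome offset is property-tested.

Coordinates: alignments report the leftmost (plus-strand) base of the
50-bp footprint, 1-based.  A minus-strand alignment means the tag
sequence equals the reverse complement of the plus-strand reference
slice; its 5' half therefore sits at the right end of the footprint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core_model import (
    GeneModel,
    GenomeSequence,
    PipelineConfig,
    PipelineError,
    revcomp,
    to_slice,
)

import logging

log = logging.getLogger(__name__)

#: seed cut points of the 25-bp half: 8 + 9 + 8
SEED_SPANS = ((0, 8), (8, 17), (17, 25))


@dataclass(frozen=True)
class Alignment:
    read_id: str
    contig_id: str
    start: int  # 1-based leftmost base of the 50-bp footprint
    strand: str
    mismatches_5prime: int
    three_prime_match: bool


@dataclass(frozen=True)
class Rejection:
    read_id: str
    reason: str  # multi_mapped | unmapped


class GenomeIndex:
    """Exact-position index of all 25-mer placements via three seed maps.

    Contigs shorter than the k-mer are skipped with a warning.  Minus
    strand lookups are done by querying the reverse complement, so the
    index itself only stores plus-strand positions.
    """

    def __init__(self, genome: Sequence[GenomeSequence], k: int = 25):
        self.k = k
        self.contig_ids: list[str] = []
        self.seqs: list[str] = []
        self.arrays: list[np.ndarray] = []
        self.seed_maps: list[dict[str, list[tuple[int, int]]]] = [
            {} for _ in SEED_SPANS
        ]
        for rec in genome:
            if len(rec) < k:
                log.warning("contig %s shorter than k=%d: skipped",
                            rec.contig_id, k)
                continue
            ci = len(self.contig_ids)
            self.contig_ids.append(rec.contig_id)
            self.seqs.append(rec.sequence)
            self.arrays.append(
                np.frombuffer(rec.sequence.encode("ascii"), dtype=np.uint8)
            )
            seq = rec.sequence
            for p in range(len(seq) - k + 1):
                for j, (a, b) in enumerate(SEED_SPANS):
                    self.seed_maps[j].setdefault(
                        seq[p + a:p + b], []
                    ).append((ci, p))

    def lookup_25mer(self, query: str) -> list[tuple[int, int, int]]:
        """All placements (contig_idx, pos, mismatches) of ``query`` on the
        plus strand with <= 2 mismatches."""
        qarr = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
        seen: set[tuple[int, int]] = set()
        out: list[tuple[int, int, int]] = []
        for j, (a, b) in enumerate(SEED_SPANS):
            for ci, p in self.seed_maps[j].get(query[a:b], ()):
                if (ci, p) in seen:
                    continue
                seen.add((ci, p))
                mm = int(np.count_nonzero(
                    self.arrays[ci][p:p + self.k] != qarr))
                if mm <= 2:
                    out.append((ci, p, mm))
        return out

    def occurrences(self, kmer: str) -> list[tuple[str, int, str]]:
        """Exact occurrences of a 25-mer on both strands, minus-strand
        positions reported in plus-strand coordinates with a strand flag."""
        out = []
        a, b = SEED_SPANS[0]
        for ci, p in self.seed_maps[0].get(kmer[a:b], ()):
            if self.seqs[ci][p:p + self.k] == kmer:
                out.append((self.contig_ids[ci], p + 1, "+"))
        rc = revcomp(kmer)
        for ci, p in self.seed_maps[0].get(rc[a:b], ()):
            if self.seqs[ci][p:p + self.k] == rc:
                out.append((self.contig_ids[ci], p + 1, "-"))
        return out


def build_index(genome: Sequence[GenomeSequence], k: int = 25) -> GenomeIndex:
    return GenomeIndex(genome, k)


def map_tag(read_id: str, seq: str, index: GenomeIndex,
            config: PipelineConfig) -> Alignment | Rejection:
    """Map one 50-bp tag; see the module docstring for the contract.

    Candidate placements require the full 50-bp footprint to lie inside a
    contig.  Zero candidates -> unmapped; more than one -> multi_mapped.
    """
    if len(seq) != config.read_len:
        raise PipelineError(
            f"read {read_id}: length {len(seq)} != {config.read_len}"
        )
    half = config.half_len
    candidates: dict[tuple[int, int, str], int] = {}

    # plus strand: 5' half at the left of the footprint
    for ci, p, mm in index.lookup_25mer(seq[:half]):
        if p + config.read_len <= len(index.seqs[ci]):
            candidates[(ci, p, "+")] = mm
    # minus strand: the read matches revcomp of the reference slice; its
    # 5' half corresponds to the right 25 bp of the footprint
    rc = revcomp(seq)
    for ci, q, mm in index.lookup_25mer(rc[half:]):
        p = q - half
        if p >= 0:
            candidates[(ci, p, "-")] = mm

    if not candidates:
        return Rejection(read_id, "unmapped")
    if len(candidates) > 1:
        return Rejection(read_id, "multi_mapped")
    (ci, p, strand), mm = next(iter(candidates.items()))
    if strand == "+":
        three = index.seqs[ci][p + half:p + 2 * half] == seq[half:]
    else:
        three = index.seqs[ci][p:p + half] == rc[:half]
    return Alignment(read_id, index.contig_ids[ci], p + 1, strand, mm, three)


@dataclass
class MappingStats:
    total: int = 0
    aligned: int = 0  # >= 1 candidate locus
    uniquely_aligned: int = 0
    rrna_filtered: int = 0


def map_reads(reads: Iterable[tuple[str, str]], index: GenomeIndex,
              config: PipelineConfig) -> tuple[list[Alignment], MappingStats]:
    stats = MappingStats()
    alignments: list[Alignment] = []
    for rid, seq in reads:
        stats.total += 1
        res = map_tag(rid, seq, index, config)
        if isinstance(res, Alignment):
            stats.aligned += 1
            stats.uniquely_aligned += 1
            alignments.append(res)
        elif res.reason == "multi_mapped":
            stats.aligned += 1
    return alignments, stats


# ---------------------------------------------------------------------------
# rRNA filtering
# ---------------------------------------------------------------------------

def filter_rrna(alignments: Sequence[Alignment],
                rrna_intervals: Sequence[tuple[str, int, int]],
                ) -> tuple[list[Alignment], int]:
    """Remove alignments whose start base falls in an rRNA interval
    (1-based inclusive intervals, as produced by the BED reader)."""
    trees: dict[str, IntervalTree] = {}
    for contig, start, end in rrna_intervals:
        trees.setdefault(contig, IntervalTree())[start:end + 1] = True
    kept = []
    filtered = 0
    for a in alignments:
        tree = trees.get(a.contig_id)
        if tree is not None and tree[a.start]:
            filtered += 1
        else:
            kept.append(a)
    return kept, filtered


# ---------------------------------------------------------------------------
# stranded coverage and per-gene sense/antisense counts
# ---------------------------------------------------------------------------

DepthArrays = dict[str, dict[str, np.ndarray]]


def coverage_and_counts(alignments: Sequence[Alignment],
                        genes: Sequence[GeneModel],
                        contig_lengths: Mapping[str, int],
                        read_len: int = 50,
                        ) -> tuple[pd.DataFrame, DepthArrays, int]:
    """Per-gene sense/antisense tag counts plus per-base stranded depth.

    A tag is assigned to the gene whose span contains the tag's start
    (leftmost footprint base): sense when the alignment strand equals the
    gene strand, antisense otherwise.  When genes on both strands contain
    the start, the same-strand gene takes precedence; ties within a
    strand go to the gene starting first.  Unassigned tags still
    contribute depth.  Totals reconcile: assigned + unassigned equals the
    number of input alignments.
    """
    depth: DepthArrays = {
        c: {"+": np.zeros(n, dtype=np.int32), "-": np.zeros(n, dtype=np.int32)}
        for c, n in contig_lengths.items()
    }
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.contig_id, IntervalTree())[g.start:g.end + 1] = g
    counts = pd.DataFrame(
        0, index=pd.Index([g.gene_id for g in genes], name="gene_id"),
        columns=["sense", "antisense"],
    )
    unassigned = 0
    for a in alignments:
        lo = a.start - 1
        arr = depth[a.contig_id][a.strand]
        arr[lo:lo + read_len] += 1
        tree = trees.get(a.contig_id)
        overlapping = sorted(
            (iv.data for iv in tree[a.start]), key=lambda g: (g.start, g.end)
        ) if tree is not None else []
        same = [g for g in overlapping if g.strand == a.strand]
        opposite = [g for g in overlapping if g.strand != a.strand]
        if same:
            counts.loc[same[0].gene_id, "sense"] += 1
        elif opposite:
            counts.loc[opposite[0].gene_id, "antisense"] += 1
        else:
            unassigned += 1
    return counts, depth, unassigned


def depth_to_bedgraph(depth: DepthArrays, strand: str, path) -> None:
    """Write one strand's per-base depth as a bedGraph-style TSV
    (contig, 0-based start, end, depth), run-length encoded."""
    lines = []
    for contig in sorted(depth):
        arr = depth[contig][strand]
        if not len(arr):
            continue
        change = np.flatnonzero(np.diff(arr)) + 1
        bounds = np.concatenate(([0], change, [len(arr)]))
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            val = int(arr[lo])
            if val:
                lines.append(f"{contig}\t{lo}\t{hi}\t{val}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def bedgraph_to_depth(path, contig_lengths: Mapping[str, int]) -> dict[str, np.ndarray]:
    out = {c: np.zeros(n, dtype=np.int32) for c, n in contig_lengths.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            contig, lo, hi, val = line.split("\t")
            out[contig][int(lo):int(hi)] = int(val)
    return out
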