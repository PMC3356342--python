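"""Strand-specific transcribed-contig discovery from per-base depth.

A transcribed contig is a maximal run of consecutive bases whose depth on
one strand reaches the expression threshold (default 2x, no bridging
across sub-threshold bases); only runs longer than 180 bp are reported.
Contigs are then classified against the gene annotation: overlapping a
same-strand gene by at least one base makes a contig genic_sense
(same-strand overlap takes precedence when both strands are hit),
overlapping genes only on the opposite strand makes it antisense, and
overlapping no gene makes it intergenic.  The "non-coding" tally is the
intergenic + antisense total, with genic_sense contigs kept separate.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core_model import (
    GeneModel,
    NormalizedCounts,
    PipelineConfig,
    TranscribedContig,
    from_slice,
)

from .tag_mapper import DepthArrays


def expressed_contigs(depth: DepthArrays,
                      config: PipelineConfig) -> list[TranscribedContig]:
    """Maximal runs with depth >= min_expressed_depth, longer than 180 bp."""
    out: list[TranscribedContig] = []
    for contig in sorted(depth):
        for strand in ("+", "-"):
            arr = depth[contig][strand]
            mask = arr >= config.min_expressed_depth
            if not mask.any():
                continue
            padded = np.concatenate(([False], mask, [False]))
            edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
            for lo, hi in zip(edges[::2], edges[1::2]):
                if hi - lo < config.min_contig_bp:
                    continue
                start, end = from_slice(int(lo), int(hi))
                out.append(TranscribedContig(
                    contig, strand, start, end,
                    mean_depth=float(arr[lo:hi].mean()),
                ))
    return out


def classify_contigs(contigs: Sequence[TranscribedContig],
                     genes: Sequence[GeneModel],
                     ) -> tuple[list[TranscribedContig], dict[str, int]]:
    """Assign genic_sense / antisense / intergenic classes in place and
    return per-class counts (plus the non-coding total)."""
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.contig_id, IntervalTree())[g.start:g.end + 1] = g
    counts = {"genic_sense": 0, "antisense": 0, "intergenic": 0}
    for c in contigs:
        tree = trees.get(c.contig_id)
        hits = [iv.data for iv in tree[c.start:c.end + 1]] if tree else []
        if any(g.strand == c.strand for g in hits):
            c.klass = "genic_sense"
        elif hits:
            c.klass = "antisense"
        else:
            c.klass = "intergenic"
        counts[c.klass] += 1
    counts["non_coding"] = counts["antisense"] + counts["intergenic"]
    return list(contigs), counts


def genome_coverage(depth: DepthArrays) -> float:
    """Percent of the single-strand genome length expressed on either
    strand, counting the two strands separately (ceiling 200%)."""
    total = 0
    covered = 0
    for contig, strands in depth.items():
        n = len(strands["+"])
        total += n
        covered += int((strands["+"] > 0).sum()) + int((strands["-"] > 0).sum())
    return 100.0 * covered / total if total else 0.0


def antisense_report(contigs_by_phase: Mapping[str, Sequence[TranscribedContig]],
                     norm: NormalizedCounts,
                     genes: Sequence[GeneModel],
                     phase_pair: tuple[str, str] = ("log", "stationary"),
                     ) -> pd.DataFrame:
    """Per-gene antisense summary across two growth phases.

    A gene enters the report when an antisense-classified contig overlaps
    it on the opposite strand in either phase.  For each such gene the
    report carries the best containment fraction (overlap length over
    gene length), sense and antisense normalized values in both phases,
    and an inverse-correlation flag set when sense expression falls while
    antisense rises from the first to the second phase.
    """
    early, late = phase_pair
    best_containment: dict[str, float] = {}
    phases_seen: dict[str, set[str]] = {}
    for phase, contigs in contigs_by_phase.items():
        for c in contigs:
            if c.klass != "antisense":
                continue
            for g in genes:
                if (g.contig_id != c.contig_id or g.strand == c.strand):
                    continue
                ov = min(g.end, c.end) - max(g.start, c.start) + 1
                if ov <= 0:
                    continue
                frac = ov / g.length
                if frac > best_containment.get(g.gene_id, 0.0):
                    best_containment[g.gene_id] = frac
                phases_seen.setdefault(g.gene_id, set()).add(phase)
    rows = []
    for gid in sorted(best_containment):
        if gid not in norm.sense.index:
            continue
        s_early = float(norm.sense.loc[gid, early])
        s_late = float(norm.sense.loc[gid, late])
        a_early = float(norm.antisense.loc[gid, early])
        a_late = float(norm.antisense.loc[gid, late])
        rows.append({
            "gene_id": gid,
            "containment": best_containment[gid],
            "phases_with_antisense_contig": ",".join(sorted(phases_seen[gid])),
            f"sense_{early}": s_early,
            f"sense_{late}": s_late,
            f"antisense_{early}": a_early,
            f"antisense_{late}": a_late,
            "inverse_correlation": bool(s_late < s_early and a_late > a_early),
        })
    return pd.DataFrame(rows)
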